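"""Approximately shortest masked superstrings of k-mer sets.

A *masked superstring* of a k-mer set K is a pair (S, M): a superstring S
containing every k-mer of K as a substring (in either orientation under the
bidirectional model), plus a same-length binary mask M selecting which k-mer
occurrences are *represented*.  Occurrences of k-mers outside K ("ghosts",
created at merge junctions with overlap < k-1) always carry mask 0, so the
represented set equals K exactly.  Masked superstrings generalize
spectrum-preserving string sets (SPSS): any SPSS becomes one by concatenation
with junction windows masked out.

Superstrings are built with the classic global greedy shortest-common-
superstring heuristic: strings are merged in order of decreasing
suffix-prefix overlap length (k-1 down to 0), with deterministic
lexicographic tie-breaking, and self-merges and cycles forbidden.  Under the
bidirectional model each canonical k-mer may be placed in either orientation,
and placing it consumes its reverse complement too.

Mask policies:

* ``min-one``  — each represented k-mer marked exactly once, at its leftmost
  occurrence (popcount = |K|); required for dictionary indexes.
* ``max-one``  — every occurrence of a represented k-mer marked; required for
  membership indexes.
* ``unoptimized`` — anything else (e.g. the mask inherited from an SPSS).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .kmers import KmerSet, StrandModel, canonical, reverse_complement

__all__ = [
    "MaskPolicy",
    "MaskedSuperstring",
    "greedy_superstring",
    "from_spss",
    "apply_mask_policy",
    "represented_set",
]


class MaskPolicy(str, enum.Enum):
    MIN_ONE = "min-one"
    MAX_ONE = "max-one"
    UNOPTIMIZED = "unoptimized"


@dataclass(frozen=True)
class MaskedSuperstring:
    """A superstring S over {A,C,G,T} with a same-length 0/1 mask M."""

    k: int
    model: StrandModel
    S: str
    M: str
    policy: MaskPolicy = MaskPolicy.UNOPTIMIZED

    def __post_init__(self) -> None:
        object.__setattr__(self, "model", StrandModel(self.model))
        object.__setattr__(self, "policy", MaskPolicy(self.policy))
        if len(self.M) != len(self.S):
            raise ValueError(
                f"mask length {len(self.M)} != superstring length {len(self.S)}"
            )
        if set(self.M) - {"0", "1"}:
            raise ValueError("mask must be a string over {0, 1}")
        # no k-mer can start in the last k-1 positions
        tail = self.M[max(0, len(self.M) - self.k + 1) :]
        if "1" in tail:
            raise ValueError("mask has a 1 within the last k-1 positions")

    def __len__(self) -> int:
        return len(self.S)

    def window(self, p: int) -> str:
        """The k-mer occurrence starting at position p (superstring strand)."""
        return self.S[p : p + self.k]

    def popcount(self) -> int:
        return self.M.count("1")


def _window_key(ms_model: StrandModel, window: str) -> str:
    if ms_model is StrandModel.BIDIRECTIONAL:
        return canonical(window)
    return window


def represented_set(ms: MaskedSuperstring) -> KmerSet:
    """Decode the k-mer set represented by a masked superstring.

    A k-mer belongs to the set iff at least one of its occurrences carries
    mask bit 1 (canonicalized under the bidirectional model).
    """
    out: set[str] = set()
    for p, bit in enumerate(ms.M):
        if bit == "1":
            out.add(_window_key(ms.model, ms.window(p)))
    return KmerSet(k=ms.k, model=ms.model, kmers=frozenset(out))


def apply_mask_policy(
    ms: MaskedSuperstring, target: MaskPolicy | str
) -> MaskedSuperstring:
    """Recompute the mask of ``ms`` to the target policy; S is unchanged.

    The represented set is invariant: min-one marks the leftmost occurrence
    of each represented k-mer, max-one marks every occurrence.
    """
    target = MaskPolicy(target)
    if target is MaskPolicy.UNOPTIMIZED:
        raise ValueError("cannot target the unoptimized policy")
    rep = set(represented_set(ms).kmers)
    return _mask_for_set(ms.S, ms.k, ms.model, rep, target)


def _mask_for_set(
    S: str,
    k: int,
    model: StrandModel,
    rep: set[str],
    policy: MaskPolicy,
) -> MaskedSuperstring:
    """Single left-to-right scan producing a min-one or max-one mask for rep."""
    bits = bytearray(b"0" * len(S))
    seen: set[str] = set()
    for p in range(len(S) - k + 1):
        key = _window_key(model, S[p : p + k])
        if key not in rep:
            continue
        if policy is MaskPolicy.MAX_ONE:
            bits[p] = ord("1")
        elif key not in seen:
            bits[p] = ord("1")
            seen.add(key)
    return MaskedSuperstring(
        k=k, model=model, S=S, M=bits.decode(), policy=policy
    )


def from_spss(
    segments: list[str], k: int, model: StrandModel | str = StrandModel.UNIDIRECTIONAL
) -> MaskedSuperstring:
    """Turn a spectrum-preserving string set into a masked superstring.

    Segments are concatenated without separators; the mask marks the first
    |segment| - k + 1 positions of each segment (its own k-mer starts) and
    leaves junction-spanning windows as ghosts.
    """
    model = StrandModel(model)
    parts: list[str] = []
    bits: list[str] = []
    for seg in segments:
        seg = seg.upper()
        if len(seg) < k:
            raise ValueError(f"SPSS segment {seg!r} shorter than k={k}")
        parts.append(seg)
        n_kmers = len(seg) - k + 1
        bits.append("1" * n_kmers + "0" * (k - 1))
    return MaskedSuperstring(
        k=k,
        model=model,
        S="".join(parts),
        M="".join(bits),
        policy=MaskPolicy.UNOPTIMIZED,
    )


# ---------------------------------------------------------------------------
# Global greedy superstring
# ---------------------------------------------------------------------------

_FWD, _REV = 0, 1


def _flip(o: int) -> int:
    return o ^ 1


class _GreedyState:
    """Paths of oriented k-mers under construction.

    Each input k-mer is a node with two physical ends; a merge of overlap d
    consumes the suffix end of the left oriented node and the prefix end of
    the right oriented node.  A node end that is still free is always exposed
    at a path boundary, so endpoint bookkeeping reduces to per-end freeness
    plus union-find for cycle prevention.
    """

    def __init__(self, nodes: list[str], bidirectional: bool):
        self.nodes = nodes
        self.bidirectional = bidirectional
        n = len(nodes)
        self.parent = list(range(n))
        # end_free[v][o]: the suffix end of orientation o (== prefix end of
        # the flipped orientation) is unconsumed
        self.end_free = [[True, True] for _ in range(n)]
        self.out_edge: dict[tuple[int, int], tuple[int, int, int]] = {}
        self.in_edge: dict[tuple[int, int], tuple[int, int, int]] = {}

    def find(self, v: int) -> int:
        while self.parent[v] != v:
            self.parent[v] = self.parent[self.parent[v]]
            v = self.parent[v]
        return v

    def oriented(self, v: int, o: int) -> str:
        s = self.nodes[v]
        return s if o == _FWD else reverse_complement(s)

    def orientations(self):
        return (_FWD, _REV) if self.bidirectional else (_FWD,)

    def merge(self, x: int, ox: int, y: int, oy: int, d: int) -> None:
        self.end_free[x][ox] = False
        self.end_free[y][_flip(oy)] = False
        self.out_edge[(x, ox)] = (y, oy, d)
        self.in_edge[(y, oy)] = (x, ox, d)
        self.parent[self.find(x)] = self.find(y)

    def successor(self, v: int, o: int):
        """Outgoing merge edge of oriented node (v, o), in either record."""
        e = self.out_edge.get((v, o))
        if e is not None:
            return e
        e = self.in_edge.get((v, _flip(o)))
        if e is not None:  # recorded as (x, ox) -> (v, flip(o)); flip it
            x, ox, d = e
            return (x, _flip(ox), d)
        return None


def _greedy_merge_level(state: _GreedyState, d: int) -> None:
    """Apply all greedy merges of overlap exactly d, in lexicographic order
    of (left oriented string, right oriented string, orientation flags)."""
    # right candidates bucketed by their length-d prefix
    buckets: dict[str, list[tuple[str, int, int, int]]] = {}
    for v, s in enumerate(state.nodes):
        for o in state.orientations():
            if not state.end_free[v][_flip(o)]:
                continue
            os_ = state.oriented(v, o)
            buckets.setdefault(os_[:d], []).append((os_, o, v, o))
    for lst in buckets.values():
        lst.sort()

    lefts = sorted(
        (state.oriented(v, o), o, v, o)
        for v, s in enumerate(state.nodes)
        for o in state.orientations()
        if state.end_free[v][o]
    )
    heads: dict[str, int] = {}
    for ls, _lo, x, ox in lefts:
        if not state.end_free[x][ox]:  # consumed earlier in this level
            continue
        bucket = buckets.get(ls[-d:])
        if not bucket:
            continue
        rx = state.find(x)
        head = heads.get(ls[-d:], 0)
        pos = head
        while pos < len(bucket):
            _rs, _ro, y, oy = bucket[pos]
            if not state.end_free[y][_flip(oy)]:
                if pos == head:
                    head += 1
                pos += 1
                continue
            if state.find(y) == rx:  # would close a cycle (incl. self-merge)
                pos += 1
                continue
            state.merge(x, ox, y, oy, d)
            if pos == head:
                head += 1
            break
        heads[ls[-d:]] = head


def _assemble_paths(state: _GreedyState) -> list[str]:
    """Walk every merged path and return its string, lex-canonicalized."""
    paths: list[str] = []
    emitted: set[int] = set()
    for v in range(len(state.nodes)):
        for o in state.orientations():
            # (v, o) is a path's left endpoint iff its prefix end is free
            if not state.end_free[v][_flip(o)]:
                continue
            if state.find(v) in emitted:
                continue
            chunks = [state.oriented(v, o)]
            cur = (v, o)
            while True:
                nxt = state.successor(*cur)
                if nxt is None:
                    break
                w, ow, d = nxt
                chunks.append(state.oriented(w, ow)[d:])
                cur = (w, ow)
            s = "".join(chunks)
            if state.bidirectional:
                s = min(s, reverse_complement(s))
            paths.append(s)
            emitted.add(state.find(v))
    return paths


def greedy_superstring(
    kset: KmerSet, policy: MaskPolicy | str = MaskPolicy.MIN_ONE
) -> MaskedSuperstring:
    """Build an approximately shortest masked superstring by global greedy.

    Merges are applied by decreasing overlap length from k-1 down to 1;
    remaining paths are concatenated in lexicographic order.  The result is
    deterministic, contains every k-mer of the set, and satisfies
    |S| <= k * |K|.  The mask is produced at the requested policy
    (min-one by default).
    """
    policy = MaskPolicy(policy)
    if len(kset) == 0:
        return MaskedSuperstring(
            k=kset.k, model=kset.model, S="", M="", policy=policy
        )
    nodes = sorted(kset.kmers)
    state = _GreedyState(nodes, kset.model is StrandModel.BIDIRECTIONAL)
    for d in range(kset.k - 1, 0, -1):
        _greedy_merge_level(state, d)
    S = "".join(sorted(_assemble_paths(state)))
    return _mask_for_set(S, kset.k, kset.model, set(kset.kmers), policy)
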