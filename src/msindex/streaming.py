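"""kLCP-accelerated streamed queries.

When consecutive overlapping k-mers of a query text are present in the
indexed set, each next answer can be derived from the previous suffix-array
interval in O(1): the *kLCP array* marks adjacent suffix-array ranks whose
suffixes share a prefix of length >= k-1, so the interval of a k-mer can be
widened to the interval of its (k-1)-prefix by scanning for the bounding
0 bits, after which a single backward-search step with the preceding text
character yields the next k-mer's interval.  Only a k-mer absent from the
superstring forces a full O(k) backward search for its successor.

In the bidirectional model consecutive k-mers may flip strand inside the
superstring, while kLCP extension follows one fixed strand.  Queries are
therefore split into blocks; a saturating strand counter predicts each
block's dominant strand, the predicted strand is streamed over the whole
block, and only the positions it missed are retried on the other strand.

Telemetry (the number of full backward searches and of kLCP extension steps)
is returned with the answers, making the amortization claims countable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .index import EMPTY_INTERVAL, SAInterval, backward_search

if TYPE_CHECKING:  # pragma: no cover
    from .index import SuperstringIndex
    from .mbwt import SuffixArray

__all__ = ["KLCPArray", "StreamResult", "build_klcp", "extend_to_prefix_interval", "stream_query"]

_ACGT = frozenset("ACGT")


@dataclass
class KLCPArray:
    """Bit vector over suffix-array ranks: bits[t] = 1 iff the suffixes of
    rank t and t+1 share a common prefix of length >= k-1.  The last bit
    (no successor pair) is 0."""

    bits: np.ndarray
    k: int


def build_klcp(sa: "SuffixArray", k: int) -> KLCPArray:
    """Build the kLCP array from a suffix array by Kasai's algorithm.

    LCP values are capped at k-1 (the threshold of interest), which keeps the
    pass linear without affecting the thresholded bits.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    text = sa.text
    order = sa.sa
    n = len(order)
    rank_of = np.empty(n, dtype=np.intp)
    rank_of[order] = np.arange(n)
    cap = k - 1
    lcp = np.zeros(n, dtype=np.intp)  # lcp[t] between ranks t and t+1
    h = 0
    for i in range(n):
        r = rank_of[i]
        if r == n - 1:
            h = 0
            continue
        j = order[r + 1]
        while h < cap and i + h < n and j + h < n and text[i + h] == text[j + h]:
            h += 1
        lcp[r] = h
        if h:
            h -= 1
    bits = (lcp >= cap).astype(np.uint8)
    bits[n - 1] = 0
    return KLCPArray(bits=bits, k=k)


def extend_to_prefix_interval(interval: SAInterval, klcp: KLCPArray) -> SAInterval:
    """Widen a present k-mer's interval to its (k-1)-prefix interval.

    Linear scans move the bounds outward while the separating kLCP bits are
    1; the result is the maximal enclosing run, i.e. the SA interval of the
    k-mer minus its last character.  Idempotent on already-maximal intervals.
    """
    if interval.empty:
        raise ValueError("cannot extend an empty interval")
    bits = klcp.bits
    i, j = interval.i, interval.j
    while i > 0 and bits[i - 1]:
        i -= 1
    n = len(bits)
    while j < n and bits[j - 1]:
        j += 1
    return SAInterval(i, j)


@dataclass
class StreamResult:
    """Per-position streamed answers plus operation-count telemetry.

    ``answers[t]`` corresponds to the k-mer starting at text position t
    (booleans for member, integers for lookup); ``full_searches`` counts
    O(k) backward searches, ``extensions`` counts O(1) kLCP steps.
    """

    answers: list
    full_searches: int = 0
    extensions: int = 0


def _one_backward_step(index: "SuperstringIndex", iv: SAInterval, c: str) -> SAInterval:
    img = index.image
    lt = img.count_lt(c)
    i = lt + img.rank(c, iv.i)
    j = lt + img.rank(c, iv.j)
    return EMPTY_INTERVAL if i == j else SAInterval(i, j)


def _answer(index: "SuperstringIndex", iv: SAInterval, op: str):
    """Isolated-query answer for a single-strand interval (no strand retry)."""
    if op == "member":
        if index.general_mask:
            return index._interval_hit_general(iv)
        return index._interval_hit_maxone(iv)
    ri, rj = index._interval_rank_range(iv) if not iv.empty else (0, 0)
    return ri if ri < rj else -1


def _found(answer, op: str) -> bool:
    return bool(answer) if op == "member" else answer != -1


def _strand_pass(
    index: "SuperstringIndex",
    text: str,
    positions: list[int],
    op: str,
    result: StreamResult,
    out: dict[int, object],
):
    """Stream the k-mers of ``text`` starting at ``positions`` (an ascending
    list), right to left, chaining consecutive positions through the kLCP.

    Answers are stored into ``out`` keyed by position.  Non-ACGT windows
    answer negative and break the chain.
    """
    k = index.k
    klcp = index.klcp
    iv: SAInterval | None = None
    prev_pos: int | None = None
    for t in reversed(positions):
        window = text[t : t + k]
        if not _ACGT.issuperset(window):
            out[t] = False if op == "member" else -1
            iv = None
            prev_pos = None
            continue
        chained = iv is not None and not iv.empty and prev_pos == t + 1
        if chained:
            iv = extend_to_prefix_interval(iv, klcp)
            iv = _one_backward_step(index, iv, text[t])
            result.extensions += 1
        else:
            iv = backward_search(index, window)
            result.full_searches += 1
        out[t] = _answer(index, iv, op)
        prev_pos = t


def _rc_text(text: str) -> str:
    """Loose reverse complement for query texts: non-ACGT letters map to N."""
    out = []
    for ch in reversed(text):
        out.append("ACGTN"["TGCA".find(ch) if ch in _ACGT else 4])
    return "".join(out)


def stream_query(
    index: "SuperstringIndex",
    T: str,
    op: str = "member",
    block_size: int | None = None,
) -> StreamResult:
    """Answer member/lookup for every k-mer start of T, with streaming.

    Unidirectional model: one right-to-left pass over T; after a k-mer found
    in the superstring, the next answer costs one kLCP extension plus one
    backward step.  Bidirectional model: T is split into blocks (default
    size max(k, floor(2*sqrt(|T|)))); each block is streamed on the strand
    predicted by the saturating counter and only not-found positions are
    retried on the other strand.  Answers always equal the isolated-query
    answers; only the telemetry depends on the block size.
    """
    if op not in ("member", "lookup"):
        raise ValueError(f"unknown streamed op {op!r}")
    if op == "lookup" and index.mode != "dict":
        raise ValueError("streamed lookup requires a dict-mode index")
    if index.klcp is None:
        raise ValueError("index was built without the kLCP array")
    T = T.upper()
    k = index.k
    m = len(T) - k + 1
    result = StreamResult(answers=[])
    if m <= 0:
        return result
    if not index.bidirectional:
        out: dict[int, object] = {}
        _strand_pass(index, T, list(range(m)), op, result, out)
        result.answers = [out[t] for t in range(m)]
        return result

    B = block_size if block_size is not None else max(k, math.floor(2 * math.sqrt(len(T))))
    if B < 1:
        raise ValueError(f"block size must be >= 1, got {B}")
    rc = _rc_text(T)  # position t forward <-> position n-k-t in rc, n=len(T)
    n = len(T)
    answers: dict[int, object] = {}
    for b0 in range(0, m, B):
        b1 = min(b0 + B, m)
        positions = list(range(b0, b1))
        forward_first = index.predictor.predict_forward()
        first_out: dict[int, object] = {}
        if forward_first:
            _strand_pass(index, T, positions, op, result, first_out)
        else:
            rc_positions = [n - k - t for t in reversed(positions)]
            rc_out: dict[int, object] = {}
            _strand_pass(index, rc, rc_positions, op, result, rc_out)
            first_out = {n - k - u: a for u, a in rc_out.items()}
        misses: list[int] = []
        for t in positions:
            a = first_out[t]
            if _found(a, op):
                answers[t] = a
                index.predictor.hit(forward_first)
            else:
                misses.append(t)
        if misses:
            second_out: dict[int, object] = {}
            if forward_first:
                rc_positions = [n - k - t for t in reversed(misses)]
                rc_out = {}
                _strand_pass(index, rc, rc_positions, op, result, rc_out)
                second_out = {n - k - u: a for u, a in rc_out.items()}
            else:
                _strand_pass(index, T, misses, op, result, second_out)
            for t in misses:
                a = second_out[t]
                answers[t] = a
                if _found(a, op):
                    index.predictor.hit(not forward_first)
    result.answers = [answers[t] for t in range(m)]
    return result
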