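"""Membership and dictionary query structures over the MBWT.

Two index variants are supported:

* ``memb`` — a membership index (presence test) over a *max-one* masked
  superstring: because every occurrence of a represented k-mer is marked, all
  mask bits inside a k-mer's suffix-array interval agree, and Member reads a
  single bit.
* ``dict`` — a compressed dictionary (minimal-perfect-hash style) over a
  *min-one* masked superstring: each represented k-mer carries exactly one
  mark, so ``rank1`` over the SA-transformed mask assigns k-mers the
  contiguous hash range {0, ..., |K|-1} (Lookup), and a select-driven
  first-column walk inverts the mapping (Access).

With any other mask, membership is still possible through the general-mask
path (two mask ranks per interval instead of one bit read).

In the bidirectional model a query k-mer may occur in the superstring only as
its reverse complement, so a failed search on one strand falls back to the
other.  A small saturating counter (saturation 7) predicts which strand to
try first; it biases only the search order, never the answer.
"""

from __future__ import annotations

from dataclasses import dataclass

from .kmers import StrandModel, reverse_complement
from .mbwt import (
    MBWTImage,
    build_suffix_array,
    compute_mbwt,
    mask_entropy_bits,
)
from .superstring import MaskedSuperstring, MaskPolicy

__all__ = [
    "SAInterval",
    "StrandPredictor",
    "SuperstringIndex",
    "SpaceReport",
    "build_index",
    "backward_search",
]

SATURATION = 7


class ConfigurationError(ValueError):
    """Mask policy and index mode are incompatible."""


@dataclass(frozen=True)
class SAInterval:
    """Half-open interval [i, j) of suffix-array ranks."""

    i: int
    j: int

    @property
    def empty(self) -> bool:
        return self.i == self.j

    def __len__(self) -> int:
        return self.j - self.i


EMPTY_INTERVAL = SAInterval(0, 0)


@dataclass
class StrandPredictor:
    """Signed saturating counter predicting the strand of the next hit.

    Incremented on forward hits, decremented on reverse hits, clamped to
    [-saturation, saturation].  A non-negative value predicts forward.
    """

    counter: int = 0
    saturation: int = SATURATION

    def hit(self, forward: bool) -> None:
        delta = 1 if forward else -1
        self.counter = max(-self.saturation, min(self.saturation, self.counter + delta))

    def predict_forward(self) -> bool:
        return self.counter >= 0


def backward_search(index: "SuperstringIndex", Q: str) -> SAInterval:
    """FM-index backward search: the interval of suffixes prefixed by Q.

    Characters of Q are consumed right to left; the search early-exits to the
    canonical empty interval (0, 0) as soon as the interval collapses.
    """
    img = index.image
    i, j = 0, len(img)
    for c in reversed(Q):
        lt = img.count_lt(c)
        i = lt + img.rank(c, i)
        j = lt + img.rank(c, j)
        if i == j:
            return EMPTY_INTERVAL
    return SAInterval(i, j)


@dataclass
class SpaceReport:
    """Analytic space accounting of an index (bits).

    ``superstring_bits`` is 2 bits per superstring character, ``mask_bits``
    the zeroth-order entropy log2 C(|S|, popcount(M)) of the mask, and
    ``total`` their sum — the storage bound of the index proper.  Directory
    structures for rank/select (and the optional kLCP bit vector) are the
    sublinear implementation overhead and are reported separately, never
    folded into ``total``.
    """

    superstring_bits: float
    mask_bits: float
    total: float
    bits_per_kmer: float | None
    overhead_bits: float
    klcp_bits: float = 0.0


class SuperstringIndex:
    """Queryable index over the MBWT of a masked superstring."""

    def __init__(
        self,
        image: MBWTImage,
        mode: str,
        klcp: "KLCPArray | None" = None,
        *,
        allow_general_mask: bool = False,
    ):
        if mode not in ("memb", "dict"):
            raise ConfigurationError(f"unknown mode {mode!r}")
        required = MaskPolicy.MAX_ONE if mode == "memb" else MaskPolicy.MIN_ONE
        if image.policy is not required and not allow_general_mask:
            raise ConfigurationError(
                f"mode {mode!r} requires a {required.value} mask "
                f"(got {image.policy.value}); pass allow_general_mask=True "
                "to opt into general-mask queries"
            )
        self.image = image
        self.mode = mode
        self.klcp = klcp
        self.general_mask = image.policy is not required
        self.predictor = StrandPredictor()

    # -- basic properties ----------------------------------------------------
    @property
    def k(self) -> int:
        return self.image.k

    @property
    def model(self) -> StrandModel:
        return self.image.model

    @property
    def bidirectional(self) -> bool:
        return self.model is StrandModel.BIDIRECTIONAL

    def _check_query(self, Q: str) -> None:
        if len(Q) != self.k:
            raise ValueError(f"query length {len(Q)} != k={self.k}")

    # -- interval-level predicates -------------------------------------------
    def _interval_hit_maxone(self, iv: SAInterval) -> bool:
        return not iv.empty and self.image.mprime[iv.i] == "1"

    def _interval_rank_range(self, iv: SAInterval) -> tuple[int, int]:
        return self.image.mask.rank1(iv.i), self.image.mask.rank1(iv.j)

    def _interval_hit_general(self, iv: SAInterval) -> bool:
        if iv.empty:
            return False
        ri, rj = self._interval_rank_range(iv)
        return ri < rj

    def _strand_order(self, Q: str) -> list[tuple[str, bool]]:
        """(query string, is_forward) pairs in predictor-preferred order."""
        if not self.bidirectional:
            return [(Q, True)]
        pairs = [(Q, True), (reverse_complement(Q), False)]
        if not self.predictor.predict_forward():
            pairs.reverse()
        return pairs

    # -- query operations ------------------------------------------------------
    def member(self, Q: str) -> bool:
        """Is the (canonicalized) k-mer Q in the indexed set?

        Requires a max-one mask (memb mode): a non-empty backward-search
        interval is uniform in the mask, so its first bit is the answer.  The
        predictor-preferred strand is searched first; on a miss the other
        strand is tried (bidirectional model only).
        """
        self._check_query(Q)
        if self.general_mask:
            return self.member_general_mask(Q)
        if self.mode != "memb":
            # a min-one mask is not interval-uniform; use the general path
            return self.member_general_mask(Q)
        for q, forward in self._strand_order(Q):
            if self._interval_hit_maxone(backward_search(self, q)):
                self.predictor.hit(forward)
                return True
        return False

    def member_general_mask(self, Q: str) -> bool:
        """Membership under an arbitrary mask policy.

        True iff the interval of Q (on either strand, per the model) contains
        at least one 1 — determined by two mask ranks per strand.
        """
        self._check_query(Q)
        for q, forward in self._strand_order(Q):
            if self._interval_hit_general(backward_search(self, q)):
                self.predictor.hit(forward)
                return True
        return False

    def lookup(self, Q: str) -> int:
        """The minimal perfect hash of Q in {0, ..., |K|-1}, or -1 if absent.

        Requires a min-one mask (dict mode).  The single mark of a
        represented k-mer lives in the interval of exactly one strand, so
        both strands are checked before concluding absence.
        """
        self._check_query(Q)
        if self.mode != "dict":
            raise ConfigurationError("lookup requires a dict-mode index")
        for q, forward in self._strand_order(Q):
            iv = backward_search(self, q)
            if iv.empty:
                continue
            ri, rj = self._interval_rank_range(iv)
            if ri < rj:
                self.predictor.hit(forward)
                return ri
        return -1

    def access(self, h: int) -> str:
        """The k-mer with hash h, in superstring orientation.

        Inverse of :meth:`lookup` up to reverse complementation: starting at
        the h-th mask mark, k first-column/select steps spell the k-mer left
        to right.
        """
        if self.mode != "dict":
            raise ConfigurationError("access requires a dict-mode index")
        img = self.image
        if not 0 <= h < img.mask.n_ones:
            raise IndexError(f"hash {h} out of range [0, {img.mask.n_ones})")
        i = img.mask.select1(h)
        out = []
        for _ in range(self.k):
            c = img.f_char(i)
            i = img.select(c, i - img.count_lt(c))
            out.append(c)
        return "".join(out)

    # -- space accounting ------------------------------------------------------
    def space_report(self, K_size: int) -> SpaceReport:
        """Analytic storage bound: 2|S| + log2 C(|S|, |M|_1), plus overhead.

        Overhead models rank/select directories at 64-position blocks with
        32-bit counters (one counter per alphabet symbol for S', one for the
        mask), and counts the kLCP bit vector when present.
        """
        n = len(self.image)  # |S| + 1 (sentinel)
        s_len = n - 1
        ones = self.image.mask.n_ones
        superstring_bits = 2.0 * s_len
        mask_bits = mask_entropy_bits(s_len, ones) if s_len else 0.0
        total = superstring_bits + mask_bits
        blocks = -(-n // 64)
        overhead = blocks * 32 * (len("ACGT$")) + blocks * 32
        klcp_bits = float(len(self.klcp.bits)) if self.klcp is not None else 0.0
        return SpaceReport(
            superstring_bits=superstring_bits,
            mask_bits=mask_bits,
            total=total,
            bits_per_kmer=(total / K_size) if K_size else None,
            overhead_bits=float(overhead),
            klcp_bits=klcp_bits,
        )


def build_index(
    ms: MaskedSuperstring,
    mode: str = "memb",
    with_klcp: bool = False,
    *,
    allow_general_mask: bool = False,
) -> SuperstringIndex:
    """Build a membership or dictionary index from a masked superstring.

    The mask policy must match the mode (max-one for memb, min-one for dict)
    unless ``allow_general_mask`` opts into the slower general-mask query
    path.  ``with_klcp`` additionally builds the kLCP bit vector enabling
    O(1)-amortized streamed queries.
    """
    sa = build_suffix_array(ms.S)
    image = compute_mbwt(ms, sa)
    klcp = None
    if with_klcp:
        from .streaming import build_klcp

        klcp = build_klcp(sa, ms.k)
    return SuperstringIndex(
        image, mode, klcp, allow_general_mask=allow_general_mask
    )
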