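"""The Masked Burrows-Wheeler Transform (MBWT).

The MBWT extends the classical BWT to masked superstrings: alongside the BWT
image S' of the superstring S, the mask M is permuted into suffix-array order,
giving the *SA-transformed mask* M' with M'[i] = M[j] where j is the start of
the i-th lexicographically smallest suffix of S.  The pair (S', M') losslessly
encodes (S, M) while making every k-mer occurrence addressable by backward
search, which is what turns a masked superstring into an exact index.

Conventions
-----------
The implementation appends a single terminal sentinel ``$`` smaller than all
bases (character order $ < A < C < G < T), with a 0 mask bit appended for the
sentinel position.  The mathematically cleaner cyclic-rotation formulation is
provided as reference functions (:func:`cyclic_mbwt_definition`,
:func:`cyclic_mbwt_rotate_glue`) restricted to primitive strings, where the
two constructions — permuting the mask directly by suffix rank versus rotating
the mask left by one, gluing it to the text, and running a text-keyed BWT —
provably coincide.

Suffix arrays are built with a numpy prefix-doubling sort (worst-case
O(n log^2 n)); rank/select over S' and M' use plain cumulative-count tables.
Physical succinctness is not attempted: index space is *accounted*
analytically (2 bits per superstring character for S', the zeroth-order
entropy log2 C(|S|, |M|_1) for the mask, with rank/select directory overhead
reported separately).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from .kmers import StrandModel
from .superstring import MaskedSuperstring, MaskPolicy

__all__ = [
    "SENTINEL",
    "ALPHABET",
    "SuffixArray",
    "MBWTImage",
    "build_suffix_array",
    "compute_mbwt",
    "invert_mbwt",
    "mask_entropy_bits",
    "cyclic_mbwt_definition",
    "cyclic_mbwt_rotate_glue",
]

SENTINEL = "$"
ALPHABET = "$ACGT"  # index = internal code; sentinel smallest
_CODE = {c: i for i, c in enumerate(ALPHABET)}

_ENC = np.full(128, -1, dtype=np.int8)
for _c, _i in _CODE.items():
    _ENC[ord(_c)] = _i


class StructuralError(ValueError):
    """A BWT image is malformed (missing or duplicated sentinel)."""


def _encode(text: str) -> np.ndarray:
    arr = _ENC[np.frombuffer(text.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = sorted({ch for ch in text if ch not in _CODE})
        raise ValueError(f"character(s) {bad!r} outside alphabet {ALPHABET!r}")
    return arr.astype(np.intp)


class SuffixArray:
    """Suffix array of S + sentinel, suffixes in increasing lexicographic order."""

    def __init__(self, text: str, sa: np.ndarray):
        self.text = text
        self.sa = np.asarray(sa, dtype=np.intp)

    def __len__(self) -> int:
        return len(self.sa)


def build_suffix_array(S: str) -> SuffixArray:
    """Build the suffix array of ``S`` + sentinel by prefix doubling."""
    text = S + SENTINEL
    if SENTINEL in S:
        raise ValueError("input string must not contain the sentinel")
    codes = _encode(text)
    n = len(codes)
    rank = codes.copy()
    step = 1
    while True:
        second = np.full(n, -1, dtype=np.intp)
        second[: n - step] = rank[step:]
        order = np.lexsort((second, rank))
        r_ord = rank[order]
        s_ord = second[order]
        changed = np.ones(n, dtype=bool)
        changed[1:] = (r_ord[1:] != r_ord[:-1]) | (s_ord[1:] != s_ord[:-1])
        new_rank = np.empty(n, dtype=np.intp)
        new_rank[order] = np.cumsum(changed) - 1
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return SuffixArray(text, order)
        step *= 2


class _BitSupport:
    """Rank/select over a 0/1 numpy array via cumulative counts."""

    def __init__(self, bits: np.ndarray):
        self.bits = bits
        self._cum = np.concatenate(([0], np.cumsum(bits, dtype=np.intp)))
        self._ones = np.flatnonzero(bits)

    def rank1(self, i: int) -> int:
        """Number of 1s in bits[0:i]."""
        return int(self._cum[i])

    def select1(self, r: int) -> int:
        """Position of the r-th 1 (0-based)."""
        if not 0 <= r < len(self._ones):
            raise IndexError(f"select1({r}) out of range")
        return int(self._ones[r])

    @property
    def n_ones(self) -> int:
        return len(self._ones)


class MBWTImage:
    """MBWT of a masked superstring, with rank/select support.

    Attributes
    ----------
    sprime, mprime : str
        BWT image of S + sentinel and the SA-transformed (extended) mask.
    counts : numpy array of length 6
        ``counts[code(c)]`` = number of characters of the text strictly
        smaller than ``c`` (sentinel included); ``counts[5]`` = n.
    """

    def __init__(
        self,
        k: int,
        model: StrandModel,
        sprime: str,
        mprime: str,
        policy: MaskPolicy = MaskPolicy.UNOPTIMIZED,
    ):
        if len(sprime) != len(mprime):
            raise StructuralError("sprime and mprime lengths differ")
        if sprime.count(SENTINEL) != 1:
            raise StructuralError("BWT image must contain exactly one sentinel")
        self.k = k
        self.model = StrandModel(model)
        self.policy = MaskPolicy(policy)
        self.sprime = sprime
        self.mprime = mprime
        codes = _encode(sprime)
        self._codes = codes
        n = len(codes)
        onehot = np.zeros((n, len(ALPHABET)), dtype=np.intp)
        onehot[np.arange(n), codes] = 1
        self._occ = np.vstack(
            [np.zeros(len(ALPHABET), dtype=np.intp), np.cumsum(onehot, axis=0)]
        )
        char_counts = self._occ[n]
        self.counts = np.concatenate(([0], np.cumsum(char_counts)))
        self._positions = [np.flatnonzero(codes == c) for c in range(len(ALPHABET))]
        mask_bits = (
            np.frombuffer(mprime.encode("ascii"), dtype=np.uint8) - ord("0")
        ).astype(np.intp)
        if set(mprime) - {"0", "1"}:
            raise StructuralError("mprime must be over {0, 1}")
        self.mask = _BitSupport(mask_bits)

    def __len__(self) -> int:
        return len(self.sprime)

    # -- rank/select over the BWT string ------------------------------------
    def rank(self, c: str, i: int) -> int:
        """Occurrences of character c in sprime[0:i]."""
        return int(self._occ[i, _CODE[c]])

    def select(self, c: str, r: int) -> int:
        """Position of the r-th occurrence (0-based) of c in sprime."""
        pos = self._positions[_CODE[c]]
        if not 0 <= r < len(pos):
            raise IndexError(f"select({c!r}, {r}) out of range")
        return int(pos[r])

    def count_lt(self, c: str) -> int:
        """|S|_<c: number of text characters strictly smaller than c."""
        return int(self.counts[_CODE[c]])

    def f_char(self, i: int) -> str:
        """The first-column (sorted text) character at suffix rank i."""
        c = int(np.searchsorted(self.counts, i, side="right")) - 1
        return ALPHABET[c]

    def lf(self, i: int) -> int:
        """Last-to-first mapping: the rank of the suffix one position left."""
        c = self.sprime[i]
        return self.count_lt(c) + self.rank(c, i)


def compute_mbwt(ms: MaskedSuperstring, sa: SuffixArray | None = None) -> MBWTImage:
    """Compute the MBWT of a masked superstring (sentinel convention).

    ``sprime[i] = text[sa[i] - 1 mod n]`` is the standard BWT of S + sentinel;
    ``mprime[i]`` is the extended mask (M plus a 0 for the sentinel) at the
    start of the i-th smallest suffix.  A precomputed suffix array of ``ms.S``
    may be passed to avoid re-sorting.
    """
    if sa is None:
        sa = build_suffix_array(ms.S)
    text = sa.text
    n = len(text)
    ext_mask = ms.M + "0"
    sprime = "".join(text[(j - 1) % n] for j in sa.sa)
    mprime = "".join(ext_mask[j] for j in sa.sa)
    return MBWTImage(ms.k, ms.model, sprime, mprime, ms.policy)


def invert_mbwt(img: MBWTImage) -> MaskedSuperstring:
    """Recover (S, M) exactly from an MBWT image by an LF-mapping walk.

    Starting at the sentinel row, each LF step emits the preceding text
    character; the emitted character's mask bit is mprime at the rank of the
    suffix starting at that text position (i.e. at the post-step row).
    """
    n = len(img)
    chars: list[str] = []
    bits: list[str] = []
    i = 0  # rank of the sentinel-only suffix
    for _ in range(n - 1):
        c = img.sprime[i]
        if c == SENTINEL:
            raise StructuralError("unexpected sentinel during inversion")
        i = img.lf(i)
        chars.append(c)
        bits.append(img.mprime[i])
    S = "".join(reversed(chars))
    M = "".join(reversed(bits))
    return MaskedSuperstring(k=img.k, model=img.model, S=S, M=M, policy=img.policy)


def mask_entropy_bits(n: int, ones: int) -> float:
    """log2 of binomial(n, ones): the zeroth-order entropy of the mask.

    Computed via log-gamma so huge masks do not overflow.  This is the mask
    term of the analytic space bound 2|S| + log2 C(|S|, |M|_1) + o(|S|).
    """
    if not 0 <= ones <= n:
        raise ValueError(f"need 0 <= ones <= n, got ones={ones}, n={n}")
    ln = gammaln(n + 1) - gammaln(ones + 1) - gammaln(n - ones + 1)
    return float(ln / np.log(2.0))


# ---------------------------------------------------------------------------
# Cyclic-convention reference forms (used to validate the construction)
# ---------------------------------------------------------------------------

def _check_primitive(rotations: list[str]) -> None:
    if len(set(rotations)) != len(rotations):
        raise ValueError("cyclic MBWT requires a primitive (aperiodic) string")


def cyclic_mbwt_definition(S: str, M: str) -> tuple[str, str]:
    """Direct cyclic MBWT: sort rotations, read last characters and the mask
    at each rotation's start position."""
    n = len(S)
    rotations = [S[j:] + S[:j] for j in range(n)]
    _check_primitive(rotations)
    order = sorted(range(n), key=lambda j: rotations[j])
    sprime = "".join(S[(j - 1) % n] for j in order)
    mprime = "".join(M[j] for j in order)
    return sprime, mprime


def cyclic_mbwt_rotate_glue(S: str, M: str) -> tuple[str, str]:
    """Cyclic MBWT via rotate-left-by-1, glue, text-keyed BWT, unzip.

    The mask is rotated one position left, zipped to the text, and the pairs
    are sorted by rotations of the *text only*; the last pair of each sorted
    rotation is unzipped into (sprime, mprime).
    """
    n = len(S)
    rotations = [S[j:] + S[:j] for j in range(n)]
    _check_primitive(rotations)
    m2 = M[1:] + M[:1]
    order = sorted(range(n), key=lambda j: rotations[j])
    sprime = "".join(S[(j - 1) % n] for j in order)
    mprime = "".join(m2[(j - 1) % n] for j in order)
    return sprime, mprime
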