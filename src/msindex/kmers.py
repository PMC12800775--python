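"""Canonical k-mer arithmetic and k-mer set extraction.

A k-mer is a length-k string over the DNA alphabet {A, C, G, T}.  Two strand
models are supported:

* ``unidirectional`` — a k-mer and its reverse complement are distinct objects;
* ``bidirectional`` — a k-mer and its reverse complement are considered equal,
  and every set member is stored in *canonical* form, defined here as the
  lexicographically smaller of the pair.  The convention is fixed so that
  downstream dictionary hashes are stable.

Windows containing non-ACGT letters (N, IUPAC ambiguity codes) are skipped
during extraction rather than rejected; lower-case input is upcased on
ingestion, since letter case is reserved for mask encoding in the masked
superstring interchange format.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StrandModel",
    "KmerSet",
    "reverse_complement",
    "canonical",
    "extract_kmer_set",
    "subsample",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALPHABET = frozenset("ACGT")


class AlphabetError(ValueError):
    """A sequence contains a character outside {A, C, G, T}."""


class StrandModel(str, enum.Enum):
    """Whether a k-mer and its reverse complement are identified."""

    UNIDIRECTIONAL = "uni"
    BIDIRECTIONAL = "bi"


def _check_alphabet(seq: str) -> None:
    if not _ALPHABET.issuperset(seq):
        bad = sorted(set(seq) - _ALPHABET)
        raise AlphabetError(f"non-ACGT character(s) {bad!r} in sequence")


def reverse_complement(seq: str) -> str:
    """Return the reverse complement of a DNA string.

    Involutive: ``reverse_complement(reverse_complement(x)) == x``.

    Raises
    ------
    AlphabetError
        If ``seq`` contains a character outside {A, C, G, T}.
    """
    _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Return the canonical form of a k-mer: min(kmer, RC(kmer)).

    A palindromic k-mer (one equal to its own reverse complement, possible
    only for even k) canonicalizes to itself.
    """
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass(frozen=True)
class KmerSet:
    """A finite set of k-mers with its length ``k`` and strand model.

    Under the bidirectional model every member equals its own canonical form.
    """

    k: int
    model: StrandModel
    kmers: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        object.__setattr__(self, "model", StrandModel(self.model))
        object.__setattr__(self, "kmers", frozenset(self.kmers))
        for km in self.kmers:
            if len(km) != self.k:
                raise ValueError(f"k-mer {km!r} has length != k={self.k}")
            _check_alphabet(km)
            if self.model is StrandModel.BIDIRECTIONAL and canonical(km) != km:
                raise ValueError(f"k-mer {km!r} is not canonical")

    def __len__(self) -> int:
        return len(self.kmers)

    def __contains__(self, kmer: str) -> bool:
        """Membership under the set's strand model (canonicalizes first)."""
        if len(kmer) != self.k:
            return False
        if self.model is StrandModel.BIDIRECTIONAL:
            kmer = canonical(kmer)
        return kmer in self.kmers

    def __iter__(self):
        return iter(self.kmers)


def extract_kmer_set(
    sequences: list[str],
    k: int,
    model: StrandModel | str = StrandModel.UNIDIRECTIONAL,
    *,
    strict: bool = False,
) -> KmerSet:
    """Extract the set of k-mers of a collection of DNA sequences.

    Every length-k window over {A,C,G,T} contributes one k-mer (canonicalized
    under the bidirectional model).  Windows containing any other letter are
    skipped, unless ``strict`` is set, in which case such sequences raise
    :class:`AlphabetError`.  Sequences shorter than k contribute nothing.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    model = StrandModel(model)
    bidir = model is StrandModel.BIDIRECTIONAL
    out: set[str] = set()
    for seq in sequences:
        seq = seq.upper()
        if strict:
            _check_alphabet(seq)
        # split on non-ACGT runs so no window spans an invalid letter
        for run in _acgt_runs(seq):
            for p in range(len(run) - k + 1):
                km = run[p : p + k]
                out.add(canonical(km) if bidir else km)
    return KmerSet(k=k, model=model, kmers=frozenset(out))


def _acgt_runs(seq: str):
    """Yield maximal substrings of ``seq`` over {A, C, G, T}."""
    start = None
    for i, ch in enumerate(seq):
        if ch in _ALPHABET:
            if start is None:
                start = i
        else:
            if start is not None:
                yield seq[start:i]
                start = None
    if start is not None:
        yield seq[start:]


def subsample(
    kset: KmerSet,
    fraction: float,
    seed: int,
    *,
    exact: bool = False,
) -> KmerSet:
    """Uniformly subsample a k-mer set, deterministically given ``seed``.

    By default each k-mer is kept independently with probability ``fraction``
    (Bernoulli thinning).  With ``exact=True`` exactly
    ``round(fraction * |K|)`` k-mers are kept (hypergeometric variant).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    members = sorted(kset.kmers)  # fixed order => reproducible draws
    rng = np.random.default_rng(seed)
    if exact:
        n_keep = int(round(fraction * len(members)))
        idx = rng.choice(len(members), size=n_keep, replace=False)
        kept = [members[i] for i in idx]
    else:
        mask = rng.random(len(members)) < fraction
        kept = [m for m, keep in zip(members, mask) if keep]
    return KmerSet(k=kset.k, model=kset.model, kmers=frozenset(kept))
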