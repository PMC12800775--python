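"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths: naive
suffix sorting, naive adjacent-LCP computation, and window-enumeration
decoding are used to cross-check the production implementations.
"""

from __future__ import annotations

import numpy as np
import pytest

from msindex import KmerSet, StrandModel, canonical


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def naive_suffix_array(S: str) -> list[int]:
    """O(n^2 log n) suffix sort of S + '$' with '$' smallest."""
    text = S + "\x00"  # NUL sorts below ACGT like the sentinel
    return sorted(range(len(text)), key=lambda i: text[i:])


def naive_adjacent_lcp(S: str) -> list[int]:
    """LCP of lexicographically adjacent suffixes of S + sentinel."""
    text = S + "\x00"
    sa = naive_suffix_array(S)
    out = []
    for a, b in zip(sa, sa[1:]):
        x, y = text[a:], text[b:]
        h = 0
        while h < min(len(x), len(y)) and x[h] == y[h]:
            h += 1
        out.append(h)
    return out


def window_set(S: str, M: str, k: int, model: str) -> set[str]:
    """Decode a masked superstring by direct window enumeration."""
    out = set()
    for p in range(len(S) - k + 1):
        if M[p] == "1":
            w = S[p : p + k]
            out.add(canonical(w) if model == "bi" else w)
    return out


def naive_prefix_interval(S: str, prefix: str) -> tuple[int, int]:
    """SA interval of suffixes of S + sentinel starting with ``prefix``."""
    sa = naive_suffix_array(S)
    text = S + "\x00"
    lo = len(sa)
    hi = 0
    found = False
    for r, p in enumerate(sa):
        if text[p : p + len(prefix)] == prefix:
            if not found:
                lo = r
                found = True
            hi = r + 1
    return (lo, hi) if found else (0, 0)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n)) if n else ""


def random_kmer_set(rng: np.random.Generator, k: int, n: int, model: str) -> KmerSet:
    kmers = set()
    for _ in range(n):
        km = random_dna(rng, k)
        kmers.add(canonical(km) if model == "bi" else km)
    return KmerSet(k=k, model=StrandModel(model), kmers=frozenset(kmers))


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_battery():
    """A reduced fixture battery for fast per-module tests."""
    from msindex.fixtures import standard_battery

    return standard_battery(11, small=True)
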