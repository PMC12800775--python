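"""Synthetic data generation for tests, benchmarks and examples.

The generator emulates the dataset regimes that matter for superstring-based
indexing, without external downloads:

* ``random_genome`` — a single uniform ACGT string: a k-mer set with the
  spectrum-like property (one long generating string, nearly all (k-1)-long
  overlaps present), the easy case for de Bruijn graph methods.
* ``pangenome`` — g mutants of one base genome with i.i.d. substitutions at
  per-base rate mu: high-diversity collections whose polymorphisms fragment
  the de Bruijn graph.
* ``random_kmers`` — n uniform random k-mers: essentially overlap-free sets,
  the worst case for (k-1)-overlap-based methods and the regime where masked
  superstrings retain their guarantees.
* ``subsampled`` — any of the above pushed through uniform subsampling,
  emulating sketched or downsampled sets with destroyed overlap structure.

All outputs are deterministic functions of the seed.
"""

from __future__ import annotations

import numpy as np

from .kmers import KmerSet, StrandModel, canonical, extract_kmer_set, subsample

__all__ = [
    "random_genome",
    "pangenome",
    "random_kmers",
    "generate_fixture",
    "standard_battery",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_genome(L: int, seed: int) -> str:
    """A uniform random DNA string of length L."""
    if L < 0:
        raise ValueError(f"L must be >= 0, got {L}")
    rng = np.random.default_rng(seed)
    return rng.choice(_BASES, size=L).tobytes().decode("ascii")


def pangenome(L: int, g: int, mu: float, seed: int) -> list[str]:
    """g mutants of one random base genome, substitutions i.i.d. at rate mu."""
    if g < 1:
        raise ValueError(f"g must be >= 1, got {g}")
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"mutation rate must be in [0, 1], got {mu}")
    rng = np.random.default_rng(seed)
    base = rng.choice(_BASES, size=L)
    genomes = []
    for _ in range(g):
        seq = base.copy()
        sites = np.flatnonzero(rng.random(L) < mu)
        # substitute with one of the three other bases
        if len(sites):
            shift = rng.integers(1, 4, size=len(sites))
            idx = np.searchsorted(_BASES, seq[sites])
            seq[sites] = _BASES[(idx + shift) % 4]
        genomes.append(seq.tobytes().decode("ascii"))
    return genomes


def random_kmers(
    n: int, k: int, model: StrandModel | str, seed: int
) -> KmerSet:
    """n uniform random k-mers (canonicalized and deduplicated per model)."""
    model = StrandModel(model)
    rng = np.random.default_rng(seed)
    draws = rng.choice(_BASES, size=(n, k))
    kmers = set()
    for row in draws:
        km = row.tobytes().decode("ascii")
        kmers.add(canonical(km) if model is StrandModel.BIDIRECTIONAL else km)
    return KmerSet(k=k, model=model, kmers=frozenset(kmers))


def generate_fixture(kind: str, seed: int, **params) -> dict:
    """Dispatching front-end: returns {'sequences': [...]} and/or
    {'kmer_set': KmerSet} depending on the fixture kind.

    Parameters by kind: random_genome(L, [k, model]); pangenome(L, g, mu,
    [k, model]); random_kmers(n, k, model); subsampled(base=<kind>, f,
    plus the base kind's parameters).
    """
    if kind == "random_genome":
        seqs = [random_genome(params["L"], seed)]
        out = {"sequences": seqs}
        if "k" in params:
            out["kmer_set"] = extract_kmer_set(
                seqs, params["k"], params.get("model", "uni")
            )
        return out
    if kind == "pangenome":
        seqs = pangenome(params["L"], params["g"], params["mu"], seed)
        out = {"sequences": seqs}
        if "k" in params:
            out["kmer_set"] = extract_kmer_set(
                seqs, params["k"], params.get("model", "uni")
            )
        return out
    if kind == "random_kmers":
        kset = random_kmers(params["n"], params["k"], params.get("model", "uni"), seed)
        return {"kmer_set": kset}
    if kind == "subsampled":
        base = dict(params)
        fraction = base.pop("f")
        inner = generate_fixture(base.pop("base"), seed, **base)
        if "kmer_set" not in inner:
            raise ValueError("subsampled fixture needs k to extract a k-mer set")
        inner["kmer_set"] = subsample(
            inner["kmer_set"], fraction, seed + 1, exact=params.get("exact", False)
        )
        return inner
    raise ValueError(f"unknown fixture kind {kind!r}")


def standard_battery(seed: int, *, small: bool = False) -> list[tuple[str, KmerSet]]:
    """The standard fixture battery: named k-mer sets spanning genome,
    pangenome, random-k-mer and subsampled regimes, both strand models,
    k in {5, 7, 11, 15, 31}.

    ``small`` shrinks every size by ~4x for quick test runs.
    """
    s = 4 if small else 1
    specs: list[tuple[str, str, dict]] = [
        ("genome-k11-uni", "random_genome", dict(L=20000 // s, k=11, model="uni")),
        ("genome-k11-bi", "random_genome", dict(L=20000 // s, k=11, model="bi")),
        ("genome-k31-uni", "random_genome", dict(L=30000 // s, k=31, model="uni")),
        ("genome-k31-bi", "random_genome", dict(L=30000 // s, k=31, model="bi")),
        ("genome-k5-uni", "random_genome", dict(L=400, k=5, model="uni")),
        ("genome-k5-bi", "random_genome", dict(L=400, k=5, model="bi")),
        ("pan-k15-uni", "pangenome", dict(L=6000 // s, g=8, mu=0.01, k=15, model="uni")),
        ("pan-k15-bi", "pangenome", dict(L=6000 // s, g=8, mu=0.01, k=15, model="bi")),
        ("pan-k11-bi", "pangenome", dict(L=4000 // s, g=4, mu=0.05, k=11, model="bi")),
        ("rand-k31-uni", "random_kmers", dict(n=3000 // s, k=31, model="uni")),
        ("rand-k31-bi", "random_kmers", dict(n=3000 // s, k=31, model="bi")),
        ("rand-k15-bi", "random_kmers", dict(n=2000 // s, k=15, model="bi")),
        ("rand-k7-uni", "random_kmers", dict(n=500 // s, k=7, model="uni")),
        ("rand-k7-bi", "random_kmers", dict(n=500 // s, k=7, model="bi")),
        ("sub-genome-k11-uni", "subsampled",
         dict(base="random_genome", L=20000 // s, k=11, model="uni", f=0.1)),
        ("sub-genome-k31-bi", "subsampled",
         dict(base="random_genome", L=30000 // s, k=31, model="bi", f=0.1)),
        ("sub-pan-k15-bi", "subsampled",
         dict(base="pangenome", L=6000 // s, g=8, mu=0.01, k=15, model="bi", f=0.1)),
        ("sub-rand-k31-bi", "subsampled",
         dict(base="random_kmers", n=3000 // s, k=31, model="bi", f=0.1)),
        ("sub-rand-k15-bi", "subsampled",
         dict(base="random_kmers", n=2000 // s, k=15, model="bi", f=0.1)),
        ("sub-pan-k11-uni", "subsampled",
         dict(base="pangenome", L=4000 // s, g=4, mu=0.05, k=11, model="uni", f=0.1)),
    ]
    battery = []
    for i, (name, kind, params) in enumerate(specs):
        fx = generate_fixture(kind, seed + 1000 * i, **params)
        battery.append((name, fx["kmer_set"]))
    return battery
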