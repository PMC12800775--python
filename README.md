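# msindex

Space-efficient indexing of arbitrary k-mer sets via masked superstrings and
the Masked Burrows-Wheeler Transform (MBWT).

## The problem

Modern sequence analysis tokenizes genomes, pangenomes and read sets into
*k-mers* — length-k strings over {A, C, G, T} — and needs compact data
structures answering, for a fixed set *K* of (canonical) k-mers:

* **Membership** — is a query k-mer *Q* in *K*?
* **Dictionary** — a bijection between *K* and the hash range
  {0, …, |K|−1}: `lookup(Q)` returns *Q*'s unique minimal hash (or −1),
  `access(h)` returns the k-mer with hash *h* (a minimal perfect hash with
  rejection, plus its inverse).
* **Streaming** — amortized O(1) queries for consecutive overlapping k-mers
  of a query sequence.

Most indexes exploit the *spectrum-like property* — real k-mer sets are
generated by few long strings, i.e. long unary paths in the de Bruijn graph —
and degrade badly when (k−1)-overlaps are missing: small k, subsampled or
sketched sets, diverse pangenomes, metagenomes.

## The method

A **masked superstring** of *K* is a pair (S, M): a superstring *S*
containing every k-mer of *K* as a substring (in either orientation under the
bidirectional strand model), plus a binary mask *M* with |M| = |S| selecting
which k-mer occurrences are *represented*. Occurrences of alien "ghost"
k-mers created at superstring junctions carry mask 0, so the represented set
is exactly *K*. Because superstrings may exploit overlaps of *any* length —
not only k−1 — this representation unifies and strictly generalizes
spectrum-preserving string sets (SPSS), and stays compact on overlap-poor
sets. `msindex` builds approximately shortest superstrings with the classic
global greedy heuristic (merge by decreasing suffix–prefix overlap, with
deterministic tie-breaking).

The pair is indexed by the **Masked Burrows-Wheeler Transform**: the BWT
image S′ of *S* together with the *SA-transformed mask* M′ defined by
M′[i] = M[j], where *j* is the starting position of the i-th
lexicographically smallest suffix of *S*. Backward search over S′ yields the
suffix-array interval [i, j) of a query k-mer; M′ then validates the
candidate occurrences:

* with a **max-one** mask (every occurrence of a represented k-mer marked),
  all mask bits inside an interval agree, and `member` reads one bit;
* with a **min-one** mask (each represented k-mer marked exactly once, at
  its leftmost occurrence), `lookup` returns
  `ri = rank1(M′, i)` whenever `ri < rank1(M′, j)` — a contiguous, minimal
  and unique hash — and `access` inverts it by a select-driven first-column
  walk of k steps.

The index costs `2|S| + log2 C(|S|, |M|₁) + o(|S|)` bits — at most
(3+o(1))·|S|, and 2+o(1) bits per distinct canonical k-mer when
|S| = |K| + o(|K|). `msindex` reports this accounting analytically
(`space_report`), separating the exact terms from rank/select directory
overhead.

Streamed queries use the **kLCP array** — a bit vector marking adjacent
suffix-array ranks whose suffixes share a prefix of length ≥ k−1. After a
positive k-mer, the interval of the next overlapping k-mer costs one kLCP
extension plus one backward-search step. In the bidirectional model, query
sequences are split into blocks whose likely strand is predicted by a
saturating counter (saturation 7); only positions missed on the predicted
strand are retried on the other.

## Worked example

```python
import msindex as m
from msindex.fixtures import random_genome

genome = random_genome(2000, seed=7)
kset = m.extract_kmer_set([genome], k=21, model="bi")
print("distinct canonical 21-mers:", len(kset))

ms = m.greedy_superstring(kset, policy="min-one")
print("superstring length:", len(ms.S), " mask ones:", ms.popcount())

idx = m.build_index(ms, mode="dict", with_klcp=True)
q = genome[100:121]
h = idx.lookup(q)
print("lookup:", q, "->", h)
print("access:", h, "->", idx.access(h))

rep = idx.space_report(len(kset))
print(f"space: 2|S| = {rep.superstring_bits:.0f} bits, "
      f"mask = {rep.mask_bits:.1f} bits, "
      f"{rep.bits_per_kmer:.3f} bits per k-mer")

memb = m.build_index(m.apply_mask_policy(ms, "max-one"), "memb", with_klcp=True)
res = m.stream_query(memb, genome, op="member")
print(f"streamed {len(res.answers)} k-mers: {sum(res.answers)} present, "
      f"{res.full_searches} full searches, {res.extensions} kLCP extensions")
```

prints

```
distinct canonical 21-mers: 1980
superstring length: 2000  mask ones: 1980
lookup: GCGGAAGCGCAACTCCGTCGC -> 1198
access: 1198 -> GCGACGGAGTTGCGCTTCCGC
space: 2|S| = 4000 bits, mask = 158.1 bits, 2.100 bits per k-mer
streamed 1980 k-mers: 1980 present, 112 full searches, 1957 kLCP extensions
```

The 2000-bp genome contains 1980 distinct canonical 21-mers; greedy merging
rediscovers the generating sequence, so |S| = 2000 — essentially one
character per k-mer, giving 2.1 bits per k-mer of index. `access(1198)`
returns the k-mer in superstring orientation, here the reverse complement of
the query. Streaming answers all 1980 overlapping windows with only 112 full
backward searches; the rest are O(1) kLCP extensions.

A command-line interface mirrors the library
(`msindex index / query / lookup / access / export / fixture`); see
`msindex --help`.

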