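# Methods

## Model and scope

`msindex` represents a finite k-mer set *K* as a masked superstring (S, M)
and indexes it through the Masked Burrows-Wheeler Transform. The package
covers the full pipeline: k-mer extraction under two strand models,
approximately shortest superstring construction, mask optimization, the
transform and its inversion, exact membership and compressed-dictionary
queries, kLCP-accelerated streaming, and analytic space accounting. It does
not attempt physical succinctness (wavelet trees, RRR blocks), dynamic
updates, associated payload arrays, or parallel query execution.

## Strand models and canonicalization

Under the bidirectional model a k-mer and its reverse complement are one
object; the stored representative is the lexicographic minimum of the pair.
The convention is arbitrary but must be fixed: dictionary hashes and all
round-trip guarantees depend on it. Palindromic k-mers (possible only for
even k) canonicalize to themselves; odd k avoids them and is recommended,
but even k is permitted throughout. Windows containing non-ACGT letters are
skipped during extraction (a strict mode rejects instead); lower-case input
is upcased, since case is reserved for mask encoding in the interchange
format.

## Greedy superstring construction

The global greedy heuristic merges strings by decreasing suffix–prefix
overlap length, k−1 down to 1, then concatenates what remains. The
implementation processes one overlap length at a time with hash buckets on
length-d prefixes; each input k-mer is a node with two physical ends, a
merge consumes one end of each partner, and union-find forbids cycles and
self-merges. Under the bidirectional model every node may be placed in
either orientation (consuming both strands at once); a path endpoint exposes
one oriented k-mer per traversal direction, which keeps the candidate space
linear in the set size.

Determinism is part of the contract: at equal overlap, candidate merges are
applied in lexicographic order of (left oriented string, right oriented
string, orientation flags); leftover path strings are lex-canonicalized
(bidirectional: minimum of string and reverse complement) and concatenated
in sorted order. The output always contains every k-mer of *K* and satisfies
|S| ≤ k·|K|; on spectrum-like inputs (a single generating sequence) it
re-discovers the chain, giving |S| ≈ |K| + k − 1.

Masks are produced by a single left-to-right scan over the windows of S
against the represented set: *min-one* marks the leftmost occurrence of each
represented k-mer (popcount = |K|), *max-one* marks every occurrence. The
scan replaces the two-pass min-one→max-one conversion described for earlier
tooling; a test asserts the outputs coincide. The leftmost-occurrence choice
for min-one is itself a convention — any one-per-k-mer mask works — chosen
because it is deterministic and single-pass.

## The transform

The implementation appends one terminal sentinel `$`, smaller than every
base (order $ < A < C < G < T), and a mask bit 0 for it. S′ is the standard
BWT of S+`$`; M′ permutes the extended mask by suffix rank. The
mathematically cleaner cyclic formulation — and the equivalence between
permuting the mask directly and rotating it left by one, gluing it to the
text, and running a BWT keyed on text characters only — is kept as a pair of
reference functions restricted to primitive (aperiodic) strings, where the
cyclic BWT is well defined; tests verify their agreement and the
sentinel-based round-trip `invert ∘ transform = id`.

Suffix arrays are built by numpy prefix doubling (Manber–Myers,
O(n log² n) worst case), adequate for the problem sizes this package
targets (superstrings up to a few hundred kilobases in its test battery); a
naive O(n² log n) sort serves as the test oracle only. Rank over S′ uses a
full cumulative-occurrence table, select uses per-symbol position arrays —
functional contracts, not succinct layouts.

## Queries

Backward search follows the FM-index recurrence
`i ← C(c) + rank_c(S′, i)`, with the sentinel included in the C-counts so no
special-casing is needed, and early exit on interval collapse. Membership on
a max-one mask reads `M′[i]`; the printed one-line form of this operation in
the source literature contains an interval-emptiness typo, and the
implemented condition is (i ≠ j) ∧ M′[i] = 1, consistent with the prose
semantics. Lookup on a min-one mask returns `rank1(M′, i)` when the interval
contains a mark; access selects the h-th mark and walks the first column
with k select steps. With any other mask, membership falls back to the
two-rank test `rank1(M′, i) < rank1(M′, j)`; dictionary queries on
non-min-one masks are refused rather than returning non-contiguous hashes.

In the bidirectional model a k-mer may occur in S on either strand. A failed
strand falls back to the other; for lookup the fallback triggers whenever
the first interval carries no mark, because the single min-one mark lives on
exactly one strand's interval. A signed saturating counter (±7, incremented
on forward hits, decremented on reverse hits) picks which strand to try
first. Earlier implementations describe two separate accumulators; the
single signed counter is simpler and answer-equivalent, and a differential
test forces the predictor through its range to confirm answers never depend
on its state. Hash values are stable for a given index but not canonical
across different superstrings of the same set, since mark placement and
suffix order fix them.

## Streaming

The kLCP array marks adjacent suffix ranks sharing a (k−1)-prefix; it is
built from the suffix array by Kasai's algorithm with LCP values capped at
k−1 (the cap preserves the thresholded bits and keeps the pass linear).
Extension to the (k−1)-prefix interval scans left and right for bounding
zeros — linear scans rather than rank/select over the kLCP bit vector, which
is cheap because extensions are local; the scan-based and brute-force
intervals are compared in tests.

Streams are traversed right to left (backward search extends patterns on the
left); answers are re-ordered to text order. A k-mer found in the
superstring chains to its predecessor in O(1); a miss breaks the chain and
the next window pays a full O(k) search. Non-ACGT windows answer
negative and break the chain. In the bidirectional model the text is split
into blocks of B positions, default B = max(k, ⌊2·√|T|⌋): the literature's
printed block width is dimensionally inconsistent, and this default matches
the √-flavored block size its analysis actually uses, while remaining
configurable because correctness is B-independent (only telemetry varies —
an invariance the tests assert). Each block is streamed on the predicted
strand; positions it missed are retried on the other strand, in runs so
consecutive misses still chain. On a fully positive unidirectional stream
the telemetry reports exactly one full backward search; on strand-consistent
bidirectional text the full-search count stays within one per block plus one
per negative window.

## Space accounting

`space_report` returns the analytic bound: 2 bits per superstring character
for S′, plus the zeroth-order mask entropy log₂ C(|S|, |M|₁) computed via
log-gamma (exact for small n, overflow-free for gigabase n). The o(|S|)
rank/select directory term is implementation-defined and reported in a
separate `overhead_bits` field (modelled as 32-bit counters per 64-position
block, per symbol), never folded into the bound; the kLCP vector, when
built, adds one bit per character and is likewise reported separately. The
total satisfies ≤ 3 bits per character for every mask, and approaches 2 bits
per distinct canonical k-mer when |S| approaches |K|.

## Synthetic data

The fixture generator emulates the regimes that differentiate k-mer
indexes: `random_genome` (one generating string; nearly all (k−1)-overlaps
present — the spectrum-like easy case), `pangenome` (g mutants of a base
genome with i.i.d. substitutions at rate μ; polymorphism fragments the de
Bruijn graph), `random_kmers` (uniform k-mers; essentially overlap-free,
the worst case for (k−1)-overlap methods), and `subsampled` (uniform
thinning, Bernoulli by default, exact hypergeometric optionally). The
standard battery spans k ∈ {5, 7, 11, 15, 31}, both strand models, genomes
up to 30 kb, pangenomes up to 8 × 6 kb, random sets up to 3000 k-mers, and
10 % subsampled variants — sizes chosen so the full battery builds and
queries in tens of seconds on one CPU while covering every regime; the
compactness check uses a single 50-kb genome at k = 31.

What the generator does not emulate: sequencing errors and coverage
(k-mer-frequency) structure, repeat families, GC bias, and real pangenomic
linkage. Passing tests therefore demonstrate correctness of the data
structure and its contracts on structurally diverse sets, not performance
claims on real data.

## Numerical and degenerate-input choices

The empty k-mer set yields the empty superstring, whose index is the
sentinel-only transform answering false/−1 to everything. Queries of wrong
length, hashes out of range, malformed transforms (zero or multiple
sentinels), mask/mode mismatches without the general-mask opt-in, and
invalid parameters all raise typed errors rather than returning sentinel
values. Coordinates are 0-based half-open everywhere. Serialization stores
only the case-encoded masked superstring plus metadata and rebuilds derived
structures deterministically on load; archives are versioned and
length-checked so truncation is detected.

## Known limitations

Rank tables are O(n·σ) integers, not succinct — by design, since space is
accounted analytically; physically compact storage would change constants
but no contract. Greedy construction is quadratic in pathological bucket
collisions (though linear-ish in practice) and is not parallelized. The
suffix-array sort is not the linear-time state of the art and would be the
first bottleneck beyond tens of megabases. Frequency filtering of noisy
read sets is out of scope beyond pre-filtering the input k-mer iterator;
the index itself is frequency-agnostic.
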