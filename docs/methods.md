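# Methods

## Problem and data model

Given a set S of n distinct k-mers over {A,C,G,T}, presented as a
*path cover* of the de Bruijn graph of S (a set of p strings, each of
length >= k, that together spell every k-mer exactly once, identifying
a k-mer with its reverse complement — e.g. unitigs or stitched
unitigs/simplitigs produced by standard dBG tools), `minidex` builds a
static dictionary supporting:

* **Lookup(g)** — the unique identifier of g in [0, n), or -1;
* **Access(i)** — the k-mer string with identifier i;
* **streaming queries** — Lookup for every consecutive window of a
  pattern, sharing state between windows.

The dictionary is *exact* (no false positives and no false negatives)
and *associative* (the id is stable and invertible), and its space is
dominated by the 2-bit encoding of the input strings themselves: the
k-1 base overlap between consecutive k-mers is stored once, not per
k-mer.

## Layout

The cover is concatenated into `Strings` (2N bits for N bases) with the
cumulative string lengths in `Endpoints` (Elias–Fano). Each string is
parsed into *super-k-mers*: maximal runs of consecutive k-mers sharing
a minimizer, additionally capped at k-m+1 k-mers (see below). The z
super-k-mers are grouped into buckets by minimizer. An MPHF f over the
M distinct minimizers fixes the bucket order; bucket sizes are stored
as Elias–Fano prefix sums `Sizes` (length M+1), and the super-k-mer
start positions as ceil(log2 N)-bit absolute offsets in `Offsets`,
ascending within each bucket. n = N - p(k-1) always.

Lookup computes the minimizer r of g, retrieves the bucket
Offsets[Sizes[f(r)], Sizes[f(r)+1]), and scans each candidate
super-k-mer, comparing at most k-m+1 windows against g (windows may run
past the super-k-mer's nominal end but never past the string end; any
verified match at a valid window is correct because the id is derived
from the absolute position: id = t + w - j(k-1), where j is the index
of the containing string). Because f maps *any* m-mer into a bucket,
a query whose minimizer is not in M is recognized by comparing r with
the minimizer of the bucket's first k-mer before scanning.

**Double strandedness.** In *regular* modality the minimizer is taken
on the forward spelling only; Lookup searches g's bucket and, only if
absent, the bucket of revcomp(g) — up to two buckets per negative
query. In *canonical* modality the minimizer is the minimum over both
strands' m-mers, so g and revcomp(g) share one bucket and one scan
(comparing both orientations) suffices; the price is more distinct
minimizers, hence a slightly larger index.

## Minimizer scheme

The order on m-mers is induced by a splitmix64-style mixer of the
2-bit-packed m-mer XOR a mixed seed; the seed is stored in the index
header so query-time parsing is identical to build-time parsing on any
platform. Ties (identical 64-bit hash values — negligible in practice)
break to the leftmost window position, and to the forward strand in
canonical modality; both rules exist purely for determinism.

On uniform-random sequence, random-order minimizers select about
2/(w+1) of positions with w = k-m+1 candidate positions per window,
i.e. (k-m+2)/2 times fewer super-k-mers than k-mers; for k=31, m=20
that ratio is 6.5, which the density test and the acceptance script
measure within 5%.

**Run cap.** A super-k-mer run is closed after k-m+1 k-mers even when
the minimizer persists (possible when the minimizer m-mer recurs at
several window positions). Capping at parse time makes the parse
windows and the query-time scan windows coincide, so a bucket scan can
safely stop after k-m+1 windows per candidate. Uncapped runs longer
than k-m+1 require the same m-mer to appear twice in one window and are
rare outside engineered repeats; the cap then costs a handful of extra
super-k-mers and nothing in correctness.

## Succinct primitives

* **Elias–Fano** sequences store low halves of width
  floor(log2((U+1)/n)) plus a unary high vector; payload is asserted at
  build time to stay within n ceil(log2(U/n)) + 2n bits. Select over
  the high bits is kept as an explicit position array and accounted as
  overhead separate from the payload; successor queries binary-search
  over access.
* **Compact vectors** pack fixed-width integers in 64-bit words
  (Offsets; the skew-index value vectors).
* **MPHF**: a multi-level fingerprint construction (gamma = 1): at each
  level the still-unplaced keys hash into a bit array of their own
  cardinality; keys landing alone are placed, the rest recurse, and a
  handful of stragglers end in a sorted fallback array. Evaluation
  returns the rank of the hit bit; non-keys legitimately receive
  arbitrary in-range values, which is safe because every candidate the
  dictionary derives from an MPHF value is verified against `Strings`.
  Measured cost is ~2.8–3.3 bits/key (budgeted at <= 4); the
  construction is deterministic given the header seed.

## Skew index

Bucket sizes are heavily skewed: most minimizers label one super-k-mer,
few label very many. Buckets of size s <= 2^ell are simply scanned
(<= 2^ell candidates). For larger buckets, k-mers are partitioned by
size class (2^i < s <= 2^(i+1) for ell <= i < L; (2^L, max] for the
last class); each class gets its own MPHF f_i over its k-mers and a
compact vector V_i whose entry at f_i(g) is the index q of g's
super-k-mer within its bucket — i+1 bits per entry, ceil(log2 max) in
the top class. A heavy-bucket lookup therefore inspects exactly one
candidate (q >= bucket size already proves absence). When
max < 2^L, classes above ceil(log2 max) - 1 are simply omitted and the
top occupied class uses ceil(log2 max)-bit entries.

Skew keys are canonical (strand-minimum) packed k-mers so both
orientations of a query retrieve the same entry; for k > 32 a 64-bit
fingerprint of the canonical spelling is used instead, and a
fingerprint collision can only add a candidate that the verifying scan
rejects. Defaults ell=6, L=12; the heavy-bucket test fixtures use
ell=2, L=5 with m=4 so that desk-scale covers exceed the threshold.

## Streaming queries

For consecutive windows the streamer caches, per searched strand, the
last minimizer, whether it is in M, and its bucket; and the absolute
position plus orientation of the last match. When the minimizer
repeats: if it was unknown, the window is absent with no work; if the
previous window matched, the match is first *extended* by one position
(rightward after a forward match, leftward after a reverse-complement
match — the backward direction is what prevents re-scanning the bucket
once per window, i.e. quadratically many comparisons, on
reverse-complemented patterns). Every fast path re-verifies the k-mer
against `Strings` and the endpoints before acceptance, so streaming is
observationally identical to per-window Lookup; the test suite asserts
this window by window, and checks with instrumentation counters that
scan work grows linearly in pattern length. On a miss the match
position is dropped but the minimizer/bucket cache is kept. The state
is a fixed set of scalars, independent of pattern length. A failed
extension falls back to the cached bucket scan without trying the
opposite direction (one directional attempt per cached orientation).

## Synthetic data

The generator emulates exactly the properties the dictionary depends
on, and nothing more: uniform-random strings of configurable number and
length, with rejection-regeneration to guarantee no duplicate canonical
k-mers (the path-cover contract); query workloads with a controlled hit
rate (high-hit: ~90% of patterns are cover substrings, half
reverse-complemented, giving >= 70% stored windows; low-hit: random
patterns, < 1% stored); and a heavy-bucket knob that implants the
m-mers with globally minimal hash under the scheme seed — any window
containing one necessarily adopts it as minimizer, so spaced implants
drive one bucket's size past 2^ell deterministically. Uniform sequence
reproduces the minimizer-density regime but none of the repeat
structure, long homopolymers, or base-composition bias of real genomes,
so passing tests demonstrate algorithmic correctness and the expected
*statistical* behavior, not genome-scale space/time figures. Covers and
query workloads salt their PRNG seed sequences differently so that
equal user seeds never yield correlated base streams.

## Numerical and degenerate-input choices

* Alphabet fixed to A=0, C=1, G=2, T=3 so complement = XOR 3.
* Non-ACGT bases are a hard error in cover strings, but in query
  patterns every window touching one reports -1 and resets the
  streaming state.
* k in [2, 63] (k <= 32 uses single-word packed keys throughout);
  m in [1, min(k, 32)]; default m = ceil(log4 N) + 1.
* Coordinates are 0-based half-open; offsets absolute in [0, N).
* Duplicate-k-mer verification at build is optional (`verify_distinct`)
  since cover generators already guarantee it.
* Empty skew partitions are zero-length stubs; the index file layout is
  fixed and byte-deterministic (save -> load -> save is the identity).

## Problem sizes used by the test suite

Bijection/exactness suites run on 20 seeded covers of 4–8 strings of
60–350 bases (hundreds to a few thousand k-mers each, both modalities,
exhaustive positive checks and >= 2x10^5 negatives in total); the
density law is measured on 10^6 uniform bases. These sizes exercise
every code path (including heavy buckets via the implant knob) while
keeping the pure-Python query loop comfortably fast.

## Known limitations

* The dictionary is static: no insertions, deletions, abundances or
  colors.
* Lookup is a few orders of magnitude slower than a tuned native
  implementation of the same structure; the point of this package is
  the data structure's correctness, space accounting and observable
  behavior, not wall-clock competitiveness.
* Space accounting reports the succinct payloads; Python object
  overhead and the explicit select/rank directories are reported
  separately and excluded from the bits/k-mer figures.
* m is limited to 32 (single 64-bit word per m-mer).
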