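# minidex

An exact, associative, compressed dictionary for k-mer sets, for
bioinformaticians who need fast membership and identifier queries over
the k-mer spectrum of a genome or pan-genome.

Given the n distinct k-mers of a sequence collection presented as a
**path cover** of its de Bruijn graph (unitigs or stitched
unitigs/simplitigs: p strings that together contain every k-mer exactly
once, a k-mer being identified with its reverse complement), `minidex`
builds a static index supporting:

* `Lookup(g)` — a unique id in [0, n) if the k-mer g (or its reverse
  complement) is stored, else −1 — never a false positive;
* `Access(i)` — the k-mer spelled by identifier i;
* streaming membership over every consecutive window of a pattern
  (FASTA/FASTQ), with state shared between overlapping windows.

## The data structure

The cover strings are stored once, 2-bit packed (`Strings`, 2N bits,
with string `Endpoints` in an Elias–Fano sequence). Each string is
parsed into *super-k-mers* — maximal runs of consecutive k-mers sharing
the same **minimizer**, the m-mer minimizing a seeded 64-bit hash
order. A minimal perfect hash function f over the M distinct minimizers
indexes the buckets: prefix-summed bucket `Sizes` (Elias–Fano) and
absolute super-k-mer `Offsets` (⌈log2 N⌉ bits each). Lookup hashes the
query's minimizer r, scans the ≤ k−m+1 windows of each super-k-mer in
bucket B_r against `Strings`, and returns

    id = t + w − j(k−1)

for a match at window w of the super-k-mer at offset t inside string j:
the global rank of the k-mer among all valid windows, so ids are a
bijection onto [0, n) and `Access` inverts them by binary search on the
endpoints. Heavy buckets (size > 2^ℓ) are answered through a **skew
index**: per size class, an MPHF over the class's k-mers plus a compact
vector giving each k-mer's super-k-mer directly, so worst-case lookup
work is bounded. A *canonical* parsing modality takes the minimizer as
the minimum over both strands so that one bucket serves both
orientations; the *regular* modality is smaller but may inspect two
buckets per negative query.

## Worked example

```python
import minidex as mx

cover = mx.gen_cover(mx.FixtureSpec(seed=1, p=4, min_len=90, max_len=140, k=31))
d = mx.Dictionary.build(cover, mx.DictConfig(k=31, m=8, canonical=True))

g = cover[2][10:41]                    # a stored 31-mer
res = d.lookup(g)
print(res.id, res.orientation)         # 170 forward
print(d.lookup(mx.revcomp(g)).id)      # 170  (same id on both strands)
print(d.access(res.id) == g)           # True
print(mx.compute_stats(d).summary())
```

prints

```
170 forward
170
True
k=31 m=8 modality=canonical ell=6 L=12
n=306 k-mers, p=4 strings, N=426 bases
z=33 super-k-mers, M=33 minimizers, max bucket=1
total 1449 bits = 4.735 bits/k-mer
(split-by-super-k-mer layout would cost at least 8.47 bits/k-mer)
```

Here the 4 cover strings hold n = N − p(k−1) = 426 − 4·30 = 306
k-mers in z = 33 super-k-mers under M = 33 distinct minimizers; the
match for `g` was found at window w = 9 of a super-k-mer at offset
t = 221 in string j = 2, giving id 221 + 9 − 60 = 170. The final lines
are the space report: the measured bits per k-mer of this toy index and
the cost floor of the alternative layout that would duplicate each
super-k-mer's k−1 tail bases.

The same flows are scriptable from a shell:

```
minidex fixtures cover --seed 4 -p 5 -o cover.fa
minidex build cover.fa -k 31 --canonical -o cover.sshx
minidex fixtures queries cover.fa --workload high_hit --seed 8 -o reads.fa
minidex query cover.sshx reads.fa            # per-read TSV + aggregate
minidex stats cover.sshx                     # space accounting report
```

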