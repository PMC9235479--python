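"""Space accounting and bucket-size statistics for a built dictionary.

Component payloads follow the layout costs: 2N bits for the packed
strings, the Elias-Fano payloads for Endpoints and the prefix-summed
Sizes, z * ceil(log2 N) bits for Offsets, the MPHF payload for the
minimizer function, and per-partition (MPHF + compact vector) bits for
the skew index.  For comparison the report also prints the cost floor
of the alternative layout that partitions the strings by super-k-mer,
2 + 2z(k-1)/n bits per k-mer: each super-k-mer would then pay 2(k-1)
bits for its own copy of the k-1 overlapping tail bases.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass




def alternative_layout_bits_per_kmer(z: int, n: int, k: int) -> float:
    """Lower bound of the split-by-super-k-mer layout: 2 + 2z(k-1)/n."""
    return 2.0 + 2.0 * z * (k - 1) / n


def heavy_bucket_fraction_pct(size_pct: dict[int, float], ell: int) -> float:
    """Percentage of buckets of size > 2^ell, from a size histogram in %.

    ``size_pct`` maps bucket size -> percentage of buckets (percentages
    assumed to cover all sizes <= 2^ell; the remainder is heavy).
    """
    small = sum(pct for size, pct in size_pct.items() if size <= (1 << ell))
    return round(100.0 - small, 10)


@dataclass
class StatsReport:
    """Per-component space report plus the bucket-size histogram."""

    n: int
    p: int
    N: int
    z: int
    M: int
    max_bucket: int
    k: int
    m: int
    canonical: bool
    ell: int
    L: int
    component_bits: dict[str, int]
    skew_partition_bits: dict[int, tuple[int, int]]
    size_histogram_pct: dict[int, float]

    @property
    def total_bits(self) -> int:
        return sum(self.component_bits.values())

    @property
    def bits_per_kmer(self) -> float:
        return self.total_bits / self.n

    @property
    def alternative_bits_per_kmer(self) -> float:
        return alternative_layout_bits_per_kmer(self.z, self.n, self.k)

    def to_tsv(self) -> str:
        lines = ["component\tbits\tbits_per_kmer"]
        for name, bits in self.component_bits.items():
            lines.append(f"{name}\t{bits}\t{bits / self.n:.4f}")
        lines.append(f"total\t{self.total_bits}\t{self.bits_per_kmer:.4f}")
        lines.append("")
        lines.append("bucket_size\tpercent_of_buckets")
        for size in sorted(self.size_histogram_pct):
            lines.append(f"{size}\t{self.size_histogram_pct[size]:.4f}")
        return "\n".join(lines)

    def summary(self) -> str:
        mode = "canonical" if self.canonical else "regular"
        out = [
            f"k={self.k} m={self.m} modality={mode} ell={self.ell} L={self.L}",
            f"n={self.n} k-mers, p={self.p} strings, N={self.N} bases",
            f"z={self.z} super-k-mers, M={self.M} minimizers, "
            f"max bucket={self.max_bucket}",
            f"total {self.total_bits} bits = {self.bits_per_kmer:.3f} bits/k-mer",
            f"(split-by-super-k-mer layout would cost at least "
            f"{self.alternative_bits_per_kmer:.2f} bits/k-mer)",
        ]
        return "\n".join(out)


def compute_stats(d) -> StatsReport:
    """Measure every component of a built :class:`Dictionary`."""
    comp = {
        "strings": d.strings.nbits,
        "endpoints": d.endpoints_ef.payload_bits,
        "minimizer_mphf": d.minimizer_mphf.payload_bits,
        "sizes": d.sizes.payload_bits,
        "offsets": d.offsets.nbits,
        "skew_index": d.skew.payload_bits,
    }
    sizes = d.bucket_sizes()
    hist = Counter(int(s) for s in sizes)
    total = len(sizes)
    size_pct = {s: 100.0 * c / total for s, c in sorted(hist.items())}
    return StatsReport(
        n=d.n, p=d.p, N=d.N, z=d.z, M=d.M, max_bucket=d.max_bucket,
        k=d.k, m=d.config.m, canonical=d.config.canonical,
        ell=d.config.ell, L=d.config.L,
        component_bits=comp,
        skew_partition_bits=d.skew.partition_bits(),
        size_histogram_pct=size_pct,
    )
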