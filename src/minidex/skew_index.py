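"""Skew index: bounded worst-case lookup for heavy minimizer buckets.

The distribution of bucket sizes (super-k-mers per minimizer) is heavily
skewed: most buckets hold a single super-k-mer, a few hold very many.
Scanning a heavy bucket would make lookup cost unbounded, so every k-mer
living in a bucket of size s > 2^l is keyed into a per-size-class MPHF
f_i together with a compact vector V_i storing, at position f_i(g), the
index q of the super-k-mer of its bucket that contains g.  Size classes
are 2^i < s <= 2^(i+1) for l <= i < L and (2^L, max] for the last one;
an entry of partition i needs i+1 bits (the last one ceil(log2 max)).
A lookup in a heavy bucket then inspects exactly one candidate
super-k-mer; V_i is arbitrary on non-keys, so the candidate is always
verified against the stored strings (and q >= bucket size proves
absence outright).

Keys are canonical (strand-minimum) packed k-mers, so either orientation
of a query retrieves the same entry.
"""

from __future__ import annotations

import math
import struct

import numpy as np

from .bits import CompactVector
from .minimizers import mix64
from .mphf import Mphf

SMALL = -1  #: sentinel returned by partition_of for small buckets


def n_size_classes(ell: int, L: int) -> int:
    """Number of size classes between the threshold and the cap: L - l + 1."""
    if not 0 <= ell < L:
        raise ValueError("need 0 <= ell < L")
    return L - ell + 1


def partition_of(s: int, ell: int, L: int) -> int:
    """Size-class of a bucket of size s, or SMALL when ceil(log2 s) <= l."""
    if s < 1:
        raise ValueError("bucket size must be >= 1")
    b = math.ceil(math.log2(s)) if s > 1 else 0
    if b <= ell:
        return SMALL
    return min(b - 1, L)


def partition_width(i: int, ell: int, L: int, max_bucket: int) -> int:
    """Bits per entry of partition i: i+1, except ceil(log2 max) for the
    top occupied partition."""
    top = SkewIndex._top_partition(ell, L, max_bucket)
    return SkewIndex._width_of(i, top, max_bucket)


class SkewIndex:
    """Per-partition (Mphf, CompactVector) pairs over heavy-bucket k-mers."""

    def __init__(self, ell: int, L: int, max_bucket: int,
                 partitions: dict[int, tuple[Mphf, CompactVector]]):
        self.ell = ell
        self.L = L
        self.max_bucket = max_bucket
        self.partitions = partitions

    @classmethod
    def build(cls, heavy_buckets, ell: int, L: int, max_bucket: int,
              seed: int = 0) -> "SkewIndex":
        """Build from ``heavy_buckets``: iterable of (size, [(key, q), ...]).

        ``q`` is the index of the containing super-k-mer within its own
        bucket.  Buckets of size <= 2^l must not be passed.
        """
        per_part: dict[int, tuple[list[int], list[int]]] = {}
        for size, pairs in heavy_buckets:
            i = partition_of(size, ell, L)
            if i == SMALL:
                raise ValueError(f"bucket of size {size} is small, not skew-indexed")
            keys, vals = per_part.setdefault(i, ([], []))
            for key, q in pairs:
                keys.append(key)
                vals.append(q)
        top = cls._top_partition(ell, L, max_bucket)
        partitions: dict[int, tuple[Mphf, CompactVector]] = {}
        for i, (keys, vals) in sorted(per_part.items()):
            width = cls._width_of(i, top, max_bucket)
            f = Mphf.build(np.asarray(keys, dtype=np.uint64),
                           seed=mix64(seed ^ (0xC2B2AE3D27D4EB4F + i)))
            v = np.zeros(len(keys), dtype=np.uint64)
            for key, q in zip(keys, vals):
                v[f(key)] = q
            partitions[i] = (f, CompactVector.from_values(v, width))
        return cls(ell, L, max_bucket, partitions)

    @staticmethod
    def _top_partition(ell: int, L: int, max_bucket: int) -> int:
        """Highest occupied partition index.

        When max < 2^L, partitions above ceil(log2 max) - 1 are omitted
        and the top one stores ceil(log2 max)-bit entries.
        """
        if max_bucket <= (1 << ell):
            return ell  # degenerate: no heavy buckets at all
        return min(L, max(ell, math.ceil(math.log2(max_bucket)) - 1))

    @classmethod
    def _width_of(cls, i: int, top: int, max_bucket: int) -> int:
        if i >= top:
            return max(1, math.ceil(math.log2(max_bucket)))
        return i + 1

    # -- queries -----------------------------------------------------------
    def lookup(self, key: int, bucket_size: int) -> int | None:
        """Candidate super-k-mer index q for a k-mer with canonical ``key``.

        Returns None when the size class has no partition (cannot happen
        for sizes realized by the index; callers then fall back to a
        scan).  A returned q >= bucket_size certifies absence.
        """
        i = partition_of(bucket_size, self.ell, self.L)
        if i == SMALL:
            raise ValueError("small buckets are scanned, not skew-looked-up")
        part = self.partitions.get(i)
        if part is None:
            return None
        f, v = part
        return v[f(key)]

    # -- accounting --------------------------------------------------------
    @property
    def n_partitions(self) -> int:
        return len(self.partitions)

    @property
    def payload_bits(self) -> int:
        return sum(f.payload_bits + v.nbits for f, v in self.partitions.values())

    def partition_bits(self) -> dict[int, tuple[int, int]]:
        """Per partition: (mphf bits, vector bits)."""
        return {i: (f.payload_bits, v.nbits) for i, (f, v) in self.partitions.items()}

    # -- serialization -----------------------------------------------------
    def to_bytes(self) -> bytes:
        parts = [struct.pack("<QQQQ", self.ell, self.L, self.max_bucket,
                             len(self.partitions))]
        for i in sorted(self.partitions):
            f, v = self.partitions[i]
            parts.append(struct.pack("<Q", i))
            parts.append(f.to_bytes())
            parts.append(v.to_bytes())
        return b"".join(parts)

    @classmethod
    def from_buffer(cls, buf: memoryview, off: int) -> tuple["SkewIndex", int]:
        ell, L, max_bucket, n_parts = struct.unpack_from("<QQQQ", buf, off)
        off += 32
        partitions: dict[int, tuple[Mphf, CompactVector]] = {}
        for _ in range(n_parts):
            (i,) = struct.unpack_from("<Q", buf, off)
            off += 8
            f, off = Mphf.from_buffer(buf, off)
            v, off = CompactVector.from_buffer(buf, off)
            partitions[i] = (f, v)
        return cls(ell, L, max_bucket, partitions), off
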