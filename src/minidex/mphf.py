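"""Minimal perfect hashing over static sets of 64-bit keys.

A multi-level fingerprint construction: at each level every still-unplaced
key hashes into a bit array of size ~gamma * (#remaining); keys that land
alone get the bit set and are placed, colliding keys proceed to the next
level.  Evaluation walks the levels until a set bit is hit and returns
the rank of that bit across all levels.  A handful of stragglers after
the last level are kept in a sorted fallback array.  On the build keys
the function is a bijection onto [0, n); on any other input it returns
an arbitrary in-range value (never an error) -- exactly the contract the
dictionary needs, since every candidate it produces is verified against
the stored strings.

With gamma = 1 the expected payload is about 2.8 bits per key.
"""

from __future__ import annotations

import struct

import numpy as np

from .bits import BitVector
from .errors import DuplicateKeyError
from .minimizers import mix64, mix64_np

_MAX_LEVELS = 28
_GAMMA = 1.0


def _level_seed(master_seed: int, level: int) -> int:
    return mix64(master_seed ^ (0xA076_1D64_78BD_642F + level * 0x9DDF_EA08_EB38_2D69))


class Mphf:
    """Minimal perfect hash function f: keys -> {0, ..., n_keys-1}."""

    def __init__(self, n_keys, seed, levels, level_offsets, fallback_keys, fallback_ranks):
        self.n_keys = n_keys
        self.seed = seed
        self.levels: list[BitVector] = levels
        # rank of the first bit of each level in the concatenated order
        self.level_offsets: list[int] = level_offsets
        self.fallback_keys = np.ascontiguousarray(fallback_keys, dtype=np.uint64)
        self.fallback_ranks = np.ascontiguousarray(fallback_ranks, dtype=np.int64)
        self._rank_dirs = [bv.popcounts() for bv in levels]

    # -- construction ------------------------------------------------------
    @classmethod
    def build(cls, keys, seed: int = 0) -> "Mphf":
        keys = np.asarray(keys, dtype=np.uint64)
        if keys.size == 0:
            raise ValueError("key set must be non-empty")
        if len(np.unique(keys)) != len(keys):
            raise DuplicateKeyError("duplicate keys in MPHF construction")
        n = len(keys)
        remaining = keys
        levels: list[BitVector] = []
        level_offsets: list[int] = []
        rank = 0
        for t in range(_MAX_LEVELS):
            if remaining.size == 0:
                break
            size = max(64, int(_GAMMA * len(remaining) + 63) // 64 * 64)
            pos = (mix64_np(remaining ^ np.uint64(_level_seed(seed, t)))
                   % np.uint64(size)).astype(np.int64)
            counts = np.bincount(pos, minlength=size)
            alone = counts[pos] == 1
            bv = BitVector.from_positions(pos[alone], size)
            levels.append(bv)
            level_offsets.append(rank)
            rank += int(alone.sum())
            remaining = remaining[~alone]
        fallback_keys = np.sort(remaining)
        fallback_ranks = np.arange(rank, rank + len(remaining), dtype=np.int64)
        return cls(n, seed, levels, level_offsets, fallback_keys, fallback_ranks)

    # -- evaluation --------------------------------------------------------
    def __call__(self, x: int) -> int:
        """Evaluate on any 64-bit input; in [0, n_keys) always."""
        x &= (1 << 64) - 1
        for t, bv in enumerate(self.levels):
            pos = mix64(x ^ _level_seed(self.seed, t)) % bv.n_bits
            wi, sh = pos >> 6, pos & 63
            word = int(bv.words[wi])
            if (word >> sh) & 1:
                dir_ = self._rank_dirs[t]
                below = word & ((1 << sh) - 1)
                return self.level_offsets[t] + int(dir_[wi]) + below.bit_count()
        if self.fallback_keys.size:
            i = int(np.searchsorted(self.fallback_keys, np.uint64(x)))
            if i < len(self.fallback_keys) and self.fallback_keys[i] == np.uint64(x):
                return int(self.fallback_ranks[i])
        return mix64(x ^ 0x5851F42D4C957F2D) % self.n_keys  # non-key: arbitrary

    def eval_array(self, xs: np.ndarray) -> np.ndarray:
        return np.fromiter((self(int(x)) for x in xs), dtype=np.int64, count=len(xs))

    # -- space accounting --------------------------------------------------
    @property
    def payload_bits(self) -> int:
        """Level bit arrays plus fallback entries (key + rank)."""
        bits = sum(bv.n_bits for bv in self.levels)
        return bits + 128 * len(self.fallback_keys)

    @property
    def bits_per_key(self) -> float:
        return self.payload_bits / self.n_keys

    # -- serialization -----------------------------------------------------
    def to_bytes(self) -> bytes:
        parts = [struct.pack("<QQQQ", self.n_keys, self.seed,
                             len(self.levels), len(self.fallback_keys))]
        for bv, off in zip(self.levels, self.level_offsets):
            parts.append(struct.pack("<Q", off))
            parts.append(bv.to_bytes())
        parts.append(self.fallback_keys.astype("<u8").tobytes())
        parts.append(self.fallback_ranks.astype("<i8").tobytes())
        return b"".join(parts)

    @classmethod
    def from_buffer(cls, buf: memoryview, off: int) -> tuple["Mphf", int]:
        n_keys, seed, n_levels, n_fb = struct.unpack_from("<QQQQ", buf, off)
        off += 32
        levels, level_offsets = [], []
        for _ in range(n_levels):
            (lo,) = struct.unpack_from("<Q", buf, off)
            off += 8
            bv, off = BitVector.from_buffer(buf, off)
            levels.append(bv)
            level_offsets.append(lo)
        fb_keys = np.frombuffer(buf, dtype="<u8", count=n_fb, offset=off).copy()
        off += 8 * n_fb
        fb_ranks = np.frombuffer(buf, dtype="<i8", count=n_fb, offset=off).copy()
        off += 8 * n_fb
        return cls(n_keys, seed, levels, level_offsets, fb_keys, fb_ranks), off
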