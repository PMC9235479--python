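"""Fixed-width bit packing on 64-bit words.

Backs the Offsets array and the skew-index value vectors.  Only what the
dictionary needs: build from an integer array, random access, bulk
decode, byte serialization.
"""

from __future__ import annotations

import struct

import numpy as np

_W = np.uint64(64)


class CompactVector:
    """n integers of a fixed width (1..64 bits) packed into uint64 words."""

    def __init__(self, words: np.ndarray, n: int, width: int):
        self.words = np.ascontiguousarray(words, dtype=np.uint64)
        self.n = n
        self.width = width

    @classmethod
    def from_values(cls, values, width: int) -> "CompactVector":
        if not 1 <= width <= 64:
            raise ValueError("width must be in [1, 64]")
        vals = np.asarray(values, dtype=np.uint64)
        if vals.size and width < 64 and int(vals.max()) >> width:
            raise ValueError(f"value does not fit in {width} bits")
        n = len(vals)
        n_words = (n * width + 63) // 64 + 1  # +1 spare word for overhang reads
        words = np.zeros(n_words, dtype=np.uint64)
        if n:
            bitpos = np.arange(n, dtype=np.uint64) * np.uint64(width)
            wi = (bitpos >> np.uint64(6)).astype(np.int64)
            sh = bitpos & np.uint64(63)
            np.bitwise_or.at(words, wi, vals << sh)
            spill = (sh + np.uint64(width)) > _W
            if spill.any():
                hi = vals[spill] >> (_W - sh[spill])
                np.bitwise_or.at(words, wi[spill] + 1, hi)
        return cls(words, n, width)

    def __len__(self) -> int:
        return self.n

    def __getitem__(self, i: int) -> int:
        if not 0 <= i < self.n:
            raise IndexError(i)
        w = self.width
        bitpos = i * w
        wi, sh = bitpos >> 6, bitpos & 63
        v = int(self.words[wi]) >> sh
        if sh + w > 64:
            v |= int(self.words[wi + 1]) << (64 - sh)
        return v & ((1 << w) - 1) if w < 64 else v & ((1 << 64) - 1)

    def to_array(self) -> np.ndarray:
        if self.n == 0:
            return np.empty(0, dtype=np.uint64)
        w = np.uint64(self.width)
        bitpos = np.arange(self.n, dtype=np.uint64) * w
        wi = (bitpos >> np.uint64(6)).astype(np.int64)
        sh = bitpos & np.uint64(63)
        lo = self.words[wi] >> sh
        overhang = np.where(sh > 0, _W - sh, np.uint64(0))
        hi = np.where(sh > 0, self.words[wi + 1], np.uint64(0)) << overhang
        v = lo | np.where((sh + w) > _W, hi, np.uint64(0))
        if self.width < 64:
            v &= np.uint64((1 << self.width) - 1)
        return v

    @property
    def nbits(self) -> int:
        """Payload size: n * width bits."""
        return self.n * self.width

    # -- serialization -----------------------------------------------------
    def to_bytes(self) -> bytes:
        head = struct.pack("<QQQ", self.n, self.width, len(self.words))
        return head + self.words.tobytes()

    @classmethod
    def from_buffer(cls, buf: memoryview, off: int) -> tuple["CompactVector", int]:
        n, width, n_words = struct.unpack_from("<QQQ", buf, off)
        off += 24
        words = np.frombuffer(buf, dtype="<u8", count=n_words, offset=off).copy()
        off += 8 * n_words
        return cls(words, n, width), off


class BitVector:
    """Plain bit vector with vectorized construction; used by the MPHF."""

    def __init__(self, words: np.ndarray, n_bits: int):
        self.words = np.ascontiguousarray(words, dtype=np.uint64)
        self.n_bits = n_bits

    @classmethod
    def zeros(cls, n_bits: int) -> "BitVector":
        return cls(np.zeros((n_bits + 63) // 64, dtype=np.uint64), n_bits)

    @classmethod
    def from_positions(cls, positions: np.ndarray, n_bits: int) -> "BitVector":
        bv = cls.zeros(n_bits)
        pos = np.asarray(positions, dtype=np.int64)
        np.bitwise_or.at(
            bv.words, pos >> 6, np.uint64(1) << (pos.astype(np.uint64) & np.uint64(63))
        )
        return bv

    def get(self, i: int) -> int:
        return (int(self.words[i >> 6]) >> (i & 63)) & 1

    def popcounts(self) -> np.ndarray:
        """Cumulative set-bit count *before* each word (rank directory)."""
        cnt = np.bitwise_count(self.words).astype(np.int64)
        out = np.zeros(len(cnt) + 1, dtype=np.int64)
        np.cumsum(cnt, out=out[1:])
        return out

    def to_bytes(self) -> bytes:
        head = struct.pack("<QQ", self.n_bits, len(self.words))
        return head + self.words.tobytes()

    @classmethod
    def from_buffer(cls, buf: memoryview, off: int) -> tuple["BitVector", int]:
        n_bits, n_words = struct.unpack_from("<QQ", buf, off)
        off += 16
        words = np.frombuffer(buf, dtype="<u8", count=n_words, offset=off).copy()
        off += 8 * n_words
        return cls(words, n_bits), off
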