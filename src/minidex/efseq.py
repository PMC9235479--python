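"""Elias-Fano encoding of monotone integer sequences.

A non-decreasing sequence S[0..n) with S[n-1] <= U is split into low
parts of fixed width l = floor(log2((U+1)/n)) and high parts coded in
unary in a bit vector (a one at position high(i)+i for every i).  The
payload then takes at most n*ceil(log2(U/n)) + 2n bits; random access
is O(1) given select-in-the-ones support (kept here as an explicit
position array, the o(n) overhead accounted separately from the
payload), and successor queries are binary searches over access.
"""

from __future__ import annotations

import math
import struct

import numpy as np

from .bits import CompactVector
from .errors import MonotonicityError, UniverseError


def payload_bound_bits(n: int, universe: int) -> int:
    """The guaranteed bound n*ceil(log2(U/n)) + 2n bits (U, n >= 1)."""
    ratio = max(1.0, universe / n)
    return n * math.ceil(math.log2(ratio)) + 2 * n if universe > 0 else 2 * n


class EFSequence:
    """Elias-Fano encoded monotone sequence with access and successor."""

    def __init__(self, universe: int, n: int, low_width: int,
                 lows: CompactVector | None, high_ones: np.ndarray):
        self.universe = universe
        self.n = n
        self.low_width = low_width
        self.lows = lows
        # positions of the ones in the (conceptual) unary high bit vector;
        # doubles as the precomputed select index.
        self._sel = np.ascontiguousarray(high_ones, dtype=np.int64)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_values(cls, values, universe: int | None = None) -> "EFSequence":
        vals = np.asarray(values, dtype=np.int64)
        n = len(vals)
        if n == 0:
            return cls(0, 0, 0, None, np.empty(0, dtype=np.int64))
        if np.any(vals[1:] < vals[:-1]):
            raise MonotonicityError("values must be non-decreasing")
        if vals[0] < 0:
            raise UniverseError("values must be non-negative")
        last = int(vals[-1])
        if universe is None:
            universe = last
        elif last > universe:
            raise UniverseError(f"value {last} exceeds universe {universe}")
        lw = max(0, int(math.floor(math.log2((universe + 1) / n))))
        if lw:
            lows = CompactVector.from_values(
                vals.astype(np.uint64) & np.uint64((1 << lw) - 1), lw
            )
            highs = vals >> lw
        else:
            lows = None
            highs = vals
        ones = highs + np.arange(n, dtype=np.int64)
        seq = cls(universe, n, lw, lows, ones)
        assert seq.payload_bits <= payload_bound_bits(n, universe), (
            "Elias-Fano payload exceeded its space bound"
        )
        return seq

    # -- queries -----------------------------------------------------------
    def __len__(self) -> int:
        return self.n

    def access(self, i: int) -> int:
        """S[i], decoded in O(1)."""
        if not 0 <= i < self.n:
            raise IndexError(f"index {i} out of [0,{self.n})")
        high = int(self._sel[i]) - i
        if self.low_width:
            return (high << self.low_width) | self.lows[i]
        return high

    __getitem__ = access

    def successor_rank(self, x: int) -> int:
        """Smallest i with S[i] >= x, or n if none."""
        lo, hi = 0, self.n
        while lo < hi:
            mid = (lo + hi) // 2
            if self.access(mid) < x:
                lo = mid + 1
            else:
                hi = mid
        return lo

    def to_array(self) -> np.ndarray:
        highs = self._sel - np.arange(self.n, dtype=np.int64)
        if self.low_width:
            return (highs << self.low_width) | self.lows.to_array().astype(np.int64)
        return highs

    # -- space accounting --------------------------------------------------
    @property
    def payload_bits(self) -> int:
        """Core payload: low parts plus the unary high bit vector."""
        if self.n == 0:
            return 0
        low_bits = self.n * self.low_width
        high_bits = int(self._sel[-1]) + 1  # unary vector ends at its last one
        return low_bits + high_bits

    @property
    def select_overhead_bits(self) -> int:
        """The explicit select index (o(n)-style support, not payload)."""
        return 64 * self.n

    # -- serialization (little-endian, 8-byte aligned) ----------------------
    def to_bytes(self) -> bytes:
        head = struct.pack("<QQQ", self.universe, self.n, self.low_width)
        body = self._sel.astype("<i8").tobytes()
        low = self.lows.to_bytes() if self.lows is not None else struct.pack("<QQQ", 0, 0, 0)
        return head + body + low

    @classmethod
    def from_buffer(cls, buf: memoryview, off: int) -> tuple["EFSequence", int]:
        universe, n, lw = struct.unpack_from("<QQQ", buf, off)
        off += 24
        sel = np.frombuffer(buf, dtype="<i8", count=n, offset=off).copy()
        off += 8 * n
        lows, off = CompactVector.from_buffer(buf, off)
        return cls(universe, n, lw, lows if lw else None, sel), off
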