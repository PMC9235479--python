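"""Random-order minimizers and super-k-mer parsing.

The minimizer of a k-mer g is the m-mer of g that is smallest under a
total order induced by a seeded 64-bit hash of the 2-bit packed m-mer.
Ties on equal hash values are broken by the leftmost position; across
strands (canonical modality) the forward strand wins.  A *super-k-mer*
is a maximal run of consecutive k-mers of one string sharing the same
minimizer; runs are additionally capped at k-m+1 k-mers so that a query
never has to inspect more than k-m+1 windows per super-k-mer.

In *canonical* modality the minimizer is the minimum over the m-mers of
both strands, which guarantees that a k-mer and its reverse complement
always receive the same minimizer (hence land in the same bucket).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .dna import PackedStrings

_MASK64 = (1 << 64) - 1

#: default seed for the minimizer hash order (stored in the index header)
DEFAULT_SEED = 0x9E3779B97F4A7C15


def mix64(x: int) -> int:
    """64-bit finalizer in the splitmix64 family (scalar)."""
    x &= _MASK64
    x ^= x >> 30
    x = (x * 0xBF58476D1CE4E5B9) & _MASK64
    x ^= x >> 27
    x = (x * 0x94D049BB133111EB) & _MASK64
    x ^= x >> 31
    return x


def mix64_np(x: np.ndarray) -> np.ndarray:
    """Vectorized twin of :func:`mix64` (uint64, wrapping arithmetic)."""
    x = x.astype(np.uint64, copy=True)
    x ^= x >> np.uint64(30)
    x *= np.uint64(0xBF58476D1CE4E5B9)
    x ^= x >> np.uint64(27)
    x *= np.uint64(0x94D049BB133111EB)
    x ^= x >> np.uint64(31)
    return x


@dataclass(frozen=True)
class SuperKmer:
    """One parsed super-k-mer.

    ``offset`` is the absolute position in [0,N) of its first base,
    ``length`` the number of bases K (k <= K <= 2k-m), ``minimizer`` the
    packed m-mer shared by all its K-k+1 constituent k-mers.
    """

    string_index: int
    offset: int
    length: int
    minimizer: int


class SuperKmers:
    """Column-oriented set of super-k-mers as produced by the parser."""

    def __init__(self, string_idx, offsets, n_windows, minimizers, k: int, m: int):
        self.string_idx = np.asarray(string_idx, dtype=np.int64)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.n_windows = np.asarray(n_windows, dtype=np.int64)
        self.minimizers = np.asarray(minimizers, dtype=np.uint64)
        self.k = k
        self.m = m

    def __len__(self) -> int:
        return len(self.offsets)

    @property
    def n_kmers(self) -> int:
        return int(self.n_windows.sum())

    def __iter__(self):
        k = self.k
        for j, t, c, r in zip(
            self.string_idx, self.offsets, self.n_windows, self.minimizers
        ):
            yield SuperKmer(int(j), int(t), int(c) + k - 1, int(r))


class MinimizerScheme:
    """Hash-defined order on m-mers; computes minimizers and super-k-mers.

    Parameters
    ----------
    m : minimizer length, 1 <= m <= k (m <= 32 so an m-mer packs in 64 bits)
    seed : 64-bit seed of the hash order; identical (m, seed, modality)
        give identical minimizers across runs and platforms
    canonical : select the minimum over both strands when True
    """

    def __init__(self, m: int, seed: int = DEFAULT_SEED, canonical: bool = False):
        if not 1 <= m <= 32:
            raise ValueError("minimizer length must be in [1, 32]")
        self.m = m
        self.seed = seed & _MASK64
        self.canonical = canonical
        self._seed_mix = mix64(self.seed)
        self._mask = (1 << (2 * m)) - 1

    # -- hashing -----------------------------------------------------------
    def hash_mmer(self, packed: int) -> int:
        """Hash of a 2-bit packed m-mer under this scheme's seed."""
        return mix64(packed ^ self._seed_mix)

    def _hash_np(self, packed: np.ndarray) -> np.ndarray:
        return mix64_np(packed ^ np.uint64(self._seed_mix))

    # -- per-position m-mer keys -------------------------------------------
    def _position_keys(self, codes: np.ndarray):
        """For every m-mer position: (order key, chosen packed m-mer).

        Regular modality keys by the forward-strand hash; canonical by
        the elementwise minimum of forward and reverse-complement hashes
        (forward wins ties, realizing the cross-strand tie-break).
        """
        m = self.m
        npos = len(codes) - m + 1
        pf = np.zeros(npos, dtype=np.uint64)
        for j in range(m):
            pf = (pf << np.uint64(2)) | codes[j : j + npos].astype(np.uint64)
        hf = self._hash_np(pf)
        if not self.canonical:
            return hf, pf
        pr = np.zeros(npos, dtype=np.uint64)
        for j in range(m):
            pr |= (codes[j : j + npos].astype(np.uint64) ^ np.uint64(3)) << np.uint64(
                2 * j
            )
        hr = self._hash_np(pr)
        take_f = hf <= hr
        return np.minimum(hf, hr), np.where(take_f, pf, pr)

    # -- single k-mer ------------------------------------------------------
    def minimizer(self, codes: np.ndarray) -> tuple[int, int]:
        """(packed minimizer, position) of one k-mer given as codes.

        Scalar rolling-hash scan; bit-exact with the vectorized parser.
        """
        m = self.m
        K = len(codes)
        if K < m:
            raise ValueError("k-mer shorter than m")
        mask = self._mask
        top = 2 * (m - 1)
        pf = 0
        pr = 0
        best_key = None
        best_val = 0
        best_pos = 0
        for i, c in enumerate(codes):
            c = int(c)
            pf = ((pf << 2) | c) & mask
            pr = (pr >> 2) | ((c ^ 3) << top)
            if i < m - 1:
                continue
            pos = i - m + 1
            key = self.hash_mmer(pf)
            val = pf
            if self.canonical:
                kr = self.hash_mmer(pr)
                if kr < key:
                    key, val = kr, pr
            if best_key is None or key < best_key:
                best_key, best_val, best_pos = key, val, pos
        return best_val, best_pos

    # -- all windows of a string -------------------------------------------
    def window_minimizers(self, codes: np.ndarray, k: int):
        """Per k-mer window of ``codes``: (minimizer value, its position).

        Leftmost-minimum sliding window (size k-m+1) over the position
        keys, via a monotone deque; ties keep the earlier position.
        """
        m = self.m
        if k < m:
            raise ValueError("k must be >= m")
        n_win = len(codes) - k + 1
        if n_win <= 0:
            return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
        keys, vals = self._position_keys(codes)
        w = k - m + 1
        out_val = np.empty(n_win, dtype=np.uint64)
        out_pos = np.empty(n_win, dtype=np.int64)
        dq: deque[int] = deque()
        keys_l = keys.tolist()
        for p in range(len(keys_l)):
            kp = keys_l[p]
            while dq and keys_l[dq[-1]] > kp:
                dq.pop()
            dq.append(p)
            if dq[0] <= p - w:
                dq.popleft()
            i = p - w + 1
            if i >= 0:
                out_pos[i] = dq[0]
        out_val = vals[out_pos]
        return out_val, out_pos

    # -- super-k-mer parsing -----------------------------------------------
    def parse_super_kmers(self, ps: PackedStrings, k: int) -> SuperKmers:
        """Partition every string's k-mers into capped constant-minimizer runs.

        Each run holds at most k-m+1 k-mers; consecutive runs of a string
        overlap by exactly k-1 bases; every k-mer belongs to one run.
        """
        cap = k - self.m + 1
        str_idx: list[int] = []
        offsets: list[int] = []
        counts: list[int] = []
        mins: list[int] = []
        E = ps.endpoints
        for j in range(ps.n_strings):
            lo, hi = int(E[j]), int(E[j + 1])
            vals, _ = self.window_minimizers(ps.codes[lo:hi], k)
            n_win = len(vals)
            if n_win == 0:
                continue
            # boundaries where the minimizer value changes
            change = np.flatnonzero(vals[1:] != vals[:-1]) + 1
            starts = np.concatenate(([0], change, [n_win]))
            for a, b in zip(starts[:-1], starts[1:]):
                a, b = int(a), int(b)
                v = int(vals[a])
                # cap runs at k-m+1 windows
                for s in range(a, b, cap):
                    c = min(cap, b - s)
                    str_idx.append(j)
                    offsets.append(lo + s)
                    counts.append(c)
                    mins.append(v)
        return SuperKmers(str_idx, offsets, counts, mins, k, self.m)
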