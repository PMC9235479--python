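"""The assembled k-mer dictionary: build, Lookup, Access, iteration.

Given a path cover of a de Bruijn graph (strings over {A,C,G,T}, each of
length >= k, jointly containing every k-mer exactly once up to reverse
complement), the dictionary stores:

* Strings  -- the 2-bit concatenation of the cover (N bases, p strings);
* Endpoints -- Elias-Fano sequence of cumulative string lengths;
* f        -- an MPHF over the M distinct minimizers;
* Sizes    -- Elias-Fano prefix sums of bucket sizes, in the order of f;
* Offsets  -- ceil(log2 N)-bit absolute offsets of the z super-k-mers,
              grouped by bucket, ascending within each bucket;
* SkewIndex -- per-size-class MPHFs for the k-mers of heavy buckets.

The number of stored k-mers is n = N - p(k-1), and the identifier of the
k-mer found at window w of the super-k-mer at offset t, inside string j,
is i = t + w - j(k-1): global window rank, skipping the k-1 alien
windows at the tail of every preceding string.  Lookup of an absent
k-mer returns -1, never a false positive: every candidate position is
verified against Strings, and a bucket reached through a minimizer
r not in M is recognized by comparing r with the minimizer of the first
k-mer of the bucket.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import dna
from .dna import PackedStrings
from .efseq import EFSequence
from .errors import ConfigMismatchError, IntegrityError
from .minimizers import DEFAULT_SEED, MinimizerScheme, SuperKmers, mix64
from .mphf import Mphf
from .skew_index import SMALL, SkewIndex, partition_of

_MPHF_SALT = 0x1B873593A4093822


def identifier(t: int, w: int, j: int, k: int) -> int:
    """Identifier of the k-mer at window w of the super-k-mer at offset t,
    lying in string j: i = t + w - j(k-1)."""
    return t + w - j * (k - 1)


def default_m(N: int, k: int) -> int:
    """Recommended minimizer length m = ceil(log4 N) + 1, clamped to [1, k]."""
    m = math.ceil(math.log(N, 4)) + 1 if N > 1 else 1
    return max(1, min(m, k, 32))


def canonical_window_keys(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical (strand-min) 64-bit key of every k-mer window of ``codes``.

    Vectorized for k <= 32 (collision-free packed form); falls back to
    per-window fingerprints for larger k.
    """
    npos = len(codes) - k + 1
    if npos <= 0:
        return np.empty(0, dtype=np.uint64)
    if k <= 32:
        pf = np.zeros(npos, dtype=np.uint64)
        pr = np.zeros(npos, dtype=np.uint64)
        for j in range(k):
            pf = (pf << np.uint64(2)) | codes[j : j + npos].astype(np.uint64)
            pr |= (codes[j : j + npos].astype(np.uint64) ^ np.uint64(3)) << np.uint64(2 * j)
        return np.minimum(pf, pr)
    return np.fromiter(
        (dna.canonical_key(codes[i : i + k]) for i in range(npos)),
        dtype=np.uint64,
        count=npos,
    )


@dataclass(frozen=True)
class DictConfig:
    """Build parameters of a dictionary.

    ``ell``/``L`` are the skew-index threshold and cap exponents: buckets
    of size <= 2^ell are scanned, larger ones answered through the skew
    index whose last size class covers (2^L, max].
    """

    k: int
    m: int | None = None
    canonical: bool = False
    ell: int = 6
    L: int = 12
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.k < 2 or self.k > 63:
            raise ValueError("k must be in [2, 63]")
        if self.m is not None and not 1 <= self.m <= min(self.k, 32):
            raise ValueError("m must satisfy 1 <= m <= min(k, 32)")
        if not 0 <= self.ell < self.L:
            raise ValueError("need 0 <= ell < L")


@dataclass
class LookupResult:
    """Outcome of one Lookup: the unique id in [0, n) or -1."""

    id: int = -1
    orientation: str = "none"  # forward | reverse | none
    begin: int = -1
    end: int = -1
    t: int = -1  # offset of the matched super-k-mer (or scan start)
    w: int = -1  # window of the match within the scan
    string_index: int = -1


@dataclass
class QueryCounters:
    """Instrumentation for lookup and streaming paths."""

    windows: int = 0
    hits: int = 0
    extensions: int = 0
    f_evals: int = 0
    buckets_scanned: int = 0
    superkmers_scanned: int = 0


class Dictionary:
    """Exact associative dictionary over the k-mers of a path cover."""

    def __init__(self, config: DictConfig, strings: PackedStrings,
                 endpoints_ef: EFSequence, minimizer_mphf: Mphf,
                 sizes: EFSequence, offsets, skew: SkewIndex):
        self.config = config
        self.strings = strings
        self.endpoints_ef = endpoints_ef
        self.minimizer_mphf = minimizer_mphf
        self.sizes = sizes
        self.offsets = offsets
        self.skew = skew
        self.scheme = MinimizerScheme(config.m, config.seed, config.canonical)
        # derived caches
        E = strings.endpoints
        k = config.k
        self._kmers_before = np.concatenate(
            (E[:-1] - np.arange(strings.n_strings, dtype=np.int64) * (k - 1),
             [strings.n_bases - strings.n_strings * (k - 1)])
        )

    # -- basic stats -------------------------------------------------------
    @property
    def k(self) -> int:
        return self.config.k

    @property
    def n(self) -> int:
        """Number of stored k-mers: N - p(k-1)."""
        return self.strings.n_bases - self.strings.n_strings * (self.k - 1)

    @property
    def p(self) -> int:
        return self.strings.n_strings

    @property
    def N(self) -> int:
        return self.strings.n_bases

    @property
    def z(self) -> int:
        """Number of super-k-mers."""
        return len(self.offsets)

    @property
    def M(self) -> int:
        """Number of distinct minimizers."""
        return len(self.sizes) - 1

    @property
    def max_bucket(self) -> int:
        return self.skew.max_bucket

    # -- construction ------------------------------------------------------
    @classmethod
    def build(cls, cover, config: DictConfig,
              verify_distinct: bool = False) -> "Dictionary":
        k = config.k
        ps = PackedStrings.from_strings(cover, k=k)
        if config.m is None:
            config = replace(config, m=default_m(ps.n_bases, k))
        scheme = MinimizerScheme(config.m, config.seed, config.canonical)
        sk = scheme.parse_super_kmers(ps, k)
        if verify_distinct:
            cls._verify_distinct(ps, k)
        uniq, inverse = np.unique(sk.minimizers, return_inverse=True)
        f = Mphf.build(uniq, seed=mix64(config.seed ^ _MPHF_SALT))
        bucket_ids = f.eval_array(uniq)[inverse]
        order = np.lexsort((sk.offsets, bucket_ids))
        counts = np.bincount(bucket_ids, minlength=len(uniq))
        prefix = np.zeros(len(uniq) + 1, dtype=np.int64)
        np.cumsum(counts, out=prefix[1:])
        sizes = EFSequence.from_values(prefix, universe=len(sk))
        width = max(1, math.ceil(math.log2(max(2, ps.n_bases))))
        from .bits import CompactVector

        offsets = CompactVector.from_values(sk.offsets[order], width)
        skew = cls._build_skew(ps, sk, order, prefix, config)
        return cls(config, ps, EFSequence.from_values(ps.endpoints),
                   f, sizes, offsets, skew)

    @staticmethod
    def _verify_distinct(ps: PackedStrings, k: int) -> None:
        keys = []
        E = ps.endpoints
        for j in range(ps.n_strings):
            keys.append(canonical_window_keys(ps.codes[E[j]:E[j + 1]], k))
        allk = np.concatenate(keys)
        if len(np.unique(allk)) != len(allk):
            raise IntegrityError("duplicate k-mers in the input collection")

    @classmethod
    def _build_skew(cls, ps, sk: SuperKmers, order, prefix, config) -> SkewIndex:
        k = config.k
        counts = np.diff(prefix)
        max_bucket = int(counts.max()) if len(counts) else 0
        threshold = 1 << config.ell
        sorted_offsets = sk.offsets[order]
        sorted_windows = sk.n_windows[order]
        heavy = []
        for b in np.flatnonzero(counts > threshold):
            begin, end = int(prefix[b]), int(prefix[b + 1])
            pairs = []
            for q in range(end - begin):
                t = int(sorted_offsets[begin + q])
                c = int(sorted_windows[begin + q])
                keys = canonical_window_keys(ps.codes[t : t + c + k - 1], k)
                pairs.extend((int(key), q) for key in keys)
            heavy.append((end - begin, pairs))
        return SkewIndex.build(heavy, config.ell, config.L, max_bucket,
                               seed=config.seed)

    # -- membership --------------------------------------------------------
    def is_valid_window(self, t: int) -> bool:
        """True iff [t, t+k) does not cross a string boundary."""
        return self.strings.is_valid_window(t, self.k)

    def _string_of(self, t: int) -> int:
        return self.strings.string_of(t)

    def _locate_bucket(self, r: int,
                       counters: QueryCounters | None = None) -> tuple[int, int, bool]:
        """Bucket [begin, end) of minimizer r, and whether r is in M.

        The MPHF locates a bucket for *any* input; r not in M is detected
        by comparing r with the minimizer of the first k-mer of the first
        super-k-mer in the bucket (the foreign-minimizer guard), which is
        required for exactness.
        """
        h = self.minimizer_mphf(r)
        if counters:
            counters.f_evals += 1
        begin, end = self.sizes.access(h), self.sizes.access(h + 1)
        t0 = self.offsets[begin]
        k = self.k
        r0, _ = self.scheme.minimizer(self.strings.codes[t0 : t0 + k])
        return begin, end, r0 == r

    def _search_in_bucket(self, codes: np.ndarray, begin: int, end: int, *,
                          rc_codes=None,
                          counters: QueryCounters | None = None,
                          use_skew: bool = True) -> LookupResult:
        """Search a confirmed bucket for ``codes`` (and ``rc_codes``).

        Heavy buckets go through the skew index (one verified candidate);
        small ones are scanned.  At most k-m+1 windows of each candidate
        super-k-mer are compared.
        """
        k, m = self.k, self.config.m
        result = LookupResult(begin=begin, end=end)
        size = end - begin
        if use_skew and partition_of(size, self.config.ell, self.config.L) != SMALL:
            key = int(canonical_window_keys(codes, k)[0])
            q = self.skew.lookup(key, size)
            if q is not None:
                if q >= size:
                    return result
                candidates = (q,)
            else:  # size class absent: fall back to a scan
                candidates = range(size)
        else:
            candidates = range(size)
        if counters:
            counters.buckets_scanned += 1
        cap = k - m + 1
        E = self.strings.endpoints
        qb = codes.tobytes()
        rb = rc_codes.tobytes() if rc_codes is not None else None
        for q in candidates:
            t = self.offsets[begin + q]
            if counters:
                counters.superkmers_scanned += 1
            j = self._string_of(t)
            n_scan = min(cap, int(E[j + 1]) - t - k + 1)
            seg = self.strings.codes[t : t + n_scan + k - 1].tobytes()
            w = seg.find(qb)
            if w >= 0 and w < n_scan:
                result.id = identifier(t, w, j, k)
                result.orientation = "forward"
                result.t, result.w, result.string_index = t, w, j
                return result
            if rb is not None:
                w = seg.find(rb)
                if w >= 0 and w < n_scan:
                    result.id = identifier(t, w, j, k)
                    result.orientation = "reverse"
                    result.t, result.w, result.string_index = t, w, j
                    return result
        return result

    def lookup(self, g: str, counters: QueryCounters | None = None,
               use_skew: bool = True) -> LookupResult:
        """Context-less Lookup: unique id in [0, n) of g, or -1.

        A k-mer and its reverse complement are identified.  Canonical
        modality inspects a single bucket; regular modality searches g
        first and, only when absent, its reverse complement (a second
        bucket).
        """
        if len(g) != self.k:
            raise ConfigMismatchError(f"query length {len(g)} != k={self.k}")
        codes = dna.try_encode(g)
        if counters:
            counters.windows += 1
        if (codes == 255).any():
            return LookupResult()
        res = self._lookup_codes(codes, counters, use_skew)
        if counters and res.id >= 0:
            counters.hits += 1
        return res

    def _lookup_codes(self, codes, counters, use_skew) -> LookupResult:
        r, _ = self.scheme.minimizer(codes)
        begin, end, known = self._locate_bucket(r, counters)
        if self.config.canonical:
            if not known:
                return LookupResult(begin=begin, end=end)
            rc = dna.revcomp_codes(codes)
            return self._search_in_bucket(codes, begin, end, rc_codes=rc,
                                          counters=counters, use_skew=use_skew)
        if known:
            res = self._search_in_bucket(codes, begin, end,
                                         counters=counters, use_skew=use_skew)
            if res.id >= 0:
                return res
        rc = dna.revcomp_codes(codes)
        r2, _ = self.scheme.minimizer(rc)
        begin, end, known = self._locate_bucket(r2, counters)
        if not known:
            return LookupResult(begin=begin, end=end)
        res = self._search_in_bucket(rc, begin, end,
                                     counters=counters, use_skew=use_skew)
        if res.id >= 0:
            res.orientation = "reverse"
        return res

    # -- access and iteration ----------------------------------------------
    def access(self, i: int) -> str:
        """The k-mer with identifier i, spelled as stored in Strings."""
        if not 0 <= i < self.n:
            raise IndexError(f"identifier {i} out of [0,{self.n})")
        kb = self._kmers_before
        j = int(np.searchsorted(kb, i, side="right")) - 1
        t = i + j * (self.k - 1)
        return dna.decode(self.strings.codes[t : t + self.k])

    def iterate(self):
        """Yield (id, k-mer) for id = 0..n-1 in id order."""
        k = self.k
        E = self.strings.endpoints
        i = 0
        for j in range(self.p):
            for t in range(int(E[j]), int(E[j + 1]) - k + 1):
                yield i, dna.decode(self.strings.codes[t : t + k])
                i += 1

    def bucket_sizes(self) -> np.ndarray:
        """Sizes of all M buckets (differences of the Sizes prefix sums)."""
        return np.diff(self.sizes.to_array())
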