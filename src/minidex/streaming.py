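"""Stateful streaming membership over consecutive k-mer windows.

Consecutive windows of a pattern overlap by k-1 symbols and are likely
to share a minimizer, so the streamer caches (per searched strand): the
last minimizer r, whether r belongs to the indexed minimizer set M, and
r's bucket [begin, end).  When the minimizer repeats, the MPHF, Sizes
and the foreign-minimizer guard are all skipped; if additionally r was
unknown, the window is declared absent with no work at all.  The state
also holds the absolute position of the last match in Strings and its
orientation, and first tries to *extend* that match: one position to
the right after a forward match, one to the left after a
reverse-complement match (without the backward direction, a fully
reverse-complemented pattern would re-scan its bucket for every window
-- quadratically many k-mer comparisons).  Every fast path is
re-verified against Strings and the string endpoints before being
accepted, so the optimization is observationally invisible: results are
identical, window by window, to independent Lookup calls.

Windows containing a non-ACGT base report id = -1 and reset the state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dna
from .dictionary import Dictionary, LookupResult, QueryCounters, identifier


@dataclass
class _BucketCache:
    """Cached bucket of the last minimizer seen on one search strand."""

    r: int | None = None
    known: bool = False
    begin: int = -1
    end: int = -1


@dataclass
class StreamState:
    """Constant-size state carried between consecutive windows."""

    fwd: _BucketCache = field(default_factory=_BucketCache)
    rev: _BucketCache = field(default_factory=_BucketCache)  # regular modality only
    last_pos: int | None = None
    orientation: str = "none"

    def reset(self) -> None:
        self.fwd = _BucketCache()
        self.rev = _BucketCache()
        self.last_pos = None
        self.orientation = "none"


def _try_extend(d: Dictionary, codes: np.ndarray, state: StreamState,
                counters: QueryCounters | None,
                orientation_cache: bool) -> LookupResult | None:
    """Verified extension of the previous match by one position."""
    if state.last_pos is None:
        return None
    k = d.k
    if state.orientation == "forward":
        p = state.last_pos + 1
        target = codes
    elif state.orientation == "reverse" and orientation_cache:
        p = state.last_pos - 1
        target = dna.revcomp_codes(codes)
    else:
        return None
    if p < 0 or not d.strings.is_valid_window(p, k):
        return None
    if not np.array_equal(d.strings.codes[p : p + k], target):
        return None
    j = d.strings.string_of(p)
    res = LookupResult(
        id=identifier(p, 0, j, k),
        orientation=state.orientation,
        t=p, w=0, string_index=j,
    )
    if counters:
        counters.extensions += 1
    return res


def _cached_bucket(d: Dictionary, r: int, cache: _BucketCache,
                   counters) -> _BucketCache:
    """Refresh the cached bucket for r, reusing it when r is unchanged."""
    if cache.r != r:
        begin, end, known = d._locate_bucket(r, counters)
        cache.r, cache.begin, cache.end, cache.known = r, begin, end, known
    return cache


def stream_query(d: Dictionary, pattern: str,
                 counters: QueryCounters | None = None,
                 use_skew: bool = True,
                 orientation_cache: bool = True) -> list[LookupResult]:
    """Lookup results for every window P[i, i+k), i = 0..|P|-k.

    ``orientation_cache=False`` disables the backward-extension direction
    (extension is then only ever attempted forward); it exists to
    demonstrate the anti-quadratic effect of orientation caching on
    reverse-complemented patterns.
    """
    k = d.k
    codes = dna.try_encode(pattern)
    n_win = len(codes) - k + 1
    if n_win <= 0:
        return []
    invalid = codes == 255
    results: list[LookupResult] = []
    state = StreamState()

    # window validity and per-window minimizers on maximal valid stretches
    win_ok = np.ones(n_win, dtype=bool)
    if invalid.any():
        for b in np.flatnonzero(invalid):
            win_ok[max(0, b - k + 1) : b + 1] = False
    win_r = np.zeros(n_win, dtype=np.uint64)
    pos = 0
    while pos < n_win:
        if not win_ok[pos]:
            pos += 1
            continue
        seg_end = pos
        while seg_end < n_win and win_ok[seg_end]:
            seg_end += 1
        vals, _ = d.scheme.window_minimizers(codes[pos : seg_end - 1 + k], k)
        win_r[pos:seg_end] = vals
        pos = seg_end

    for i in range(n_win):
        if counters:
            counters.windows += 1
        if not win_ok[i]:
            results.append(LookupResult())
            state.reset()
            continue
        window = codes[i : i + k]
        r = int(win_r[i])
        res = None
        if state.fwd.r == r:
            # same bucket as the previous window: try to extend the match
            res = _try_extend(d, window, state, counters, orientation_cache)
        if res is None:
            cache = _cached_bucket(d, r, state.fwd, counters)
            if not cache.known:
                # r not in M: this strand's search is skipped entirely
                res = LookupResult(begin=cache.begin, end=cache.end)
            elif d.config.canonical:
                res = d._search_in_bucket(
                    window, cache.begin, cache.end,
                    rc_codes=dna.revcomp_codes(window),
                    counters=counters, use_skew=use_skew)
            else:
                res = d._search_in_bucket(window, cache.begin, cache.end,
                                          counters=counters, use_skew=use_skew)
            if res.id < 0 and not d.config.canonical:
                rc = dna.revcomp_codes(window)
                r2, _ = d.scheme.minimizer(rc)
                cache2 = _cached_bucket(d, r2, state.rev, counters)
                if cache2.known:
                    res2 = d._search_in_bucket(rc, cache2.begin, cache2.end,
                                               counters=counters,
                                               use_skew=use_skew)
                    if res2.id >= 0:
                        res2.orientation = "reverse"
                        res = res2
        if res.id >= 0:
            if counters:
                counters.hits += 1
            state.last_pos = res.t + res.w
            state.orientation = res.orientation
        else:
            state.last_pos = None
        results.append(res)
    return results


def stream_stats(results: list[LookupResult],
                 counters: QueryCounters | None = None) -> dict:
    """Aggregate report over one or more streamed patterns."""
    windows = len(results)
    hits = sum(1 for r in results if r.id >= 0)
    report = {
        "windows": windows,
        "hits": hits,
        "misses": windows - hits,
        "hit_fraction": hits / windows if windows else 0.0,
    }
    if counters is not None:
        assert counters.hits == hits and counters.windows == windows, (
            "instrumentation inconsistent with per-window results"
        )
        report.update(
            extensions=counters.extensions,
            f_evals=counters.f_evals,
            bucket_scans=counters.buckets_scanned,
            superkmers_scanned=counters.superkmers_scanned,
        )
    return report
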