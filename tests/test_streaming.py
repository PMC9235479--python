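"""Streaming queries: observational equivalence, state, anti-quadratic scans."""

import dataclasses

import numpy as np
import pytest

import minidex as mx
from conftest import K, random_kmers
from minidex.streaming import StreamState, stream_query, stream_stats


def batch_ids(d, pattern):
    return [d.lookup(pattern[i : i + d.k]).id
            for i in range(len(pattern) - d.k + 1)]


def test_equivalence_with_batch_lookup(modal_dict):
    cover, d = modal_dict
    rng = np.random.default_rng(41)
    patterns = (
        cover
        + [mx.revcomp(s) for s in cover]
        + [mx.decode(rng.integers(0, 4, 120).astype(np.uint8)) for _ in range(5)]
        + [cover[0][:40] + "N" + cover[1][:60]]  # invalid base mid-pattern
    )
    for pat in patterns:
        got = [r.id for r in stream_query(d, pat)]
        assert got == batch_ids(d, pat)


def test_equivalence_on_heavy_buckets(heavy_dict):
    cover, d = heavy_dict
    for pat in (cover[0], mx.revcomp(cover[0])):
        assert [r.id for r in stream_query(d, pat)] == batch_ids(d, pat)


def test_short_and_invalid_patterns(modal_dict):
    cover, d = modal_dict
    assert stream_query(d, "ACGT") == []
    res = stream_query(d, "N" * (K + 3))
    assert [r.id for r in res] == [-1, -1, -1, -1]


def test_state_reset_between_patterns(modal_dict):
    """Querying two patterns separately equals querying them independently."""
    cover, d = modal_dict
    a, b = cover[0], mx.revcomp(cover[1])
    combined = [r.id for r in stream_query(d, a)] + \
               [r.id for r in stream_query(d, b)]
    assert combined == batch_ids(d, a) + batch_ids(d, b)


def test_stored_string_extends_on_every_repeated_minimizer(modal_dict):
    cover, d = modal_dict
    pat = cover[0]
    c = mx.QueryCounters()
    res = stream_query(d, pat, counters=c)
    n_win = len(pat) - K + 1
    assert all(r.id >= 0 for r in res)
    # ids consecutive within one stored string
    ids = [r.id for r in res]
    assert ids == list(range(ids[0], ids[0] + n_win))
    # every window whose minimizer equals the previous one extends
    vals, _ = d.scheme.window_minimizers(mx.encode(pat), K)
    repeats = int((vals[1:] == vals[:-1]).sum())
    assert c.extensions == repeats
    assert c.extensions <= c.hits


def test_unknown_minimizer_skips_f_evaluations(modal_dict):
    """On an all-negative pattern, f is evaluated at most once per
    distinct-minimizer run (twice per run in regular modality)."""
    cover, d = modal_dict
    pat = mx.decode(np.random.default_rng(47).integers(0, 4, 400).astype(np.uint8))
    c = mx.QueryCounters()
    res = stream_query(d, pat, counters=c)
    vals, _ = d.scheme.window_minimizers(mx.encode(pat), K)
    runs = 1 + int((vals[1:] != vals[:-1]).sum())
    per_run = 1 if d.config.canonical else 2
    assert c.f_evals <= per_run * runs


def test_anti_quadratic_reverse_complement(heavy_dict):
    """Backward extension keeps scan work linear on rc patterns."""
    cover, d = heavy_dict
    long_s = max(cover, key=len)
    half = mx.revcomp(long_s[: len(long_s) // 2])
    full = mx.revcomp(long_s)

    def scans(pat, cache):
        c = mx.QueryCounters()
        res = stream_query(d, pat, counters=c, orientation_cache=cache)
        assert all(r.id >= 0 for r in res)
        return c.superkmers_scanned

    s_half, s_full = scans(half, True), scans(full, True)
    # linear, not quadratic: doubling the pattern at most ~doubles the work
    assert s_full <= 3 * max(s_half, 1) + 10
    # and orientation caching beats the forward-only variant clearly
    assert scans(full, False) >= 5 * s_full


def test_stream_stats_consistency(modal_dict):
    cover, d = modal_dict
    c = mx.QueryCounters()
    results = []
    for pat in (cover[0], mx.revcomp(cover[1])):
        results += stream_query(d, pat, counters=c)
    rep = stream_stats(results, c)
    assert rep["hits"] + rep["misses"] == rep["windows"] == len(results)
    assert rep["hits"] == sum(1 for r in results if r.id >= 0)
    assert rep["extensions"] <= rep["hits"]
    assert all(v >= 0 for v in rep.values())


def test_state_is_constant_size():
    # the cached state is a fixed set of scalar fields, independent of
    # pattern length
    fields = {f.name for f in dataclasses.fields(StreamState)}
    assert fields == {"fwd", "rev", "last_pos", "orientation"}
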