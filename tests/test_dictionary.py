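"""Dictionary build invariants, Lookup/Access correctness, exactness."""

import math

import numpy as np
import pytest

import minidex as mx
from conftest import K, build_fixture_dict, random_kmers, stored_key_set


def test_identifier_arithmetic():
    # t=255, w=8, j=2, k=31: discard j(k-1)=60 alien ranks
    assert mx.identifier(255, 8, 2, 31) == 203


def test_single_kmer_dictionary():
    g = random_kmers(1, seed=42)[0]
    d = mx.Dictionary.build([g], mx.DictConfig(k=K, m=8))
    assert (d.n, d.z, d.M) == (1, 1, 1)
    assert d.lookup(g).id == 0
    assert d.access(0) == g


def test_build_structural_invariants(modal_dict):
    cover, d = modal_dict
    assert d.n == d.N - d.p * (K - 1)
    prefix = d.sizes.to_array()
    assert prefix[0] == 0 and prefix[-1] == d.z
    assert (np.diff(prefix) > 0).all()  # every bucket non-empty
    # offsets: ceil(log2 N) bits each, ascending within each bucket
    assert d.offsets.width == math.ceil(math.log2(d.N))
    offs = d.offsets.to_array().astype(np.int64)
    assert (offs < d.N).all()
    for b in range(d.M):
        bucket = offs[prefix[b] : prefix[b + 1]]
        assert (np.diff(bucket) > 0).all() if len(bucket) > 1 else True
    # z and n recounted by brute force from the parse
    sk = d.scheme.parse_super_kmers(d.strings, K)
    assert len(sk) == d.z and sk.n_kmers == d.n


def test_lookup_bijection_and_strand_invariance(modal_dict):
    cover, d = modal_dict
    ids = []
    for i, g in d.iterate():
        res = d.lookup(g)
        assert res.id == i
        assert res.orientation == "forward"
        assert d.lookup(mx.revcomp(g)).id == i
        ids.append(res.id)
    assert sorted(ids) == list(range(d.n))


def test_access_lookup_mutually_inverse(modal_dict):
    cover, d = modal_dict
    for i in range(0, d.n, 7):
        g = d.access(i)
        assert d.lookup(g).id == i
    for i, g in d.iterate():
        back = d.access(d.lookup(g).id)
        assert back in (g, mx.revcomp(g))


def test_no_false_positives(modal_dict):
    cover, d = modal_dict
    oracle = stored_key_set(cover)
    for q in random_kmers(3000, seed=17):
        key = int(mx.canonical_window_keys(mx.encode(q), K)[0])
        res = d.lookup(q)
        assert (res.id >= 0) == (key in oracle)


def test_mutated_negatives(modal_dict):
    """Single-base mutations of stored k-mers are overwhelmingly absent."""
    cover, d = modal_dict
    oracle = stored_key_set(cover)
    rng = np.random.default_rng(23)
    kmers = [g for _, g in d.iterate()]
    for _ in range(2000):
        g = list(kmers[int(rng.integers(len(kmers)))])
        pos = int(rng.integers(K))
        g[pos] = "ACGT"[int(rng.integers(4))]
        q = "".join(g)
        key = int(mx.canonical_window_keys(mx.encode(q), K)[0])
        assert (d.lookup(q).id >= 0) == (key in oracle)


def test_is_valid_window():
    one = mx.Dictionary.build(["".join(random_kmers(1, k=40))],
                              mx.DictConfig(k=31, m=8))
    assert one.is_valid_window(9)   # 9 + 31 = 40 = N
    assert not one.is_valid_window(10)
    two_strings = random_kmers(2, k=31, seed=3)
    d = mx.Dictionary.build(two_strings, mx.DictConfig(k=31, m=8))
    assert d.is_valid_window(0)
    assert not d.is_valid_window(1)
    assert d.is_valid_window(31)
    # agrees with a direct endpoint-interval oracle
    cover, dd = build_fixture_dict(seed=5, canonical=False)
    E = dd.strings.endpoints
    for t in range(dd.N):
        j = int(np.searchsorted(E, t, side="right")) - 1
        assert dd.is_valid_window(t) == (t + K <= E[j + 1])


def test_iterate_matches_input_kmers(modal_dict):
    cover, d = modal_dict
    emitted = list(d.iterate())
    assert [i for i, _ in emitted] == list(range(d.n))
    got = {int(mx.canonical_window_keys(mx.encode(g), K)[0]) for _, g in emitted}
    assert got == stored_key_set(cover)


def test_input_validation_errors():
    with pytest.raises(mx.ShortStringError):
        mx.Dictionary.build(["ACGT"], mx.DictConfig(k=31))
    with pytest.raises(mx.InvalidBaseError):
        mx.Dictionary.build(["ACGTN" + "A" * 30], mx.DictConfig(k=31, m=8))
    g = random_kmers(1, seed=9)[0]
    with pytest.raises(mx.IntegrityError):
        mx.Dictionary.build([g, mx.revcomp(g)], mx.DictConfig(k=K, m=8),
                            verify_distinct=True)


def test_query_side_errors(modal_dict):
    cover, d = modal_dict
    with pytest.raises(mx.ConfigMismatchError):
        d.lookup("ACGT")
    with pytest.raises(IndexError):
        d.access(d.n)
    with pytest.raises(IndexError):
        d.access(-1)
    # non-ACGT in a query window is a miss, not an error
    assert d.lookup("N" * K).id == -1


def test_default_m_formula():
    assert mx.default_m(405, 31) == math.ceil(math.log(405, 4)) + 1 == 6
    cover, d = build_fixture_dict(seed=2, canonical=False, m=None)
    assert d.config.m == mx.default_m(d.N, K)


def test_stats_report_consistency(modal_dict):
    cover, d = modal_dict
    rep = mx.compute_stats(d)
    assert rep.component_bits["strings"] == 2 * d.N
    assert rep.component_bits["offsets"] == d.z * math.ceil(math.log2(d.N))
    assert rep.total_bits == sum(rep.component_bits.values())
    assert sum(rep.size_histogram_pct.values()) == pytest.approx(100.0)
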