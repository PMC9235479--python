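"""Minimizer order, canonical strand symmetry, super-k-mer parsing."""

import numpy as np
import pytest

import minidex as mx
from minidex.dna import PackedStrings
from minidex.minimizers import MinimizerScheme


def rand_codes(n, seed):
    return np.random.default_rng(seed).integers(0, 4, n).astype(np.uint8)


def brute_minimizer(scheme, codes):
    """Exhaustive (hash, position) argmin over all m-mers, one strand or two."""
    m = scheme.m
    best = None
    for p in range(len(codes) - m + 1):
        sub = codes[p : p + m]
        cands = [(scheme.hash_mmer(mx.dna.pack_codes(sub)), mx.dna.pack_codes(sub))]
        if scheme.canonical:
            rc = mx.dna.revcomp_codes(sub)
            cands.append((scheme.hash_mmer(mx.dna.pack_codes(rc)),
                          mx.dna.pack_codes(rc)))
        h, v = min(cands)  # forward listed first: wins hash ties
        if best is None or h < best[0]:
            best = (h, v, p)
    return best[1], best[2]


def test_hash_deterministic_and_seed_sensitive():
    s = MinimizerScheme(8, seed=123)
    pm = mx.dna.pack_codes(rand_codes(8, 0))
    assert s.hash_mmer(pm) == s.hash_mmer(pm)
    codes = rand_codes(10_000, 1)
    a, _ = MinimizerScheme(10, seed=1).window_minimizers(codes, 31)
    b, _ = MinimizerScheme(10, seed=2).window_minimizers(codes, 31)
    assert (a != b).any()


def test_no_observed_hash_collisions():
    # ~1e5 random pairs of distinct m-mers; a 64-bit hash should never collide
    rng = np.random.default_rng(9)
    s = MinimizerScheme(16, seed=7)
    vals = rng.integers(0, 1 << 32, 200_000, dtype=np.uint64)
    a, b = vals[::2], vals[1::2]
    diff = a != b
    ha = mx.minimizers.mix64_np(a ^ np.uint64(s._seed_mix))
    hb = mx.minimizers.mix64_np(b ^ np.uint64(s._seed_mix))
    assert not (ha[diff] == hb[diff]).any()


def test_scalar_vector_hash_agree():
    s = MinimizerScheme(12, seed=77)
    rng = np.random.default_rng(0)
    packed = rng.integers(0, 1 << 24, 100, dtype=np.uint64)
    vec = s._hash_np(packed)
    for pm, h in zip(packed, vec):
        assert s.hash_mmer(int(pm)) == int(h)


def test_minimizer_m_equals_k():
    codes = rand_codes(20, 3)
    s = MinimizerScheme(20, seed=5)
    val, pos = s.minimizer(codes)
    assert pos == 0 and val == mx.dna.pack_codes(codes)


@pytest.mark.parametrize("canonical", [False, True], ids=["regular", "canonical"])
def test_minimizer_matches_bruteforce(canonical):
    for seed in range(30):
        codes = rand_codes(31, 100 + seed)
        s = MinimizerScheme(11, seed=42, canonical=canonical)
        assert s.minimizer(codes) == brute_minimizer(s, codes)


def test_canonical_strand_symmetry():
    s = MinimizerScheme(20, seed=13, canonical=True)
    for seed in range(1000):
        codes = rand_codes(31, seed)
        v1, _ = s.minimizer(codes)
        v2, _ = s.minimizer(mx.dna.revcomp_codes(codes))
        assert v1 == v2


def test_scalar_and_window_minimizers_agree():
    codes = rand_codes(500, 8)
    for canonical in (False, True):
        s = MinimizerScheme(9, seed=21, canonical=canonical)
        vals, _ = s.window_minimizers(codes, 31)
        for i in range(len(codes) - 30):
            v, _ = s.minimizer(codes[i : i + 31])
            assert v == int(vals[i])


def test_parse_single_kmer_string():
    ps = PackedStrings.from_strings([mx.decode(rand_codes(31, 2))])
    sk = MinimizerScheme(8, seed=3).parse_super_kmers(ps, 31)
    assert len(sk) == 1
    one = next(iter(sk))
    assert one.length == 31 and one.offset == 0


def test_parse_partition_and_cap():
    """Runs tile each string, overlap by k-1 bases, never exceed k-m+1."""
    k, m = 31, 8
    ps = PackedStrings.from_strings(
        [mx.decode(rand_codes(n, s)) for s, n in enumerate((400, 700, 55))], k=k
    )
    sk = MinimizerScheme(m, seed=17).parse_super_kmers(ps, k)
    n = ps.n_bases - ps.n_strings * (k - 1)
    assert sk.n_kmers == n
    assert (sk.n_windows <= k - m + 1).all()  # at most 24 k-mers each here
    # consecutive super-k-mers of one string tile it
    for j in range(ps.n_strings):
        sel = sk.string_idx == j
        offs, wins = sk.offsets[sel], sk.n_windows[sel]
        assert offs[0] == ps.endpoints[j]
        assert (offs[1:] == offs[:-1] + wins[:-1]).all()
        assert offs[-1] + wins[-1] - 1 + k == ps.endpoints[j + 1]
    # every constituent k-mer of a run shares the run's minimizer
    scheme = MinimizerScheme(m, seed=17)
    for skm in list(sk)[:20]:
        for w in range(skm.length - k + 1):
            v, _ = scheme.minimizer(ps.codes[skm.offset + w : skm.offset + w + k])
            assert v == skm.minimizer


def test_density_approaches_theory():
    """k-mer / super-k-mer ratio ~ (k-m+2)/2 on uniform-random DNA."""
    codes = rand_codes(200_000, 4)
    ps = PackedStrings(codes, np.array([0, len(codes)]))
    sk = MinimizerScheme(20, seed=11).parse_super_kmers(ps, 31)
    ratio = sk.n_kmers / len(sk)
    assert ratio == pytest.approx(6.5, rel=0.05)


def test_canonical_uses_at_least_as_many_minimizers():
    codes = rand_codes(50_000, 6)
    ps = PackedStrings(codes, np.array([0, len(codes)]))
    reg = MinimizerScheme(15, seed=19, canonical=False).parse_super_kmers(ps, 31)
    can = MinimizerScheme(15, seed=19, canonical=True).parse_super_kmers(ps, 31)
    assert len(np.unique(can.minimizers)) >= len(np.unique(reg.minimizers))
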