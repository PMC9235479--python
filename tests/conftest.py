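"""Shared fixtures: synthetic covers and built dictionaries."""

from __future__ import annotations

import numpy as np
import pytest

import minidex as mx

K = 31


def build_fixture_dict(seed: int, canonical: bool, *, p=4, min_len=60,
                       max_len=160, k=K, m=None, ell=6, L=12):
    cover = mx.gen_cover(mx.FixtureSpec(seed=seed, p=p, min_len=min_len,
                                        max_len=max_len, k=k))
    cfg = mx.DictConfig(k=k, m=m, canonical=canonical, ell=ell, L=L)
    return cover, mx.Dictionary.build(cover, cfg)


def stored_key_set(cover, k=K):
    """Hash-set membership oracle over canonical k-mer keys."""
    keys: set[int] = set()
    for s in cover:
        keys.update(int(x) for x in mx.canonical_window_keys(mx.encode(s), k))
    return keys


def heavy_cover(seed: int = 7, m: int = 4, k: int = K):
    """Cover with implanted minimal m-mers, forcing buckets above 2^ell."""
    scheme = mx.MinimizerScheme(m, mx.DEFAULT_SEED)
    motifs = tuple(mx.minimal_mmers(scheme, 2))
    spec = mx.FixtureSpec(seed=seed, p=5, min_len=400, max_len=600, k=k,
                          heavy_motifs=motifs, heavy_spacing=45)
    return mx.gen_cover(spec)


@pytest.fixture(scope="session", params=[False, True],
                ids=["regular", "canonical"])
def modal_dict(request):
    """(cover, dictionary) in both parsing modalities."""
    return build_fixture_dict(seed=11, canonical=request.param,
                              p=6, min_len=80, max_len=300)


@pytest.fixture(scope="session")
def heavy_dict():
    """Canonical-modality dictionary with buckets far above 2^ell (ell=2)."""
    cover = heavy_cover()
    cfg = mx.DictConfig(k=K, m=4, canonical=True, ell=2, L=5)
    return cover, mx.Dictionary.build(cover, cfg)


@pytest.fixture(scope="session")
def heavy_dict_regular():
    cover = heavy_cover(seed=9)
    cfg = mx.DictConfig(k=K, m=4, canonical=False, ell=2, L=5)
    return cover, mx.Dictionary.build(cover, cfg)


def random_kmers(n, k=K, seed=0):
    rng = np.random.default_rng(seed)
    return [mx.decode(rng.integers(0, 4, k).astype(np.uint8)) for _ in range(n)]
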