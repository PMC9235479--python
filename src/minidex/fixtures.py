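"""Deterministic synthetic path covers and query workloads.

A real path cover (stitched unitigs / simplitigs of a de Bruijn graph)
partitions the k-mer set into node-disjoint paths, so the one property
that matters to the dictionary -- no duplicate k-mers up to reverse
complement -- is enforced here by rejection: a freshly drawn string
whose canonical k-mers clash with what was already emitted is redrawn.
Uniform base composition is the default; it reproduces the statistical
regime of the minimizer-density law but none of the repeat structure of
real genomes (see the methods note).

The ``heavy_bucket_mmers`` knob implants the m-mers that are globally
smallest under a scheme's hash order; any k-mer window containing such
an m-mer is guaranteed to adopt it as its minimizer, so spaced implants
inflate one bucket far beyond 2^ell and force queries through the skew
index.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from . import dna
from .dictionary import canonical_window_keys
from .errors import GenerationError
from .minimizers import MinimizerScheme

_MAX_RETRIES = 80


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic path cover."""

    seed: int
    p: int = 4
    min_len: int = 60
    max_len: int = 160
    k: int = 31
    base_probs: tuple[float, float, float, float] | None = None  # uniform default
    heavy_motifs: tuple[str, ...] = ()  # m-mers to implant
    heavy_spacing: int = 0  # implant period in bases (0 = off)

    def __post_init__(self):
        if self.min_len < self.k:
            raise ValueError("min_len must be >= k")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")


def minimal_mmers(scheme: MinimizerScheme, count: int = 1) -> list[str]:
    """The ``count`` m-mers with the smallest hash under ``scheme``.

    A window containing one of them (and none smaller) necessarily picks
    it as minimizer; implanting them is how heavy buckets are engineered.
    Enumerates all 4^m m-mers, so intended for small m (m <= 8).
    """
    m = scheme.m
    if m > 8:
        raise ValueError("minimal_mmers enumerates 4^m candidates; use m <= 8")
    ranked = sorted(
        ("".join(t) for t in itertools.product(dna.BASES, repeat=m)),
        key=lambda s: scheme.hash_mmer(dna.pack_codes(dna.encode(s))),
    )
    return ranked[:count]


def _draw_string(rng: np.random.Generator, spec: FixtureSpec) -> str:
    length = int(rng.integers(spec.min_len, spec.max_len + 1))
    probs = spec.base_probs
    codes = rng.choice(4, size=length, p=probs) if probs else rng.integers(0, 4, length)
    s = dna.decode(codes.astype(np.uint8))
    if spec.heavy_motifs and spec.heavy_spacing:
        chars = list(s)
        for i, start in enumerate(range(0, length - spec.k, spec.heavy_spacing)):
            motif = spec.heavy_motifs[i % len(spec.heavy_motifs)]
            if start + len(motif) <= length:
                chars[start : start + len(motif)] = motif
        s = "".join(chars)
    return s


def gen_cover(spec: FixtureSpec) -> list[str]:
    """Generate a duplicate-free synthetic path cover.

    Deterministic under ``spec.seed``.  Raises GenerationError when a
    duplicate-free string cannot be drawn within a bounded number of
    retries (e.g. a tiny k with many strings).
    """
    # salted seed sequence: covers and query workloads sharing a seed must
    # not consume overlapping PRNG bit streams
    rng = np.random.default_rng([spec.seed, 0x636F76])
    seen: set[int] = set()
    cover: list[str] = []
    for _ in range(spec.p):
        for _attempt in range(_MAX_RETRIES):
            s = _draw_string(rng, spec)
            keys = canonical_window_keys(dna.encode(s), spec.k)
            uniq = set(int(x) for x in keys)
            if len(uniq) == len(keys) and not (uniq & seen):
                seen |= uniq
                cover.append(s)
                break
        else:
            raise GenerationError(
                f"could not draw a duplicate-free string after {_MAX_RETRIES} tries"
            )
    return cover


def gen_queries(cover: list[str], workload: str, n_queries: int, seed: int,
                length: int = 100, k: int = 31) -> list[str]:
    """Query patterns with a controlled hit rate.

    ``high_hit``: ~90% of patterns are substrings of the cover (half of
    the positive ones reverse-complemented), so >= 70% of all k-mer
    windows are stored.  ``low_hit``: uniform-random patterns, < 1% of
    windows stored for any realistic k.
    """
    if workload not in ("high_hit", "low_hit"):
        raise ValueError("workload must be high_hit or low_hit")
    if not cover:
        raise ValueError("cover must be non-empty")
    rng = np.random.default_rng([seed, 0x717279])
    out: list[str] = []
    for _ in range(n_queries):
        positive = workload == "high_hit" and rng.random() < 0.9
        if positive:
            s = cover[int(rng.integers(len(cover)))]
            ln = min(length, len(s))
            start = int(rng.integers(0, len(s) - ln + 1))
            pat = s[start : start + ln]
            if rng.random() < 0.5:
                pat = dna.revcomp(pat)
        else:
            pat = dna.decode(rng.integers(0, 4, length).astype(np.uint8))
        out.append(pat)
    return out


def measured_hit_fraction(cover: list[str], patterns: list[str], k: int) -> float:
    """Fraction of query windows present in the cover (hash-set oracle)."""
    stored: set[int] = set()
    for s in cover:
        stored.update(int(x) for x in canonical_window_keys(dna.encode(s), k))
    windows = 0
    hits = 0
    for pat in patterns:
        codes = dna.try_encode(pat)
        if len(codes) < k:
            continue
        keys = canonical_window_keys(codes, k)
        ok = ~np.isin(codes, 255)
        for i, key in enumerate(keys):
            if not ok[i : i + k].all():
                continue
            windows += 1
            hits += int(key) in stored
    return hits / windows if windows else 0.0
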