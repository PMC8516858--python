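"""Diploid microsatellite genetics for a selfing, clonal epiphyte.

Genotypes are arrays of integer repeat counts, shape (L, 2) for one
individual or (n, L, 2) for a batch, alleles sorted (low, high) within a
locus. The default marker panel has seven loci, mirroring a typical SSR
study of this system. Inheritance is strict self-fertilisation with a
single-step stepwise mutation model (±1 repeat per slippage, reflecting
boundary at one repeat); clonal growth copies the genotype unchanged by
default.

Two labels track identity through a simulation:

MLG (multi-locus genotype)
    distinct diploid genotype across all loci; clones and selfed offspring
    of homozygotes share an MLG.
MLL (multi-locus lineage)
    all descendants, sexual or clonal, of one founding immigrant seed;
    heterozygosity and slippage let one MLL span several MLGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_LOCI = 7

#: midpoint of the expected-heterozygosity range seen in field SSR panels
#: of this system (0.27-0.51)
DEFAULT_TARGET_HET = 0.39


@dataclass
class AllelePool:
    """Per-locus allele states and sampling frequencies for founder seeds."""

    alleles: list[np.ndarray]  # repeat counts per locus
    freqs: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.alleles) != len(self.freqs):
            raise ValueError("alleles and freqs must align per locus")
        if len(self.alleles) == 0:
            raise ValueError("empty allele pool")
        for a, f in zip(self.alleles, self.freqs):
            if len(a) == 0:
                raise ValueError("empty allele pool at a locus")
            if len(a) != len(f) or not np.isclose(np.sum(f), 1.0):
                raise ValueError("frequencies must match alleles and sum to 1")

    @property
    def n_loci(self) -> int:
        return len(self.alleles)


def default_pool(n_loci: int = N_LOCI, alleles_per_locus: int = 6,
                 base: int = 10) -> AllelePool:
    """Synthetic regional allele pool: contiguous repeat ladders with
    geometrically decaying frequencies (a common empirical shape)."""
    states = [np.arange(base, base + alleles_per_locus) for _ in range(n_loci)]
    w = 0.7 ** np.arange(alleles_per_locus)
    f = w / w.sum()
    return AllelePool(states, [f.copy() for _ in range(n_loci)])


def random_founder_genotype(
    pool: AllelePool,
    target_heterozygosity: float = DEFAULT_TARGET_HET,
    rng: np.random.Generator | None = None,
    n: int | None = None,
) -> np.ndarray:
    """Draw founder genotype(s) from the regional pool.

    Each locus is heterozygous with probability `target_heterozygosity`
    (two distinct alleles drawn by pool frequency) and homozygous
    otherwise, so the expected per-locus heterozygosity of founders equals
    the target. Returns (L, 2) for ``n=None`` else (n, L, 2).
    """
    rng = np.random.default_rng(rng)
    if not 0.0 <= target_heterozygosity <= 1.0:
        raise ValueError("target_heterozygosity must be in [0, 1]")
    squeeze = n is None
    n = 1 if squeeze else n
    L = pool.n_loci
    out = np.empty((n, L, 2), dtype=np.int16)
    for l in range(L):
        a, f = pool.alleles[l], pool.freqs[l]
        first = rng.choice(a, size=n, p=f)
        out[:, l, 0] = first
        out[:, l, 1] = first
        if len(a) > 1 and target_heterozygosity > 0:
            het = rng.uniform(size=n) < target_heterozygosity
            n_het = int(het.sum())
            if n_het:
                # second, distinct allele re-drawn by conditional frequency
                second = rng.choice(a, size=n_het, p=f)
                redraw = second == first[het]
                while redraw.any():
                    second[redraw] = rng.choice(a, size=int(redraw.sum()), p=f)
                    redraw = second == first[het]
                out[het, l, 1] = second
    out.sort(axis=2)
    return out[0] if squeeze else out


def mutate_alleles(alleles: np.ndarray, mu: float,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Stepwise mutation on an array of repeat counts.

    Each value independently slips by ±1 repeat (equal probability) with
    probability `mu`; counts reflect at the one-repeat boundary.
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must be a probability")
    rng = np.random.default_rng(rng)
    alleles = np.asarray(alleles)
    out = alleles.copy()
    if mu == 0.0:
        return out
    hit = rng.uniform(size=alleles.shape) < mu
    step = rng.choice(np.array([-1, 1], dtype=alleles.dtype), size=alleles.shape)
    out[hit] = out[hit] + step[hit]
    out[out < 1] = 2 - out[out < 1]  # reflect below one repeat
    return out


def mutate_allele(allele: int, mu: float,
                  rng: np.random.Generator | None = None) -> int:
    """Single-allele convenience wrapper around :func:`mutate_alleles`."""
    return int(mutate_alleles(np.array([allele], dtype=np.int64), mu, rng)[0])


def self_gametes(parents: np.ndarray, mu: float,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Selfed offspring genotypes for a batch of parents, (n, L, 2).

    Per locus each of the two gamete alleles is drawn independently from
    the parent's pair (Mendelian selfing), then passed through the
    stepwise mutation model.
    """
    rng = np.random.default_rng(rng)
    parents = np.asarray(parents)
    n, L, _ = parents.shape
    pick = rng.integers(0, 2, size=(n, L, 2))
    off = np.take_along_axis(parents, pick, axis=2)
    off = mutate_alleles(off, mu, rng)
    off.sort(axis=2)
    return off


def self_offspring(parent: np.ndarray, mu: float = 0.0,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """One selfed offspring of a single (L, 2) parent genotype."""
    return self_gametes(np.asarray(parent)[None], mu, rng)[0]


@dataclass
class LineageRegistry:
    """Interns genotypes to MLG ids and hands out founder MLL ids."""

    _mlg_index: dict[bytes, int] = field(default_factory=dict)
    _next_mll: int = 0

    def assign_mlg(self, genotype: np.ndarray) -> int:
        key = np.ascontiguousarray(genotype, dtype=np.int16).tobytes()
        return self._mlg_index.setdefault(key, len(self._mlg_index))

    def assign_mlg_batch(self, genotypes: np.ndarray) -> np.ndarray:
        return np.array([self.assign_mlg(g) for g in genotypes], dtype=np.int32)

    def new_mll(self, n: int = 1) -> np.ndarray:
        ids = np.arange(self._next_mll, self._next_mll + n, dtype=np.int32)
        self._next_mll += n
        return ids

    @property
    def n_mlg_seen(self) -> int:
        return len(self._mlg_index)

    @property
    def n_mll_created(self) -> int:
        return self._next_mll
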