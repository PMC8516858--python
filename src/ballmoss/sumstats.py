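"""Population-genetic summary statistics for microsatellite samples.

All statistics operate on a :class:`SampleMatrix` — individuals x loci
diploid repeat-count genotypes with subpopulation (host tree) labels and
metric coordinates. Implemented from the standard formulas: Nei
diversity with small-sample correction, Weir & Cockerham (1984) theta for
F_ST, two-level AMOVA variance components, the modified Garza-Williamson
statistic k/(R+1), Loiselle et al. (1995) pairwise kinship, the Sp
statistic of kinship decay with ln(distance), Whittaker-normalised
turnover of alleles/MLGs/MLLs, and Mantel isolation-by-distance tests on
several classical genetic distances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

#: distances below one patch are pooled at the patch scale before taking logs
MIN_LOG_DISTANCE = 0.1


@dataclass
class SampleMatrix:
    """Genotyped sample: (n, L, 2) integer alleles + labels + coordinates."""

    genotypes: np.ndarray
    subpop: np.ndarray
    coords: np.ndarray | None = None
    mlg: np.ndarray | None = None
    mll: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        self.subpop = np.asarray(self.subpop)
        if self.genotypes.ndim != 3 or self.genotypes.shape[2] != 2:
            raise ValueError("genotypes must have shape (n, L, 2)")
        if self.subpop.shape[0] != self.genotypes.shape[0]:
            raise ValueError("subpop labels must match individuals")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def pops(self) -> np.ndarray:
        return np.unique(self.subpop)

    def pop_indices(self) -> dict:
        return {p: np.flatnonzero(self.subpop == p) for p in self.pops()}

    def subset(self, rows: np.ndarray) -> "SampleMatrix":
        return SampleMatrix(
            self.genotypes[rows],
            self.subpop[rows],
            None if self.coords is None else self.coords[rows],
            None if self.mlg is None else self.mlg[rows],
            None if self.mll is None else self.mll[rows],
        )

    def require_nonempty(self) -> None:
        if self.n == 0:
            raise ValueError("empty sample")


def sample_population(
    sim,
    max_trees: int | None = None,
    per_tree: int = 15,
    rng: np.random.Generator | int | None = None,
) -> SampleMatrix:
    """Random sample of up to `per_tree` plants from each occupied tree.

    With `max_trees` set, at most that many occupied trees are drawn at
    random (the protocol of density-sweep recording); otherwise every
    occupied tree contributes.
    """
    rng = np.random.default_rng(rng)
    alive = np.flatnonzero(sim.alive)
    hosts = sim.host[alive]
    occupied = np.unique(hosts)
    if max_trees is not None and occupied.size > max_trees:
        occupied = rng.choice(occupied, size=max_trees, replace=False)
    rows = []
    for h in occupied:
        members = alive[hosts == h]
        if members.size > per_tree:
            members = rng.choice(members, size=per_tree, replace=False)
        rows.append(members)
    if not rows:
        z = np.empty((0, sim.pool.n_loci, 2), dtype=np.int16)
        return SampleMatrix(z, np.empty(0, int), np.empty((0, 2)))
    rows = np.concatenate(rows)
    ps = sim.grid.patch_size
    coords = np.column_stack(
        ((sim.ix[rows] + 0.5) * ps, (sim.iy[rows] + 0.5) * ps)
    )
    return SampleMatrix(
        sim.genotypes[rows].copy(),
        sim.host[rows].copy(),
        coords,
        sim.mlg[rows].copy(),
        sim.mll[rows].copy(),
    )


# ----------------------------------------------------------------------
# allele bookkeeping
# ----------------------------------------------------------------------
def _locus_freqs(genotypes: np.ndarray, locus: int):
    """(alleles, counts, freqs) at one locus over all gene copies."""
    a = genotypes[:, locus, :].ravel()
    alleles, counts = np.unique(a, return_counts=True)
    return alleles, counts, counts / counts.sum()


def _unbiased_he(genotypes: np.ndarray, locus: int) -> float:
    """Nei's unbiased expected heterozygosity, correction 2N/(2N-1)."""
    _, counts, freqs = _locus_freqs(genotypes, locus)
    n_copies = counts.sum()
    raw = 1.0 - float(np.sum(freqs**2))
    if n_copies < 2:
        return 0.0
    return raw * n_copies / (n_copies - 1.0)


def expected_heterozygosity(genotypes: np.ndarray, unbiased: bool = True) -> float:
    """Mean expected heterozygosity over loci."""
    L = genotypes.shape[1]
    vals = []
    for l in range(L):
        if unbiased:
            vals.append(_unbiased_he(genotypes, l))
        else:
            _, _, f = _locus_freqs(genotypes, l)
            vals.append(1.0 - float(np.sum(f**2)))
    return float(np.mean(vals))


def observed_heterozygosity(genotypes: np.ndarray) -> float:
    return float((genotypes[:, :, 0] != genotypes[:, :, 1]).mean())


def _rarefied_richness(genotypes: np.ndarray, locus: int, g: int) -> float:
    """Expected allele count in a subsample of `g` gene copies."""
    _, counts, _ = _locus_freqs(genotypes, locus)
    n = counts.sum()
    if g >= n:
        return float(len(counts))
    # P(allele missing from the g-subsample) by the hypergeometric
    miss = hypergeom.pmf(0, n, counts, g)
    return float(np.sum(1.0 - miss))


def diversity_stats(sample: SampleMatrix):
    """Per-subpopulation diversity table and panel means.

    Returns ``(per_subpop: DataFrame, means: dict)``. Per subpopulation:
    A (alleles summed over loci), A_R (allelic richness rarefied to the
    smallest subpopulation), A_P (private alleles), H_E (unbiased), H_O.
    Means: K (alleles per locus averaged over loci and subpops), R (mean
    allele-size range), plus panel means of H_E/H_O.
    """
    sample.require_nonempty()
    idx = sample.pop_indices()
    L = sample.n_loci
    n_min = min(len(v) for v in idx.values())
    g = 2 * n_min
    # which subpops carry each allele, for private-allele counts
    carriers: dict[tuple[int, float], set] = {}
    for p, rows in idx.items():
        for l in range(L):
            for a in np.unique(sample.genotypes[rows, l, :]):
                carriers.setdefault((l, a), set()).add(p)
    out = []
    k_all, r_all = [], []
    for p, rows in idx.items():
        gt = sample.genotypes[rows]
        ks, rs, hes, ar = [], [], [], []
        a_p = 0
        for l in range(L):
            alleles, _, _ = _locus_freqs(gt, l)
            ks.append(len(alleles))
            rs.append(float(alleles.max() - alleles.min()))
            hes.append(_unbiased_he(gt, l))
            ar.append(_rarefied_richness(gt, l, g))
            a_p += sum(
                1 for a in alleles if carriers[(l, a)] == {p}
            )
        out.append(
            {
                "subpop": p,
                "n": len(rows),
                "A": int(np.sum(ks)),
                "A_R": float(np.mean(ar)),
                "A_P": a_p,
                "H_E": float(np.mean(hes)),
                "H_O": observed_heterozygosity(gt),
            }
        )
        k_all.append(np.mean(ks))
        r_all.append(np.mean(rs))
    per = pd.DataFrame(out).set_index("subpop")
    means = {
        "K": float(np.mean(k_all)),
        "R": float(np.mean(r_all)),
        "H_E": float(per["H_E"].mean()),
        "H_O": float(per["H_O"].mean()),
    }
    return per, means


# ----------------------------------------------------------------------
# F-statistics
# ----------------------------------------------------------------------
@dataclass
class FisResult:
    per_subpop: pd.Series
    mean: float
    p_values: pd.Series | None = None


def fis(sample: SampleMatrix, n_perm: int = 0,
        rng: np.random.Generator | int | None = None) -> FisResult:
    """Multilocus inbreeding coefficient 1 - H_O/H_E per subpopulation.

    Observed and expected heterozygosities are summed over loci before
    the ratio (loci weighted by their diversity). Significance of
    heterozygote deficit is assessed by permuting gene copies among the
    individuals of each subpopulation.
    """
    sample.require_nonempty()
    rng = np.random.default_rng(rng)

    def _fis_one(gt: np.ndarray) -> float:
        he = [_unbiased_he(gt, l) for l in range(gt.shape[1])]
        ho = [(gt[:, l, 0] != gt[:, l, 1]).mean() for l in range(gt.shape[1])]
        s_he = float(np.sum(he))
        if s_he == 0.0:
            return np.nan
        return 1.0 - float(np.sum(ho)) / s_he

    vals, pvals = {}, {}
    for p, rows in sample.pop_indices().items():
        gt = sample.genotypes[rows]
        obs = _fis_one(gt)
        vals[p] = obs
        if n_perm and np.isfinite(obs):
            hits = 0
            for _ in range(n_perm):
                perm = np.empty_like(gt)
                for l in range(gt.shape[1]):
                    copies = gt[:, l, :].ravel().copy()
                    rng.shuffle(copies)
                    perm[:, l, :] = copies.reshape(-1, 2)
                if _fis_one(perm) >= obs:
                    hits += 1
            pvals[p] = (hits + 1) / (n_perm + 1)
    per = pd.Series(vals, name="F_IS")
    return FisResult(per, float(per.mean(skipna=True)),
                     pd.Series(pvals) if pvals else None)


def _wc_components(genotypes: np.ndarray, subpop: np.ndarray):
    """Weir & Cockerham (1984) variance components summed over loci/alleles."""
    pops = np.unique(subpop)
    r = len(pops)
    if r < 2:
        raise ValueError("F_ST requires at least 2 subpopulations")
    a_sum = b_sum = c_sum = 0.0
    n_i = np.array([(subpop == p).sum() for p in pops], dtype=float)
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    L = genotypes.shape[1]
    for l in range(L):
        alleles = np.unique(genotypes[:, l, :])
        if len(alleles) < 2:
            continue
        for u in alleles:
            p_iu = np.empty(r)
            h_iu = np.empty(r)
            for k, p in enumerate(pops):
                g = genotypes[subpop == p, l, :]
                p_iu[k] = (g == u).mean()
                h_iu[k] = ((g == u).sum(axis=1) == 1).mean()
            pbar = (n_i * p_iu).sum() / (r * nbar)
            s2 = (n_i * (p_iu - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n_i * h_iu).sum() / (r * nbar)
            a = (nbar / nc) * (
                s2
                - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2.0
            a_sum += a
            b_sum += b
            c_sum += c
    return a_sum, b_sum, c_sum


def fst(sample: SampleMatrix) -> float:
    """Global Weir-Cockerham theta over all loci.

    Subpopulations of a single individual are excluded (with a warning);
    NaN is returned for monomorphic data.
    """
    sample.require_nonempty()
    sizes = {p: (sample.subpop == p).sum() for p in sample.pops()}
    drop = [p for p, s in sizes.items() if s < 2]
    if drop:
        logger.warning("excluding single-individual subpops from F_ST: %s", drop)
    keep = ~np.isin(sample.subpop, drop)
    gt, sp = sample.genotypes[keep], sample.subpop[keep]
    a, b, c = _wc_components(gt, sp)
    tot = a + b + c
    return a / tot if tot > 0 else np.nan


def fst_pairwise(sample: SampleMatrix, linearized: bool = False) -> pd.DataFrame:
    """Pairwise WC theta matrix; optionally Slatkin's F_ST/(1-F_ST)."""
    pops = [p for p in sample.pops() if (sample.subpop == p).sum() >= 2]
    skipped = set(sample.pops()) - set(pops)
    if skipped:
        logger.warning("excluding single-individual subpops: %s", sorted(skipped))
    m = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, p in enumerate(pops):
        for q in pops[i + 1:]:
            rows = np.isin(sample.subpop, [p, q])
            a, b, c = _wc_components(sample.genotypes[rows], sample.subpop[rows])
            tot = a + b + c
            v = a / tot if tot > 0 else np.nan
            if linearized:
                v = max(v, 0.0)
                v = v / (1.0 - v) if v < 1.0 else np.inf
            m.loc[p, q] = m.loc[q, p] = v
    return m


# ----------------------------------------------------------------------
# AMOVA
# ----------------------------------------------------------------------
@dataclass
class AmovaResult:
    pct_among: float
    pct_within: float
    sigma2_among: float
    sigma2_within: float
    p_value: float | None = None


def _squared_distances(genotypes: np.ndarray, metric: str) -> np.ndarray:
    """Condensed squared inter-individual genetic distances."""
    n, L, _ = genotypes.shape
    if metric == "identity":
        # per locus: 2 - (number of shared alleles, multiset sense)
        d2 = np.zeros((n, n))
        for l in range(L):
            g = np.sort(genotypes[:, l, :], axis=1)
            a0, a1 = g[:, 0], g[:, 1]
            share = (
                (a0[:, None] == a0[None, :]).astype(int)
                + (a1[:, None] == a1[None, :]).astype(int)
            )
            # heterozygote pairs sharing in the crossed configuration
            cross = (a0[:, None] == a1[None, :]).astype(int) + (
                a1[:, None] == a0[None, :]
            ).astype(int)
            het_i = (a0 != a1)[:, None] & (a0 != a1)[None, :]
            share = np.where(het_i & (cross > share), cross, share)
            d2 += 2 - share
        np.fill_diagonal(d2, 0.0)
        return d2
    if metric == "size":
        g = np.sort(genotypes, axis=2).reshape(n, -1).astype(float)
        return squareform(pdist(g, "sqeuclidean"))
    raise ValueError(f"unknown metric {metric!r}")


def amova(
    sample: SampleMatrix,
    n_perm: int = 999,
    metric: str = "identity",
    rng: np.random.Generator | int | None = None,
) -> AmovaResult:
    """Two-level AMOVA: variance among vs within subpopulations.

    Percentages always sum to 100 (the among component is clamped at 0);
    the permutation p-value shuffles individuals among subpopulations.
    """
    sample.require_nonempty()
    if len(sample.pops()) < 2:
        raise ValueError("AMOVA requires at least 2 subpopulations")
    rng = np.random.default_rng(rng)
    d2 = _squared_distances(sample.genotypes, metric)

    def components(labels: np.ndarray):
        n = len(labels)
        pops, counts = np.unique(labels, return_counts=True)
        ssd_t = d2.sum() / (2.0 * n)
        ssd_w = 0.0
        for p, np_ in zip(pops, counts):
            rows = np.flatnonzero(labels == p)
            ssd_w += d2[np.ix_(rows, rows)].sum() / (2.0 * np_)
        ssd_a = ssd_t - ssd_w
        df_a = len(pops) - 1
        df_w = n - len(pops)
        s2_w = ssd_w / df_w if df_w > 0 else 0.0
        nprime = (n - (counts**2).sum() / n) / df_a
        s2_a = (ssd_a / df_a - s2_w) / nprime
        return s2_a, s2_w

    s2_a, s2_w = components(sample.subpop)
    s2_a_c = max(s2_a, 0.0)
    tot = s2_a_c + s2_w
    pct_among = 100.0 * s2_a_c / tot if tot > 0 else 0.0
    p_val = None
    if n_perm:
        hits = 0
        labels = sample.subpop.copy()
        for _ in range(n_perm):
            rng.shuffle(labels)
            pa, _ = components(labels)
            if pa >= s2_a:
                hits += 1
        p_val = (hits + 1) / (n_perm + 1)
    return AmovaResult(pct_among, 100.0 - pct_among, s2_a, s2_w, p_val)


# ----------------------------------------------------------------------
# Garza-Williamson
# ----------------------------------------------------------------------
def garza_williamson(sample: SampleMatrix) -> float:
    """Mean modified Garza-Williamson statistic M = k/(R+1).

    k is the allele count and R the allele-size range (in repeats) of a
    locus within a subpopulation; M is averaged over loci and subpops.
    """
    sample.require_nonempty()
    vals = []
    for _, rows in sample.pop_indices().items():
        gt = sample.genotypes[rows]
        for l in range(sample.n_loci):
            alleles = np.unique(gt[:, l, :])
            vals.append(len(alleles) / (float(alleles.max() - alleles.min()) + 1.0))
    return float(np.mean(vals))


# ----------------------------------------------------------------------
# kinship and spatial genetic structure
# ----------------------------------------------------------------------
def loiselle_kinship(sample: SampleMatrix) -> np.ndarray:
    """Pairwise Loiselle et al. (1995) kinship matrix.

    Reference allele frequencies are taken from the whole sample;
    monomorphic loci contribute nothing. Includes the small-sample
    bias correction p(1-p)/(n-1) in the numerator.
    """
    sample.require_nonempty()
    n, L = sample.n, sample.n_loci
    cols, pbar = [], []
    for l in range(L):
        alleles, _, freqs = _locus_freqs(sample.genotypes, l)
        if len(alleles) < 2:
            continue
        for a, f in zip(alleles, freqs):
            x = (sample.genotypes[:, l, :] == a).sum(axis=1) / 2.0
            cols.append(x)
            pbar.append(f)
    if not cols:
        raise ValueError("no polymorphic loci for kinship")
    X = np.column_stack(cols)
    P = np.asarray(pbar)
    dev = X - P
    denom = float(np.sum(P * (1 - P)))
    corr = float(np.sum(P * (1 - P) / (n - 1))) if n > 1 else 0.0
    F = (dev @ dev.T + corr) / denom
    return F


@dataclass
class SpResult:
    """Kinship correlogram and the Sp statistic with its permutation null."""

    class_edges: np.ndarray          # distance-class upper bounds (m)
    class_kinship: np.ndarray        # mean F_ij per class
    class_pairs: np.ndarray          # pair counts per class
    b_slope: float                   # slope of F_ij on ln(distance)
    f1: float                        # mean kinship in the first class
    sp: float
    p_value: float | None = None
    envelope: np.ndarray | None = None  # (2, n_classes) 95% null band
    class_p: np.ndarray | None = None


def sp_statistic(
    sample: SampleMatrix,
    n_classes: int = 7,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> SpResult:
    """Spatial genetic structure: kinship decay over pair-balanced
    distance classes and Sp = -b_F / (1 - F_(1)).

    Distance classes are pair-count quantiles (class sizes differ by at
    most one pair). The null distribution randomly shuffles individual
    locations (equivalently, permutes the kinship matrix against the
    fixed distance matrix).
    """
    sample.require_nonempty()
    if sample.coords is None:
        raise ValueError("coordinates required for Sp")
    if n_classes < 2:
        raise ValueError("need at least 2 distance classes")
    rng = np.random.default_rng(rng)
    n = sample.n
    D = squareform(pdist(sample.coords))
    iu = np.triu_indices(n, 1)
    d = np.maximum(D[iu], MIN_LOG_DISTANCE)
    if np.ptp(d) == 0.0:
        raise ValueError("all individuals at a single location")
    lnd = np.log(d)
    F = loiselle_kinship(sample)
    f = F[iu]
    n_pairs = d.size
    order = np.argsort(d, kind="stable")
    # pair-balanced classes: contiguous rank chunks, sizes differ <= 1
    base, extra = divmod(n_pairs, n_classes)
    sizes = np.full(n_classes, base) + (np.arange(n_classes) < extra)
    cls = np.empty(n_pairs, dtype=np.int64)
    cls[order] = np.repeat(np.arange(n_classes), sizes)
    edges = np.array([d[order][np.cumsum(sizes) - 1][k] for k in range(n_classes)])

    var_lnd = float(np.var(lnd))
    cov = float(np.mean(lnd * f) - np.mean(lnd) * np.mean(f))
    b = cov / var_lnd
    f1 = float(f[cls == 0].mean())
    sp = -b / (1.0 - f1) if f1 < 1.0 else np.nan
    class_kin = np.array([f[cls == k].mean() for k in range(n_classes)])

    p_val = env = class_p = None
    if n_perm:
        sp_null = np.empty(n_perm)
        class_null = np.empty((n_perm, n_classes))
        mean_lnd = np.mean(lnd)
        for it in range(n_perm):
            perm = rng.permutation(n)
            fp = F[np.ix_(perm, perm)][iu]
            bp = (float(np.mean(lnd * fp)) - mean_lnd * np.mean(fp)) / var_lnd
            f1p = fp[cls == 0].mean()
            sp_null[it] = -bp / (1.0 - f1p) if f1p < 1.0 else np.nan
            for k in range(n_classes):
                class_null[it, k] = fp[cls == k].mean()
        p_val = (np.sum(sp_null >= sp) + 1.0) / (n_perm + 1.0)
        env = np.percentile(class_null, [2.5, 97.5], axis=0)
        class_p = (
            (class_null >= class_kin[None, :]).sum(axis=0) + 1.0
        ) / (n_perm + 1.0)
    return SpResult(edges, class_kin, sizes, b, f1, sp, p_val, env, class_p)


# ----------------------------------------------------------------------
# turnover
# ----------------------------------------------------------------------
def turnover(sample: SampleMatrix, level: str = "mlg") -> float:
    """Whittaker-normalised among-subpopulation turnover in [0, 1].

    T/O = (gamma/alpha_bar - 1)/(S - 1) on presence/absence (Hill order
    q = 0) of the chosen units: alleles, MLGs or MLLs.
    """
    sample.require_nonempty()
    idx = sample.pop_indices()
    S = len(idx)
    if S < 2:
        raise ValueError("turnover requires at least 2 subpopulations")

    def units(rows) -> set:
        if level == "allele":
            out = set()
            for l in range(sample.n_loci):
                out.update((l, a) for a in np.unique(sample.genotypes[rows, l, :]))
            return out
        if level == "mlg":
            if sample.mlg is None:
                raise ValueError("sample lacks MLG labels")
            return set(np.unique(sample.mlg[rows]))
        if level == "mll":
            if sample.mll is None:
                raise ValueError("sample lacks MLL labels")
            return set(np.unique(sample.mll[rows]))
        raise ValueError(f"unknown level {level!r}")

    per_pop = [units(rows) for rows in idx.values()]
    gamma = len(set().union(*per_pop))
    alpha = float(np.mean([len(u) for u in per_pop]))
    return (gamma / alpha - 1.0) / (S - 1.0)


# ----------------------------------------------------------------------
# genetic distances and isolation by distance
# ----------------------------------------------------------------------
def _pop_freq_table(sample: SampleMatrix):
    """Per-subpop allele-frequency matrices aligned over a common allele set."""
    pops = list(sample.pops())
    tables = []
    for l in range(sample.n_loci):
        alleles = np.unique(sample.genotypes[:, l, :])
        tab = np.zeros((len(pops), len(alleles)))
        for i, p in enumerate(pops):
            g = sample.genotypes[sample.subpop == p, l, :].ravel()
            for j, a in enumerate(alleles):
                tab[i, j] = (g == a).mean()
        tables.append(tab)
    return pops, tables


def genetic_distance(sample: SampleMatrix, metric: str) -> pd.DataFrame:
    """Pairwise subpopulation genetic distances.

    Metrics: ``linearized_fst`` (Slatkin), ``edwards`` (Cavalli-Sforza &
    Edwards chord), ``nei`` (standard distance), ``reynolds`` (coancestry).
    """
    if metric == "linearized_fst":
        return fst_pairwise(sample, linearized=True)
    pops, tables = _pop_freq_table(sample)
    L = len(tables)
    m = pd.DataFrame(0.0, index=pops, columns=pops)
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            if metric == "edwards":
                s = np.mean([np.sqrt(t[i] * t[j]).sum() for t in tables])
                v = math.sqrt(max(1.0 - s, 0.0))
            elif metric == "nei":
                jxy = np.mean([np.sum(t[i] * t[j]) for t in tables])
                jx = np.mean([np.sum(t[i] ** 2) for t in tables])
                jy = np.mean([np.sum(t[j] ** 2) for t in tables])
                v = -math.log(jxy / math.sqrt(jx * jy)) if jxy > 0 else np.inf
            elif metric == "reynolds":
                num = np.sum([np.sum((t[i] - t[j]) ** 2) for t in tables])
                den = 2.0 * np.sum([1.0 - np.sum(t[i] * t[j]) for t in tables])
                v = num / den if den > 0 else 0.0
            else:
                raise ValueError(f"unknown metric {metric!r}")
            m.iloc[i, j] = m.iloc[j, i] = v
    return m


def mantel_ibd(
    sample: SampleMatrix,
    metric: str = "linearized_fst",
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Mantel test of genetic distance against ln(geographic distance).

    Subpopulation positions are member-coordinate centroids. Returns
    (r, p). Raises on zero-variance distance matrices.
    """
    from skbio import DistanceMatrix
    from skbio.stats.distance import mantel

    if sample.coords is None:
        raise ValueError("coordinates required")
    pops = list(sample.pops())
    if len(pops) < 3:
        raise ValueError("Mantel needs >= 3 subpopulations")
    cent = np.array(
        [sample.coords[sample.subpop == p].mean(axis=0) for p in pops]
    )
    geo = squareform(pdist(cent))
    geo = np.log(np.maximum(geo, MIN_LOG_DISTANCE))
    np.fill_diagonal(geo, 0.0)
    gen = genetic_distance(sample, metric)
    gen = gen.loc[pops, pops].to_numpy(dtype=float)
    for mname, m in (("genetic", gen), ("geographic", geo)):
        if np.ptp(squareform(m, checks=False)) == 0.0:
            raise ValueError(f"zero-variance {mname} distance matrix")
    seed = int(np.random.default_rng(rng).integers(2**31 - 1))
    r, p, _ = mantel(
        DistanceMatrix(gen), DistanceMatrix(geo),
        permutations=n_perm, seed=seed,
    )
    return float(r), float(p)


# ----------------------------------------------------------------------
# the ABC summary vector
# ----------------------------------------------------------------------
STAT_NAMES = ("K", "R", "H_E", "F_IS", "F_ST", "NGW")


def stat_vector(sample: SampleMatrix) -> dict:
    """The six-statistic summary used for calibration.

    K (mean alleles/locus), R (mean allele-size range), H_E, multilocus
    F_IS, global WC F_ST, and the mean modified Garza-Williamson M.
    """
    sample.require_nonempty()
    _, means = diversity_stats(sample)
    out = {
        "K": means["K"],
        "R": means["R"],
        "H_E": means["H_E"],
        "F_IS": fis(sample).mean,
        "NGW": garza_williamson(sample),
    }
    try:
        out["F_ST"] = fst(sample)
    except ValueError:
        out["F_ST"] = np.nan
    return {k: out[k] for k in STAT_NAMES}
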