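"""Experiment drivers: temporal, density-sweep and dynamic-landscape runs.

Three families of replicated simulations probe how the spatial genetic
structure (SGS) of an epiphyte population develops:

``time``
    colonisation of a fixed ~0.2 ha, ~20-tree grove followed yearly for
    50 years; yields the Lag / Log / Stationary phase structure of the
    abundance curve and the SGS trajectory.
``density``
    static 0.4 ha landscapes spanning 5-150 trees, recorded after 30
    years; locates the tree densities that minimise/maximise abundance
    and differentiation.
``dynamic``
    30 years on a static stand, then an abrupt deforestation or
    reforestation event, then 30 more years with tree growth, Yoda
    self-thinning and natural regeneration switched on.

Replicate seeds derive deterministically from a master seed, so every
experiment re-run reproduces its outputs exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genetics import default_pool, random_founder_genotype, self_offspring
from .genepop import write_genepop
from .ibm import SimParams, SpreadSimulation
from .landscape import (
    DensityChangeEvent,
    apply_density_change,
    build_empirical_like_grove,
    build_static_landscape,
    step_tree_dynamics,
)
from .sumstats import SampleMatrix, sample_population, stat_vector, diversity_stats

logger = logging.getLogger(__name__)

#: a yearly sample is reduced to statistics only once this established;
#: sparser samples are recorded as missing (pre-establishment instability)
MIN_STAT_N = 30
MIN_STAT_POPS = 3

TRAJ_STATS = ("K", "R", "H_E", "F_IS", "F_ST", "NGW")

#: the density sweep spans 5-150 trees on 0.4 ha, with 150 trees "filling"
#: the landscape: identical crowns sized so 150 of them saturate the area
FULL_STAND_TREES = 150


def stand_crown_radius(area_ha: float = 0.4,
                       n_full: int = FULL_STAND_TREES) -> float:
    """Crown radius (m) at which `n_full` equal crowns tile `area_ha`."""
    return float(np.sqrt(area_ha * 10_000.0 / (n_full * np.pi)))


def _stand(area_ha: float, n_trees: int, rng):
    """A density/dynamic-experiment stand: equal saturating crowns, DBH
    consistent with the crown allometry so later growth is seamless."""
    from .landscape import CROWN_PER_DBH

    r = stand_crown_radius(area_ha)
    return build_static_landscape(
        area_ha, n_trees, crown_radius=r, dbh=r / CROWN_PER_DBH, rng=rng
    )


def _rep_rngs(master_seed: int, n: int):
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(master_seed).spawn(n)]


def _year_record(year: int, sim: SpreadSimulation, rng) -> dict:
    rec = {
        "year": year,
        "abundance": sim.abundance,
        "n_mll": sim.n_mll,
        "n_mlg": sim.n_mlg,
        "clone_fraction": sim.clone_fraction,
        "tree_density": sim.grid.density_per_ha(),
        "ground_cover": sim.grid.ground_cover(),
    }
    sample = sample_population(sim, per_tree=15, rng=rng)
    stats_ok = sample.n >= MIN_STAT_N and len(sample.pops()) >= MIN_STAT_POPS
    if stats_ok:
        sv = stat_vector(sample)
        per, _ = diversity_stats(sample)
        rec.update(sv)
        rec["A"] = float(per["A"].mean())
    else:
        rec.update({k: np.nan for k in TRAJ_STATS})
        rec["A"] = np.nan
    return rec


def detect_phases(abundance: pd.Series) -> tuple[float, float]:
    """(lag_end, log_end) years from a pooled mean abundance curve.

    The plateau level is the mean over the last five recorded years. The
    Lag phase ends when abundance first exceeds 5% of the plateau; the
    Log phase ends at the inflection of the saturating curve, located as
    the first year abundance crosses half the plateau.
    """
    plateau = abundance.iloc[-5:].mean()
    if plateau <= 0:
        raise ValueError("population never established")
    above = abundance[abundance > 0.05 * plateau]
    lag_end = float(above.index[0]) if len(above) else np.nan
    above = abundance[abundance > 0.50 * plateau]
    log_end = float(above.index[0]) if len(above) else np.nan
    return lag_end, log_end


def _summarise(records: pd.DataFrame, by: str = "year") -> pd.DataFrame:
    """Replicate mean and normal-approximation 95% CI per recorded step."""
    num = records.drop(columns=["replicate"]).groupby(by)
    mean = num.mean()
    sd = num.std()
    cnt = num.count().clip(lower=1)
    half = 1.96 * sd / np.sqrt(cnt)
    out = mean.join(half, lsuffix="", rsuffix="_ci95")
    return out


@dataclass
class TimeExperimentResult:
    records: pd.DataFrame       # one row per (replicate, year)
    summary: pd.DataFrame       # replicate means + 95% CI per year
    lag_end: float
    log_end: float

    def peak_abundance(self) -> float:
        """Replicate-mean of each run's maximum yearly abundance."""
        return float(self.records.groupby("replicate")["abundance"].max().mean())

    def individuals_per_mll_at_peak(self) -> float:
        peaks = self.records.loc[
            self.records.groupby("replicate")["abundance"].idxmax()
        ]
        ratio = peaks["abundance"] / peaks["n_mll"].replace(0, np.nan)
        return float(ratio.mean())

    def mll_at_log_end(self) -> float:
        yr = int(round(self.log_end))
        sub = self.records[self.records["year"] == yr]
        return float(sub["n_mll"].mean())

    def max_fst_during_lag(self, lag_years: float = 10.0) -> float:
        """Peak of the replicate-mean yearly F_ST curve over the Lag era
        (the quantity a pooled differentiation trajectory displays)."""
        curve = self.summary.loc[self.summary.index <= lag_years, "F_ST"]
        return float(curve.max())


def run_time_experiment(
    replicates: int = 20,
    years: int = 50,
    master_seed: int = 0,
    params: SimParams | None = None,
    grid=None,
    out_dir: str | Path | None = None,
) -> TimeExperimentResult:
    """Replicated colonisation of one fixed empirical-like grove.

    The grove itself is built once from the master seed (the landscape is
    an input, not a replicate-level random quantity); replicates differ
    only in the demographic/genetic randomness.
    """
    params = params or SimParams.posterior_median()
    if grid is None:
        grid = build_empirical_like_grove(
            np.random.default_rng(np.random.SeedSequence((master_seed, 0xA11)))
        )
    rngs = _rep_rngs(master_seed, replicates)
    rows = []
    for rep, rng in enumerate(rngs):
        sim = SpreadSimulation(grid, params, rng, pool=default_pool())
        recs: list[dict] = []
        sim.run_years(years, lambda y, s: recs.append(_year_record(y, s, rng)))
        for r in recs:
            r["replicate"] = rep
        rows.extend(recs)
        logger.info("time replicate %d/%d done (peak %d plants)",
                    rep + 1, replicates, max(r["abundance"] for r in recs))
    records = pd.DataFrame(rows)
    summary = _summarise(records)
    lag_end, log_end = detect_phases(summary["abundance"])
    result = TimeExperimentResult(records, summary, lag_end, log_end)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records.to_csv(out / "time_records.csv", index=False)
        summary.to_csv(out / "time_summary.csv")
        (out / "time_phases.json").write_text(
            json.dumps({"lag_end": lag_end, "log_end": log_end})
        )
    return result


@dataclass
class DensityExperimentResult:
    records: pd.DataFrame       # one row per (density, replicate)
    summary: pd.DataFrame       # means + CI per density
    extrema: dict


def run_density_experiment(
    tree_counts=(8, 30, 76, 110, 150),
    area_ha: float = 0.4,
    years: int = 30,
    replicates: int = 3,
    master_seed: int = 0,
    params: SimParams | None = None,
    out_dir: str | Path | None = None,
) -> DensityExperimentResult:
    """Static-landscape density sweep recorded after `years` years.

    Samples up to 15 plants on up to 15 random occupied trees per run and
    reports per-density summaries plus the densities at which abundance
    and differentiation peak or dip.
    """
    params = params or SimParams.posterior_median()
    rows = []
    rngs = _rep_rngs(master_seed, len(tree_counts) * replicates)
    k = 0
    for n_trees in tree_counts:
        for rep in range(replicates):
            rng = rngs[k]
            k += 1
            grid = _stand(area_ha, n_trees, rng)
            sim = SpreadSimulation(grid, params, rng, pool=default_pool())
            sim.run_years(years)
            sample = sample_population(sim, max_trees=15, per_tree=15, rng=rng)
            rec = {
                "density": n_trees / area_ha,
                "n_trees": n_trees,
                "replicate": rep,
                "abundance": sim.abundance,
                "n_mll": sim.n_mll,
                "clone_fraction": sim.clone_fraction,
            }
            if sample.n >= MIN_STAT_N and len(sample.pops()) >= MIN_STAT_POPS:
                rec.update(stat_vector(sample))
            else:
                rec.update({s: np.nan for s in TRAJ_STATS})
            rows.append(rec)
        logger.info("density %d trees done", n_trees)
    records = pd.DataFrame(rows)
    summary = _summarise(records.drop(columns=["n_trees"]), by="density")
    extrema = {
        "density_min_abundance": float(summary["abundance"].idxmin()),
        "density_max_abundance": float(summary["abundance"].idxmax()),
        "max_abundance": float(summary["abundance"].max()),
        "n_mll_at_max_abundance": float(
            summary.loc[summary["abundance"].idxmax(), "n_mll"]
        ),
        "density_min_fst": float(summary["F_ST"].idxmin()),
        "density_max_fst": float(summary["F_ST"].idxmax()),
    }
    result = DensityExperimentResult(records, summary, extrema)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records.to_csv(out / "density_records.csv", index=False)
        summary.to_csv(out / "density_summary.csv")
        (out / "density_extrema.json").write_text(json.dumps(extrema))
    return result


def run_dynamic_experiment(
    initial_trees_per_ha: float = 375.0,
    event: DensityChangeEvent | None = None,
    area_ha: float = 0.4,
    years_static: int = 30,
    years_dynamic: int = 30,
    replicates: int = 3,
    master_seed: int = 0,
    params: SimParams | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Static spin-up, an abrupt density-change event, then a dynamic era.

    During the dynamic era trees grow (0.13 cm DBH/year), self-thin on
    Yoda's -3/2 line and regenerate naturally on open ground, while the
    epiphyte population keeps stepping monthly. Returns yearly records
    (replicate, year, abundance, n_mll, A, H_E, F_ST, tree density,
    ground cover); the event is applied at the end of `years_static`.
    """
    params = params or SimParams.posterior_median()
    event = event or DensityChangeEvent("deforest", 0.0)
    n_trees = int(round(initial_trees_per_ha * area_ha))
    rows = []
    for rep, rng in enumerate(_rep_rngs(master_seed, replicates)):
        grid = _stand(area_ha, n_trees, rng)
        sim = SpreadSimulation(grid, params, rng, pool=default_pool())
        recs: list[dict] = []
        sim.run_years(years_static,
                      lambda y, s: recs.append(_year_record(y, s, rng)))
        apply_density_change(grid, event, rng)
        for _ in range(years_dynamic):
            step_tree_dynamics(grid, dt=1.0, rng=rng)
            sim.run_years(1)
            recs.append(_year_record(len(recs) + 1, sim, rng))
        for r in recs:
            r["replicate"] = rep
        rows.extend(recs)
        logger.info("dynamic replicate %d/%d done", rep + 1, replicates)
    records = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records.to_csv(out / "dynamic_records.csv", index=False)
        _summarise(records).to_csv(out / "dynamic_summary.csv")
    return records


# ----------------------------------------------------------------------
# deterministic fixtures for tests and demos
# ----------------------------------------------------------------------
def make_fixtures(kind: str, rng: np.random.Generator | int | None = None,
                  out_dir: str | Path | None = None):
    """Small deterministic inputs: ``toy_grove``, ``toy_genotypes``,
    ``hwe_panel``, ``selfing_pedigree``.

    Returns the in-memory object; with `out_dir` the fixture is also
    written (layout CSV or Genepop file).
    """
    rng = np.random.default_rng(rng)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if kind == "toy_grove":
        grid = build_empirical_like_grove(rng)
        if out is not None:
            grid.to_layout_csv(out / "toy_grove.csv")
        return grid

    pool = default_pool()
    if kind == "toy_genotypes":
        # two subpopulations drawn from the shared regional pool
        g = random_founder_genotype(pool, 0.39, rng, n=40)
        sample = SampleMatrix(g, np.repeat([0, 1], 20),
                              coords=rng.uniform(0, 40, size=(40, 2)))
        if out is not None:
            write_genepop(sample, out / "toy_genotypes.gen")
        return sample

    if kind == "hwe_panel":
        # random union of gametes from the pool frequencies: F_IS ~ 0
        n, L = 100, pool.n_loci
        g = np.empty((n, L, 2), dtype=np.int16)
        for l in range(L):
            g[:, l, :] = rng.choice(
                pool.alleles[l], size=(n, 2), p=pool.freqs[l]
            )
        g.sort(axis=2)
        sample = SampleMatrix(g, np.repeat([0, 1], n // 2),
                              coords=rng.uniform(0, 40, size=(n, 2)))
        if out is not None:
            write_genepop(sample, out / "hwe_panel.gen")
        return sample

    if kind == "selfing_pedigree":
        # non-inbred parents + their selfed offspring over an unrelated pool
        n_pairs, n_pool = 30, 60
        parents = random_founder_genotype(pool, 0.8, rng, n=n_pairs)
        offspring = np.stack([self_offspring(p, 0.0, rng) for p in parents])
        unrelated = random_founder_genotype(pool, 0.39, rng, n=n_pool)
        g = np.concatenate([parents, offspring, unrelated])
        n = len(g)
        sample = SampleMatrix(g, np.zeros(n, dtype=int),
                              coords=rng.uniform(0, 40, size=(n, 2)))
        pairs = [(i, n_pairs + i) for i in range(n_pairs)]
        if out is not None:
            write_genepop(sample, out / "selfing_pedigree.gen")
        return sample, pairs

    raise ValueError(f"unknown fixture kind {kind!r}")
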