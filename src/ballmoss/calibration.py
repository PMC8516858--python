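"""Approximate Bayesian computation for the spread simulator.

Workflow: draw parameter vectors from the prior, run one simulation per
draw, reduce each simulated SSR sample to the six-statistic summary
vector (K, R, H_E, F_IS, F_ST, NGW), and retain the draws whose
summaries fall closest (MAD-standardised Euclidean distance) to the
observed vector. An optional local-linear regression adjustment sharpens
the retained sample. The fitted object follows the Model/Results
convention: ``ABCCalibration(observed, table).fit()`` returns an
:class:`ABCResults` carrying the posterior draws, point estimates,
credible intervals and a ``summary()`` table.

Also here: global sensitivity analysis (rank correlations of each
parameter against each output) and leave-some-out cross-validation of
parameter recoverability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genetics import default_pool
from .ibm import SimParams, SpreadSimulation
from .landscape import build_empirical_like_grove
from .sumstats import STAT_NAMES, sample_population, stat_vector

logger = logging.getLogger(__name__)

PARAM_NAMES = (
    "regional_seed_rain",
    "wind_speed",
    "mutation_rate",
    "germination_rate",
    "capture_probability",
)

#: parameters handled on the log10 scale in regression adjustment and CV
LOG_PARAMS = ("mutation_rate",)


@dataclass
class PriorSpec:
    """Independent priors of the five free parameters.

    Uniform ranges for seed rain, wind, germination and capture; the SSR
    mutation rate is Normal on the log10 scale (mean -4, sd 0.5)
    truncated to [-6, -2].
    """

    seed_rain_range: tuple[float, float] = (100.0, 500.0)
    wind_range: tuple[float, float] = (1.0, 20.0)
    log10_mu_mean: float = -4.0
    log10_mu_sd: float = 0.5
    log10_mu_range: tuple[float, float] = (-6.0, -2.0)
    germination_range: tuple[float, float] = (0.0083, 0.30)
    capture_range: tuple[float, float] = (0.01, 0.30)

    def sample(self, n: int, rng: np.random.Generator | int | None = None
               ) -> pd.DataFrame:
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(rng)
        lo, hi = self.log10_mu_range
        a = (lo - self.log10_mu_mean) / self.log10_mu_sd
        b = (hi - self.log10_mu_mean) / self.log10_mu_sd
        log_mu = sps.truncnorm.rvs(
            a, b, loc=self.log10_mu_mean, scale=self.log10_mu_sd,
            size=n, random_state=rng,
        )
        return pd.DataFrame(
            {
                "regional_seed_rain": rng.uniform(*self.seed_rain_range, size=n),
                "wind_speed": rng.uniform(*self.wind_range, size=n),
                "mutation_rate": 10.0**log_mu,
                "germination_rate": rng.uniform(*self.germination_range, size=n),
                "capture_probability": rng.uniform(*self.capture_range, size=n),
            }
        )


def sample_prior(spec: PriorSpec, n: int,
                 rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    return spec.sample(n, rng)


# ----------------------------------------------------------------------
# reference table
# ----------------------------------------------------------------------
@dataclass
class ReferenceConfig:
    """Simulation pipeline behind every reference-table row.

    Defaults mirror the calibration setting: colonisation of an
    empirical-like ~20-tree grove for 20 years (the stand age of the
    field site), sampled at up to 15 plants per occupied tree.
    """

    n_trees: int = 20
    extent: tuple[float, float] = (45.0, 45.0)
    max_span: float = 47.5
    years: int = 20
    per_tree: int = 15
    max_trees: int | None = None
    fixed_params: dict = field(default_factory=dict)

    @classmethod
    def reduced(cls) -> "ReferenceConfig":
        """Desk-scale variant for fast tables: a 12-tree ~0.13 ha grove
        followed for 15 years (~0.05 s per row)."""
        return cls(n_trees=12, extent=(36.0, 36.0), max_span=34.0, years=15)


def simulate_stats(theta: dict, config: ReferenceConfig,
                   rng: np.random.Generator | int | None = None) -> dict:
    """One simulation -> summary statistics (plus abundance and n_MLL)."""
    rng = np.random.default_rng(rng)
    grid = build_empirical_like_grove(
        rng, n_trees=config.n_trees, extent=config.extent,
        max_span=config.max_span,
    )
    params = SimParams(**{**theta, **config.fixed_params})
    sim = SpreadSimulation(grid, params, rng, pool=default_pool())
    sim.run_years(config.years)
    sample = sample_population(
        sim, max_trees=config.max_trees, per_tree=config.per_tree, rng=rng
    )
    if sample.n < 10 or len(sample.pops()) < 2:
        raise RuntimeError(
            f"population too sparse for summary statistics (n={sample.n})"
        )
    out = stat_vector(sample)
    out["abundance"] = sim.abundance
    out["n_MLL"] = sim.n_mll
    return out


@dataclass
class ReferenceTable:
    """Rows of (parameter vector, summary-statistic vector)."""

    params: pd.DataFrame
    stats: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.params)

    def to_csv(self, path_prefix: str) -> None:
        self.params.to_csv(f"{path_prefix}_params.csv", index=False)
        self.stats.to_csv(f"{path_prefix}_stats.csv", index=False)

    @classmethod
    def from_csv(cls, path_prefix: str) -> "ReferenceTable":
        return cls(
            pd.read_csv(f"{path_prefix}_params.csv"),
            pd.read_csv(f"{path_prefix}_stats.csv"),
        )

    def append(self, other: "ReferenceTable") -> "ReferenceTable":
        return ReferenceTable(
            pd.concat([self.params, other.params], ignore_index=True),
            pd.concat([self.stats, other.stats], ignore_index=True),
            self.meta,
        )


def build_reference_table(
    prior: PriorSpec,
    n_sims: int,
    config: ReferenceConfig | None = None,
    rng: np.random.Generator | int | None = None,
    progress: bool = False,
) -> ReferenceTable:
    """Simulate `n_sims` draws from the prior into a reference table.

    Failed rows (simulations too sparse to yield the statistics) are
    logged and dropped, never imputed.
    """
    config = config or ReferenceConfig()
    root = np.random.default_rng(rng)
    seeds = root.bit_generator._seed_seq.spawn(n_sims) if hasattr(
        root.bit_generator, "_seed_seq"
    ) else None
    thetas = prior.sample(n_sims, root)
    rows_p, rows_s = [], []
    n_failed = 0
    for i in range(n_sims):
        row_rng = np.random.default_rng(seeds[i]) if seeds is not None else root
        theta = thetas.iloc[i].to_dict()
        try:
            s = simulate_stats(theta, config, row_rng)
        except RuntimeError as exc:
            n_failed += 1
            logger.debug("row %d dropped: %s", i, exc)
            continue
        if any(not np.isfinite(v) for v in s.values()):
            n_failed += 1
            continue
        rows_p.append(theta)
        rows_s.append(s)
        if progress and (i + 1) % 100 == 0:
            logger.info("reference table: %d/%d rows", i + 1, n_sims)
    if n_failed:
        logger.warning("dropped %d of %d reference rows", n_failed, n_sims)
    return ReferenceTable(
        pd.DataFrame(rows_p), pd.DataFrame(rows_s),
        meta={"n_requested": n_sims, "n_failed": n_failed,
              "config": vars(config).copy()},
    )


# ----------------------------------------------------------------------
# rejection ABC (Model / Results)
# ----------------------------------------------------------------------
class ABCCalibration:
    """Rejection-ABC model: observed summaries + a reference table.

    ``fit`` standardises each statistic by its table MAD, ranks rows by
    Euclidean distance to the observed vector, retains the `tolerance`
    fraction, and optionally applies an Epanechnikov-weighted local
    linear regression adjustment.
    """

    def __init__(
        self,
        observed: dict | pd.Series,
        table: ReferenceTable,
        stat_names: tuple = STAT_NAMES,
        log_params: tuple = LOG_PARAMS,
    ):
        self.observed = pd.Series(observed)
        self.table = table
        self.stat_names = [s for s in stat_names if s in table.stats.columns]
        self.param_names = list(table.params.columns)
        self.log_params = [p for p in log_params if p in self.param_names]
        missing = set(self.stat_names) - set(self.observed.index)
        if missing:
            raise ValueError(f"observed vector lacks statistics: {sorted(missing)}")

    def _standardise(self):
        S = self.table.stats[self.stat_names].to_numpy(float)
        obs = self.observed[self.stat_names].to_numpy(float)
        mad = sps.median_abs_deviation(S, axis=0, scale="normal")
        keep = mad > 0
        if not keep.all():
            dropped = [s for s, k in zip(self.stat_names, keep) if not k]
            logger.warning("dropping constant statistics: %s", dropped)
        return S[:, keep] / mad[keep], obs[keep] / mad[keep]

    def fit(self, tolerance: float = 0.001, adjust: str = "loclinear"
            ) -> "ABCResults":
        if adjust not in ("none", "loclinear"):
            raise ValueError("adjust must be 'none' or 'loclinear'")
        n = len(self.table)
        n_keep = int(round(tolerance * n))
        if n_keep < 1:
            raise ValueError(
                f"tolerance {tolerance} retains no rows from a {n}-row table"
            )
        S, obs = self._standardise()
        d = np.sqrt(((S - obs) ** 2).sum(axis=1))
        order = np.argsort(d, kind="stable")[:n_keep]  # ties: lowest row index
        theta = self.table.params.iloc[order].reset_index(drop=True).copy()
        d_keep = d[order]
        if adjust == "loclinear":
            theta = self._loclinear(theta, S[order], obs, d_keep)
        return ABCResults(self, theta, d_keep, order, tolerance, adjust)

    def _loclinear(self, theta, S_keep, obs, d_keep):
        dmax = d_keep.max()
        w = 1.0 - (d_keep / dmax) ** 2 if dmax > 0 else np.ones_like(d_keep)
        w = np.maximum(w, 1e-8)
        X = np.column_stack([np.ones(len(S_keep)), S_keep - obs])
        WX = X * w[:, None]
        adj = theta.copy()
        for p in self.param_names:
            y = theta[p].to_numpy(float)
            if p in self.log_params:
                y = np.log10(y)
            beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ y, rcond=None)
            y_adj = y - X[:, 1:] @ beta[1:]
            adj[p] = 10.0**y_adj if p in self.log_params else y_adj
        return adj


class ABCResults:
    """Posterior sample from rejection ABC, with the usual accessors."""

    def __init__(self, model, posterior, distances, indices, tolerance, adjust):
        self.model = model
        self.posterior = posterior
        self.distances = distances
        self.indices = indices
        self.tolerance = tolerance
        self.adjust = adjust

    @property
    def n_retained(self) -> int:
        return len(self.posterior)

    def point_estimates(self, kind: str = "median") -> pd.Series:
        agg = self.posterior.median if kind == "median" else self.posterior.mean
        return agg()

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        lo = self.posterior.quantile(alpha / 2)
        hi = self.posterior.quantile(1 - alpha / 2)
        return pd.DataFrame({"lower": lo, "upper": hi})

    def summary(self, alpha: float = 0.05) -> str:
        ci = self.conf_int(alpha)
        med = self.point_estimates()
        lines = [
            "ABC rejection posterior"
            f" (retained {self.n_retained} rows,"
            f" tolerance {self.tolerance}, adjust={self.adjust})",
            f"{'parameter':<22}{'median':>12}{'lower':>12}{'upper':>12}",
        ]
        for p in self.posterior.columns:
            lines.append(
                f"{p:<22}{med[p]:>12.4g}{ci.loc[p, 'lower']:>12.4g}"
                f"{ci.loc[p, 'upper']:>12.4g}"
            )
        return "\n".join(lines)


def abc_reject(observed, table: ReferenceTable, tolerance: float = 0.001,
               adjust: str = "loclinear") -> ABCResults:
    """Functional one-shot wrapper over ABCCalibration(...).fit(...)."""
    return ABCCalibration(observed, table).fit(tolerance, adjust)


# ----------------------------------------------------------------------
# sensitivity analysis and cross-validation
# ----------------------------------------------------------------------
def sensitivity_analysis(table: ReferenceTable) -> pd.DataFrame:
    """Spearman rank correlation of each parameter with each output.

    Returns a tidy frame (parameter, output, rho, p); the sign of rho is
    the direction of the effect.
    """
    if len(table) < 100:
        raise ValueError("need >= 100 rows for a sensitivity analysis")
    rows = []
    for p in table.params.columns:
        x = table.params[p].to_numpy(float)
        for s in table.stats.columns:
            rho, pval = sps.spearmanr(x, table.stats[s].to_numpy(float))
            rows.append({"parameter": p, "output": s, "rho": rho, "p": pval})
    return pd.DataFrame(rows)


def cross_validate(
    table: ReferenceTable,
    n_eval: int = 100,
    tolerance: float = 0.01,
    adjust: str = "none",
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Leave-some-out parameter recovery.

    For `n_eval` random rows, treat the row's statistics as observed,
    estimate each parameter (posterior median) from the remaining rows,
    and correlate estimates with the true values. Returns a frame
    indexed by parameter with Pearson r and its p-value (log10 scale for
    the mutation rate).
    """
    rng = np.random.default_rng(rng)
    n = len(table)
    if n < 50:
        raise ValueError("table too small for cross-validation")
    eval_rows = rng.choice(n, size=min(n_eval, n), replace=False)
    true_vals = {p: [] for p in table.params.columns}
    est_vals = {p: [] for p in table.params.columns}
    mask = np.ones(n, dtype=bool)
    for i in eval_rows:
        mask[:] = True
        mask[i] = False
        sub = ReferenceTable(
            table.params.loc[mask].reset_index(drop=True),
            table.stats.loc[mask].reset_index(drop=True),
        )
        obs = table.stats.iloc[i]
        res = ABCCalibration(obs, sub).fit(tolerance, adjust)
        med = res.point_estimates()
        for p in table.params.columns:
            true_vals[p].append(table.params.iloc[i][p])
            est_vals[p].append(med[p])
    out = []
    for p in table.params.columns:
        t = np.asarray(true_vals[p], float)
        e = np.asarray(est_vals[p], float)
        if p in LOG_PARAMS:
            t, e = np.log10(t), np.log10(e)
        r, pval = sps.pearsonr(t, e)
        out.append({"parameter": p, "r": r, "p": pval})
    return pd.DataFrame(out).set_index("parameter")
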