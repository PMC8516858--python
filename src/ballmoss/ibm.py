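"""Monthly-step individual-based engine for epiphyte spread.

Each plant is one ramet attached to a crown patch of a host tree. The
monthly cycle is: energy update -> mortality -> (in the single annual
reproductive month) reproduction, clonal growth, seed dispersal and
regional seed rain -> germination -> ageing. Plants photosynthesise in
proportion to the light at their attachment site, mature at 48 months,
reproduce once (selfed seeds plus one ramet) when holding at least 10
energy units, and die at 72 months, at zero energy, or with their host
tree.

Seeds fly in a straight uniform-random direction, one patch per
sub-step, for up to ``5 * wind_speed`` patches; every crown patch crossed
captures the seed with probability ``capture_probability``. Uncaptured
seeds, and seeds leaving the (absorbing) landscape boundary, are lost.
Regional immigrant seeds enter at random edge points each season, carry
fresh founder genotypes and found new multi-locus lineages (MLLs).

The population is held in flat numpy arrays (one row per ramet) so a
full 50-year run on a ~20-tree grove takes seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .genetics import (
    AllelePool,
    DEFAULT_TARGET_HET,
    LineageRegistry,
    default_pool,
    random_founder_genotype,
    self_gametes,
)
from .landscape import LandscapeGrid

ORIGIN_SEED, ORIGIN_CLONE = 0, 1


@dataclass(frozen=True)
class SimParams:
    """Free parameters (first five) and fixed life-history constants.

    The five free parameters are the ones estimated by ABC; the rest are
    fixed constants of the life cycle and the energy budget. One wind
    unit corresponds to five landscape patches of free flight per
    dispersal event.
    """

    regional_seed_rain: float = 176.0  # seeds/year entering the landscape
    wind_speed: float = 17.615         # units; flight length = 5*wind patches
    mutation_rate: float = 10**-4.675  # slippage probability per gamete allele
    germination_rate: float = 0.2295   # P(attached seed -> seedling)
    capture_probability: float = 0.223  # P(capture) per crown patch crossed

    lifespan_months: int = 72
    maturity_months: int = 48
    repro_energy_threshold: float = 10.0
    energy_gain: float = 1.0          # units/month at zero shading
    maintenance_cost: float = 0.5     # units/month
    seedling_energy: float = 1.0
    post_repro_energy: float = 5.0    # reserve kept after the single reproduction
    seeds_per_energy_unit: int = 10   # seeds per 10-unit cohort spent
    season_month: int = 0             # month-of-year of the reproductive season
    somatic_mutation: bool = False    # mutate clonal copies too
    target_founder_het: float = DEFAULT_TARGET_HET
    ramet_reach_patches: int = 3      # max patch offset of a new ramet

    @classmethod
    def posterior_median(cls, **overrides) -> "SimParams":
        """Parameter vector at the midpoints of the ABC posterior 95% CIs."""
        return cls(**overrides)

    @property
    def flight_patches(self) -> int:
        return int(round(5.0 * self.wind_speed))

    def replace(self, **kw) -> "SimParams":
        return replace(self, **kw)


def _ramet_offsets(reach: int) -> np.ndarray:
    offs = [
        (di, dj)
        for di in range(-reach, reach + 1)
        for dj in range(-reach, reach + 1)
        if (di, dj) != (0, 0) and di * di + dj * dj <= reach * reach
    ]
    offs.sort(key=lambda o: o[0] ** 2 + o[1] ** 2)
    return np.array(offs, dtype=np.int64)


class SpreadSimulation:
    """State and stepper for one simulated landscape population."""

    def __init__(
        self,
        grid: LandscapeGrid,
        params: SimParams | None = None,
        rng: np.random.Generator | int | None = None,
        pool: AllelePool | None = None,
    ):
        self.grid = grid
        self.params = params or SimParams()
        self.rng = np.random.default_rng(rng)
        self.pool = pool or default_pool()
        self.registry = LineageRegistry()
        self.month = 0
        self.occupied = np.zeros(grid.nx * grid.ny, dtype=bool)
        self._alloc(0)
        self._offsets = _ramet_offsets(self.params.ramet_reach_patches)

    # ------------------------------------------------------------------
    # storage
    # ------------------------------------------------------------------
    def _alloc(self, n: int) -> None:
        L = self.pool.n_loci
        self.ix = np.empty(n, dtype=np.int32)
        self.iy = np.empty(n, dtype=np.int32)
        self.host = np.empty(n, dtype=np.int32)
        self.age = np.empty(n, dtype=np.int32)
        self.energy = np.empty(n, dtype=np.float64)
        self.reproduced = np.empty(n, dtype=bool)
        self.origin = np.empty(n, dtype=np.int8)
        self.mll = np.empty(n, dtype=np.int32)
        self.mlg = np.empty(n, dtype=np.int32)
        self.alive = np.empty(n, dtype=bool)
        self.genotypes = np.empty((n, L, 2), dtype=np.int16)

    _FIELDS = ("ix", "iy", "host", "age", "energy", "reproduced", "origin",
               "mll", "mlg", "alive", "genotypes")

    @property
    def n_rows(self) -> int:
        return self.ix.size

    def _compact(self) -> None:
        keep = self.alive
        for f in self._FIELDS:
            setattr(self, f, getattr(self, f)[keep])

    def add_plants(
        self,
        ix: np.ndarray,
        iy: np.ndarray,
        host: np.ndarray,
        genotypes: np.ndarray,
        mll: np.ndarray,
        origin: int = ORIGIN_SEED,
        age: int = 0,
        energy: float | None = None,
        mlg: np.ndarray | None = None,
    ) -> None:
        """Append established plants and mark their patches occupied."""
        n = len(ix)
        if n == 0:
            return
        if energy is None:
            energy = self.params.seedling_energy
        if mlg is None:
            mlg = self.registry.assign_mlg_batch(genotypes)
        flat = np.asarray(ix) * self.grid.ny + np.asarray(iy)
        if self.occupied[flat].any():
            raise ValueError("patch already occupied")
        self.occupied[flat] = True
        new = {
            "ix": np.asarray(ix, np.int32), "iy": np.asarray(iy, np.int32),
            "host": np.asarray(host, np.int32),
            "age": np.full(n, age, np.int32),
            "energy": np.full(n, float(energy)),
            "reproduced": np.zeros(n, bool),
            "origin": np.full(n, origin, np.int8),
            "mll": np.asarray(mll, np.int32), "mlg": np.asarray(mlg, np.int32),
            "alive": np.ones(n, bool),
            "genotypes": np.asarray(genotypes, np.int16),
        }
        for f in self._FIELDS:
            setattr(self, f, np.concatenate([getattr(self, f), new[f]]))

    # ------------------------------------------------------------------
    # observables
    # ------------------------------------------------------------------
    @property
    def abundance(self) -> int:
        return int(self.alive.sum())

    @property
    def n_mll(self) -> int:
        return int(np.unique(self.mll[self.alive]).size)

    @property
    def n_mlg(self) -> int:
        return int(np.unique(self.mlg[self.alive]).size)

    @property
    def clone_fraction(self) -> float:
        n = self.abundance
        return float((self.origin[self.alive] == ORIGIN_CLONE).mean()) if n else 0.0

    @property
    def year(self) -> float:
        return self.month / 12.0

    def plant_coords(self) -> np.ndarray:
        """(n_alive, 2) metric coordinates of living plants (patch centres)."""
        ps = self.grid.patch_size
        a = self.alive
        return np.column_stack(((self.ix[a] + 0.5) * ps, (self.iy[a] + 0.5) * ps))

    # ------------------------------------------------------------------
    # monthly cycle
    # ------------------------------------------------------------------
    def step(self) -> None:
        """Advance one month."""
        self._update_energy()
        self._mortality()
        if self.month % 12 == self.params.season_month:
            self._compact()
            self._season()
        self.age[self.alive] += 1
        self.month += 1

    def run_years(self, years: int, callback=None) -> None:
        """Run `years` full years; `callback(year, sim)` after each year."""
        for y in range(years):
            for _ in range(12):
                self.step()
            if callback is not None:
                callback(y + 1, self)

    def plant_shading(self) -> np.ndarray:
        """Shading at each row's attachment site, own host crown excluded."""
        layers = self.grid.n_layers[self.ix, self.iy].astype(float) - 1.0
        np.maximum(layers, 0.0, out=layers)
        return 1.0 - (1.0 - self.grid.shading_per_layer) ** layers

    def _update_energy(self) -> None:
        if self.n_rows == 0:
            return
        p = self.params
        gain = p.energy_gain * (1.0 - self.plant_shading()) - p.maintenance_cost
        self.energy[self.alive] += gain[self.alive]
        np.maximum(self.energy, 0.0, out=self.energy)

    def _tree_alive_mask(self) -> np.ndarray:
        max_id = max((t.id for t in self.grid.trees), default=-1)
        mask = np.zeros(max_id + 2, dtype=bool)
        for t in self.grid.trees:
            if t.alive:
                mask[t.id] = True
        return mask

    def _mortality(self) -> None:
        if self.n_rows == 0:
            return
        p = self.params
        tree_ok = self._tree_alive_mask()
        dead = self.alive & (
            (self.age >= p.lifespan_months)
            | (self.energy <= 0.0)
            | ~tree_ok[self.host]
        )
        if dead.any():
            flat = self.ix[dead] * self.grid.ny + self.iy[dead]
            self.occupied[flat] = False
            self.alive[dead] = False

    # ------------------------------------------------------------------
    # reproductive season
    # ------------------------------------------------------------------
    def _season(self) -> None:
        p = self.params
        parents = np.flatnonzero(
            self.alive
            & ~self.reproduced
            & (self.age >= p.maturity_months)
            & (self.energy >= p.repro_energy_threshold)
        )
        seed_ox = seed_oy = seed_parent = None
        if parents.size:
            cohorts = np.floor(
                self.energy[parents] / p.repro_energy_threshold
            ).astype(np.int64)
            n_seeds = cohorts * p.seeds_per_energy_unit
            self.reproduced[parents] = True
            self.energy[parents] = p.post_repro_energy
            self._grow_ramets(parents)
            seed_parent = np.repeat(parents, n_seeds)
            seed_ox = (self.ix[seed_parent] + 0.5).astype(np.float64)
            seed_oy = (self.iy[seed_parent] + 0.5).astype(np.float64)

        # regional immigrant seeds entering at landscape edges
        n_rain = int(self.rng.poisson(p.regional_seed_rain))
        if n_rain:
            rx, ry, rdir = self._edge_entries(n_rain)
        ox_all, oy_all, dir_all, par_all = [], [], [], []
        if seed_ox is not None:
            ox_all.append(seed_ox)
            oy_all.append(seed_oy)
            dir_all.append(self.rng.uniform(0.0, 2 * math.pi, size=seed_ox.size))
            par_all.append(seed_parent)
        if n_rain:
            ox_all.append(rx)
            oy_all.append(ry)
            dir_all.append(rdir)
            par_all.append(np.full(n_rain, -1, dtype=np.int64))
        if not ox_all:
            return
        ox = np.concatenate(ox_all)
        oy = np.concatenate(oy_all)
        dirs = np.concatenate(dir_all)
        par = np.concatenate(par_all)
        cap_i, cap_j, cap_par = self._fly(ox, oy, dirs, par)
        self._germinate_and_establish(cap_i, cap_j, cap_par)

    def _grow_ramets(self, parents: np.ndarray) -> None:
        """One clonal ramet per reproducing parent, on a free crown patch of
        the same host within a small neighbourhood; skipped if none free."""
        grid = self.grid
        max_id = max((t.id for t in grid.trees), default=-1)
        tx = np.zeros(max_id + 1)
        ty = np.zeros(max_id + 1)
        tr = np.zeros(max_id + 1)
        for t in grid.trees:
            tx[t.id], ty[t.id], tr[t.id] = t.x, t.y, t.crown_radius
        remaining = parents.copy()
        placed_rows = []
        placed_i: list[np.ndarray] = []
        placed_j: list[np.ndarray] = []
        order = self.rng.permutation(len(self._offsets))
        ps = grid.patch_size
        for k in order:
            if remaining.size == 0:
                break
            di, dj = self._offsets[k]
            ni = self.ix[remaining] + di
            nj = self.iy[remaining] + dj
            ok = (ni >= 0) & (ni < grid.nx) & (nj >= 0) & (nj < grid.ny)
            h = self.host[remaining]
            cx = (ni + 0.5) * ps
            cy = (nj + 0.5) * ps
            ok &= (cx - tx[h]) ** 2 + (cy - ty[h]) ** 2 <= tr[h] ** 2
            flat = ni * grid.ny + nj
            ok &= ~self.occupied[np.clip(flat, 0, self.occupied.size - 1)] & ok
            if not ok.any():
                continue
            cand = np.flatnonzero(ok)
            # one parent per target patch in this round
            _, first = np.unique(flat[cand], return_index=True)
            cand = cand[first]
            rows = remaining[cand]
            self.occupied[flat[cand]] = True
            placed_rows.append(rows)
            placed_i.append(ni[cand])
            placed_j.append(nj[cand])
            keep = np.ones(remaining.size, dtype=bool)
            keep[cand] = False
            remaining = remaining[keep]
        if not placed_rows:
            return
        rows = np.concatenate(placed_rows)
        gi = np.concatenate(placed_i)
        gj = np.concatenate(placed_j)
        geno = self.genotypes[rows].copy()
        if self.params.somatic_mutation:
            from .genetics import mutate_alleles

            geno = mutate_alleles(geno, self.params.mutation_rate, self.rng)
        # occupancy was already set above; add rows directly
        self.occupied[gi * self.grid.ny + gj] = False  # add_plants re-checks
        self.add_plants(
            gi, gj, self.host[rows], geno, self.mll[rows],
            origin=ORIGIN_CLONE,
            mlg=None if self.params.somatic_mutation else self.mlg[rows],
        )

    def _edge_entries(self, n: int):
        """Entry points on the boundary; flight directions stay uniform on
        the full circle (immigrants heading outward are simply lost)."""
        nx, ny = self.grid.nx, self.grid.ny
        perim = 2.0 * (nx + ny)
        u = self.rng.uniform(0.0, perim, size=n)
        x = np.empty(n)
        y = np.empty(n)
        side = np.searchsorted(np.cumsum([nx, ny, nx, ny]), u)
        v = u - np.concatenate(([0.0], np.cumsum([nx, ny, nx])))[side]
        s0, s1, s2, s3 = side == 0, side == 1, side == 2, side == 3
        x[s0], y[s0] = v[s0], 0.0
        x[s1], y[s1] = float(nx) - 1e-9, v[s1]
        x[s2], y[s2] = v[s2], float(ny) - 1e-9
        x[s3], y[s3] = 0.0, v[s3]
        dirs = self.rng.uniform(0.0, 2 * math.pi, size=n)
        return x, y, dirs

    def _fly(self, ox, oy, dirs, par):
        """Patch-by-patch straight flight with en-route canopy capture."""
        grid, p = self.grid, self.params
        steps = self.params.flight_patches
        dx = np.cos(dirs)
        dy = np.sin(dirs)
        x, y = ox.copy(), oy.copy()
        par = par.copy()
        cap_i: list[np.ndarray] = []
        cap_j: list[np.ndarray] = []
        cap_p: list[np.ndarray] = []
        if steps == 0:
            # no wind: the seed drops where it was released
            ii = x.astype(np.int64)
            jj = y.astype(np.int64)
            inb = (ii >= 0) & (ii < grid.nx) & (jj >= 0) & (jj < grid.ny)
            crown = np.zeros_like(inb)
            crown[inb] = grid.n_layers[ii[inb], jj[inb]] > 0
            hit = crown & (self.rng.uniform(size=x.size) < p.capture_probability)
            return ii[hit], jj[hit], par[hit]
        for _ in range(steps):
            x += dx
            y += dy
            ii = x.astype(np.int64)
            jj = y.astype(np.int64)
            inb = (x >= 0) & (ii < grid.nx) & (y >= 0) & (jj < grid.ny)
            crown = np.zeros_like(inb)
            crown[inb] = grid.n_layers[ii[inb], jj[inb]] > 0
            hit = crown & (self.rng.uniform(size=x.size) < p.capture_probability)
            if hit.any():
                cap_i.append(ii[hit])
                cap_j.append(jj[hit])
                cap_p.append(par[hit])
            keep = inb & ~hit
            if not keep.all():
                x, y, dx, dy, par = x[keep], y[keep], dx[keep], dy[keep], par[keep]
            if x.size == 0:
                break
        if not cap_i:
            z = np.empty(0, dtype=np.int64)
            return z, z.copy(), z.copy()
        return np.concatenate(cap_i), np.concatenate(cap_j), np.concatenate(cap_p)

    def _germinate_and_establish(self, ii, jj, par) -> None:
        p = self.params
        if ii.size == 0:
            return
        germ = self.rng.uniform(size=ii.size) < p.germination_rate
        ii, jj, par = ii[germ], jj[germ], par[germ]
        if ii.size == 0:
            return
        # competition for patches: incumbents win, simultaneous arrivals
        # are resolved in random order
        order = self.rng.permutation(ii.size)
        ii, jj, par = ii[order], jj[order], par[order]
        flat = ii * self.grid.ny + jj
        _, first = np.unique(flat, return_index=True)
        first = first[~self.occupied[flat[first]]]
        if first.size == 0:
            return
        ii, jj, par = ii[first], jj[first], par[first]
        host = self.grid.host[ii, jj].astype(np.int32)
        local = par >= 0
        n_loc = int(local.sum())
        n_reg = par.size - n_loc
        L = self.pool.n_loci
        geno = np.empty((par.size, L, 2), dtype=np.int16)
        mll = np.empty(par.size, dtype=np.int32)
        if n_loc:
            geno[local] = self_gametes(
                self.genotypes[par[local]], p.mutation_rate, self.rng
            )
            mll[local] = self.mll[par[local]]
        if n_reg:
            geno[~local] = random_founder_genotype(
                self.pool, p.target_founder_het, self.rng, n=n_reg
            )
            mll[~local] = self.registry.new_mll(n_reg)
        self.add_plants(ii, jj, host, geno, mll, origin=ORIGIN_SEED)

    # ------------------------------------------------------------------
    # landscape coupling
    # ------------------------------------------------------------------
    def notify_grid_changed(self) -> None:
        """Call after external tree changes (growth, thinning, felling).

        Plants whose host died are removed at the next mortality pass; no
        other state depends on cached tree geometry.
        """
        # nothing cached between steps; hook kept for API clarity
        return


def disperse_seed(
    origin_patch: tuple[int, int],
    params: SimParams,
    grid: LandscapeGrid,
    rng: np.random.Generator | int | None = None,
):
    """Disperse a single seed; returns (landing_patch, captured_tree_or_None).

    Thin single-seed wrapper over the batched flight used by the engine.
    """
    sim = SpreadSimulation(grid, params, rng)
    ox = np.array([origin_patch[0] + 0.5])
    oy = np.array([origin_patch[1] + 0.5])
    dirs = sim.rng.uniform(0.0, 2 * math.pi, size=1)
    ci, cj, _ = sim._fly(ox, oy, dirs, np.zeros(1, dtype=np.int64))
    if ci.size:
        patch = (int(ci[0]), int(cj[0]))
        return patch, int(grid.host[patch])
    return None, None


def germinate(n_seeds: int, params: SimParams,
              rng: np.random.Generator | int | None = None) -> int:
    """Number of attached seeds (out of `n_seeds`) that germinate."""
    rng = np.random.default_rng(rng)
    return int((rng.uniform(size=n_seeds) < params.germination_rate).sum())
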