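"""Summary statistics against hand computations and independent oracles."""

import numpy as np
import pytest

from conftest import make_sample
from ballmoss.genetics import default_pool, random_founder_genotype, self_gametes
from ballmoss.sumstats import (
    amova,
    diversity_stats,
    expected_heterozygosity,
    fis,
    fst,
    fst_pairwise,
    garza_williamson,
    genetic_distance,
    loiselle_kinship,
    mantel_ibd,
    sp_statistic,
    stat_vector,
    turnover,
)


def hwe_genotypes(n, freqs_per_locus, rng):
    """Random union of gametes at the given per-locus allele frequencies."""
    L = len(freqs_per_locus)
    g = np.empty((n, L, 2), dtype=np.int16)
    for l, (alleles, freqs) in enumerate(freqs_per_locus):
        g[:, l, :] = rng.choice(alleles, size=(n, 2), p=freqs)
    g.sort(axis=2)
    return g


class TestDiversity:
    def test_hand_computed_two_individual_case(self):
        # AA and AB at one locus: p(A)=0.75, raw H_E=0.375, H_O=0.5
        s = make_sample([[[1, 1]], [[1, 2]]], [0, 0])
        assert expected_heterozygosity(s.genotypes, unbiased=False) == \
            pytest.approx(0.375)
        # unbiased correction on 4 gene copies: 0.375 * 4/3 = 0.5
        per, _ = diversity_stats(s)
        assert per.loc[0, "H_E"] == pytest.approx(0.5)
        assert per.loc[0, "H_O"] == pytest.approx(0.5)

    def test_identical_homozygotes_are_monomorphic(self):
        s = make_sample(np.full((6, 3, 2), 7), [0, 0, 0, 1, 1, 1])
        per, means = diversity_stats(s)
        assert (per["A"] == 3).all()       # one allele per locus
        assert (per["H_E"] == 0).all()
        assert (per["H_O"] == 0).all()
        assert means["K"] == 1.0

    def test_private_alleles_counted_in_owning_subpop(self):
        g = np.full((4, 1, 2), 10)
        g[3] = [[10, 15]]  # allele 15 only in subpop 1
        s = make_sample(g, [0, 0, 1, 1])
        per, _ = diversity_stats(s)
        assert per.loc[0, "A_P"] == 0
        assert per.loc[1, "A_P"] == 1

    def test_brute_force_frequency_agreement(self, rng):
        """Freq-based statistics match naive recomputation to 1e-10."""
        g = random_founder_genotype(default_pool(), 0.4, rng, n=40)
        s = make_sample(g, np.repeat([0, 1], 20))
        per, _ = diversity_stats(s)
        for p in (0, 1):
            gt = s.genotypes[s.subpop == p]
            n = len(gt)
            he = []
            for l in range(gt.shape[1]):
                copies = gt[:, l, :].ravel()
                freqs = np.array(
                    [np.mean(copies == a) for a in np.unique(copies)]
                )
                raw = 1 - (freqs**2).sum()
                he.append(raw * 2 * n / (2 * n - 1))
            assert per.loc[p, "H_E"] == pytest.approx(np.mean(he), abs=1e-10)
            ho = (gt[:, :, 0] != gt[:, :, 1]).mean()
            assert per.loc[p, "H_O"] == pytest.approx(ho, abs=1e-10)


class TestFis:
    def test_all_homozygotes_polymorphic_gives_one(self):
        g = np.array([[[10, 10]], [[12, 12]], [[10, 10]], [[12, 12]]])
        s = make_sample(g, [0, 0, 0, 0])
        assert fis(s).mean == pytest.approx(1.0)

    def test_hwe_panel_is_near_zero_and_nonsignificant(self, rng):
        pool = [(np.array([10, 12, 14]), np.array([0.5, 0.3, 0.2]))] * 5
        g = hwe_genotypes(200, pool, rng)
        s = make_sample(g, np.repeat([0, 1], 100))
        res = fis(s, n_perm=99, rng=rng)
        assert abs(res.mean) < 0.08
        # no strong heterozygote-deficit signal in either subpop
        assert (res.p_values > 0.01).all()

    def test_long_selfed_cohorts_reach_empirical_range(self, rng):
        # 4 generations of selfing: F ~ 1 - 2^-4 = 0.94
        g = hwe_genotypes(
            120, [(np.array([10, 12]), np.array([0.5, 0.5]))] * 7, rng
        )
        for _ in range(4):
            g = self_gametes(g, 0.0, rng)
        s = make_sample(g, np.repeat([0, 1, 2], 40))
        assert 0.52 <= fis(s).mean <= 1.0

    def test_monomorphic_subpop_reported_missing(self):
        g = np.concatenate(
            [np.full((3, 2, 2), 9), [[[10, 11], [9, 9]]] * 3]
        ).astype(np.int16)
        s = make_sample(g, [0, 0, 0, 1, 1, 1])
        res = fis(s)
        assert np.isnan(res.per_subpop[0])
        assert np.isfinite(res.per_subpop[1])


class TestFst:
    def test_fixed_difference_gives_one(self):
        g = np.concatenate([np.full((8, 4, 2), 10), np.full((8, 4, 2), 20)])
        s = make_sample(g, np.repeat([0, 1], 8))
        assert fst(s) == pytest.approx(1.0)

    def test_single_pool_split_is_near_zero(self, rng):
        pool = [(np.array([10, 12, 14, 16]), np.full(4, 0.25))] * 7
        g = hwe_genotypes(300, pool, rng)
        s = make_sample(g, np.repeat([0, 1, 2], 100))
        assert abs(fst(s)) < 0.02

    def test_single_subpop_refused(self):
        s = make_sample(np.full((5, 2, 2), 10), [0] * 5)
        with pytest.raises(ValueError):
            fst(s)

    def test_island_model_closed_form_with_msprime(self):
        """WC theta on an island-model coalescent sample matches
        F_ST = 1/(1 + 4Nm (d/(d-1))^2) with m the total emigration rate."""
        import msprime

        d, N, m = 8, 500, 1e-4  # pairwise rate; total emigration (d-1)m
        demography = msprime.Demography.island_model([N] * d, migration_rate=m)
        mats = []
        reps = msprime.sim_ancestry(
            samples={f"pop_{i}": 12 for i in range(d)},
            demography=demography,
            sequence_length=200,
            num_replicates=400,
            random_seed=11,
        )
        for k, ts in enumerate(reps):  # independent genealogies = loci
            mts = msprime.sim_mutations(ts, rate=5e-6, random_seed=k + 1)
            if mts.num_sites:
                mats.append(mts.genotype_matrix())
        G = np.concatenate(mats)  # sites x haploid samples
        # fold haploid columns into diploids, one "locus" per SNP
        g = np.stack([G[:, ::2], G[:, 1::2]], axis=-1).transpose(1, 0, 2)
        subpop = np.repeat(np.arange(d), 12)
        s = make_sample(g[:, :500, :] + 1, subpop)
        # total emigration (d-1)m, finite-island correction (d/(d-1))^2;
        # the diffusion formula is itself approximate, so the band is loose
        expect = 1.0 / (1.0 + 4 * N * m * d**2 / (d - 1))
        assert fst(s) == pytest.approx(expect, abs=0.08)

    def test_pairwise_linearization_clamps_negatives(self, rng):
        pool = [(np.array([10, 12]), np.array([0.5, 0.5]))] * 7
        g = hwe_genotypes(60, pool, rng)
        s = make_sample(g, np.repeat([0, 1, 2], 20))
        lin = fst_pairwise(s, linearized=True)
        assert (lin.to_numpy() >= 0).all()


class TestAmova:
    def test_components_sum_to_hundred(self, rng):
        g = random_founder_genotype(default_pool(), 0.4, rng, n=30)
        s = make_sample(g, np.repeat([0, 1, 2], 10))
        res = amova(s, n_perm=49, rng=rng)
        assert res.pct_among + res.pct_within == pytest.approx(100.0)

    def test_identical_subpops_have_no_among_variance(self):
        block = np.array([[[10, 12]], [[10, 10]], [[12, 12]]] * 4)
        s = make_sample(np.concatenate([block, block]), np.repeat([0, 1], 12))
        res = amova(s, n_perm=0)
        assert res.pct_among == pytest.approx(0.0, abs=1e-9)

    def test_fully_fixed_differences_are_all_among(self, rng):
        g = np.concatenate([np.full((8, 3, 2), 10), np.full((8, 3, 2), 14)])
        s = make_sample(g, np.repeat([0, 1], 8))
        res = amova(s, n_perm=99, rng=rng)
        assert res.pct_among == pytest.approx(100.0)
        assert res.p_value < 0.05


class TestGarzaWilliamson:
    def test_hand_cases(self):
        # alleles {10,12}: k=2, R=2 -> 2/3 ; ladder {10,11,12} -> 1 ; single -> 1
        s = make_sample([[[10, 12]], [[10, 12]]], [0, 0])
        assert garza_williamson(s) == pytest.approx(2.0 / 3.0)
        s = make_sample([[[10, 11]], [[11, 12]]], [0, 0])
        assert garza_williamson(s) == pytest.approx(1.0)
        s = make_sample([[[10, 10]]], [0])
        assert garza_williamson(s) == pytest.approx(1.0)


class TestKinship:
    def test_mean_pairwise_kinship_is_near_zero(self, rng):
        g = random_founder_genotype(default_pool(), 0.4, rng, n=60)
        s = make_sample(g, np.zeros(60, int))
        F = loiselle_kinship(s)
        iu = np.triu_indices(60, 1)
        assert abs(F[iu].mean()) < 0.02

    def test_clonemates_sit_above_the_sample_mean(self, rng):
        g = random_founder_genotype(default_pool(), 0.6, rng, n=30)
        g = np.concatenate([g, g[:5]])  # five clone pairs
        s = make_sample(g, np.zeros(35, int))
        F = loiselle_kinship(s)
        iu = np.triu_indices(35, 1)
        clone_f = np.mean([F[i, 30 + i] for i in range(5)])
        assert clone_f > F[iu].mean() + 0.2

    def test_selfed_offspring_kinship_near_half(self, rng):
        """Pedigree oracle: theta(parent, selfed offspring) = (1+F_p)/2 = 0.5
        for non-inbred parents, against an unrelated reference pool."""
        from ballmoss.experiments import make_fixtures

        sample, pairs = make_fixtures("selfing_pedigree", rng)
        F = loiselle_kinship(sample)
        vals = [F[i, j] for i, j in pairs]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.12)


class TestSp:
    def test_distance_classes_balance_pairs_exactly(self, rng):
        n = 224  # C(224,2) = 24,976 pairs -> 7 classes of 3,568
        g = random_founder_genotype(default_pool(), 0.4, rng, n=n)
        s = make_sample(g, np.zeros(n, int), coords=rng.uniform(0, 50, (n, 2)))
        res = sp_statistic(s, n_classes=7, n_perm=0)
        assert res.class_pairs.sum() == 24_976
        assert res.class_pairs.max() - res.class_pairs.min() <= 1
        assert set(res.class_pairs) == {3568}

    def test_shuffled_genotypes_give_null_sp(self, rng):
        g = random_founder_genotype(default_pool(), 0.4, rng, n=80)
        s = make_sample(g, np.zeros(80, int), coords=rng.uniform(0, 50, (80, 2)))
        res = sp_statistic(s, n_perm=199, rng=rng)
        assert abs(res.sp) < 0.02
        assert res.p_value > 0.05

    def test_clonal_clustering_gives_positive_significant_sp(self, rng):
        # clumped clones: strong kinship at short distance
        base = random_founder_genotype(default_pool(), 0.6, rng, n=12)
        g, xy = [], []
        centres = rng.uniform(5, 45, (12, 2))
        for k in range(12):
            for _ in range(6):
                g.append(base[k])
                xy.append(centres[k] + rng.normal(0, 0.4, 2))
        s = make_sample(np.array(g), np.zeros(72, int), coords=np.array(xy))
        res = sp_statistic(s, n_perm=199, rng=rng)
        assert res.sp > 0.0
        assert res.p_value < 0.05
        assert res.class_kinship[0] > res.envelope[1, 0]  # first class above null

    def test_coincident_points_rejected(self, rng):
        g = random_founder_genotype(default_pool(), 0.4, rng, n=10)
        s = make_sample(g, np.zeros(10, int), coords=np.ones((10, 2)))
        with pytest.raises(ValueError):
            sp_statistic(s, n_perm=0)


class TestTurnover:
    def test_identical_composition_is_zero(self):
        s = make_sample(np.full((8, 2, 2), 10), np.repeat([0, 1], 4),
                        mlg=[0, 1, 2, 3, 0, 1, 2, 3])
        assert turnover(s, "mlg") == pytest.approx(0.0)

    def test_disjoint_composition_is_one(self):
        s = make_sample(np.full((8, 2, 2), 10), np.repeat([0, 1], 4),
                        mlg=[0, 1, 2, 3, 4, 5, 6, 7])
        assert turnover(s, "mlg") == pytest.approx(1.0)

    def test_half_shared_hand_value(self):
        # pops {A,B} and {B,C}: gamma=3, alpha=2, S=2 -> (1.5-1)/1 = 0.5
        s = make_sample(np.full((4, 2, 2), 10), [0, 0, 1, 1], mlg=[0, 1, 1, 2])
        assert turnover(s, "mlg") == pytest.approx(0.5)

    def test_allele_level_turnover(self):
        g = np.array([[[10, 10]], [[10, 12]], [[10, 10]], [[10, 12]]])
        s = make_sample(g, [0, 0, 1, 1])
        assert turnover(s, "allele") == pytest.approx(0.0)


class TestMantel:
    @staticmethod
    def _drift(g, rng):
        """One generation of pure drift (random union of deme gametes)."""
        out = np.empty_like(g)
        for l in range(g.shape[1]):
            copies = g[:, l, :].ravel()
            out[:, l, :] = rng.choice(copies, size=(len(g), 2))
        out.sort(axis=2)
        return out

    def test_stepping_stone_isolation_by_distance(self, rng):
        """Serial-founder chain: differentiation accumulates with position."""
        pool = [(np.array([10, 12, 14, 16]), np.full(4, 0.25))] * 7
        demes, gens_between = 6, 8
        g = hwe_genotypes(40, pool, rng)
        samples, coords, labels = [], [], []
        for d in range(demes):
            take = rng.choice(40, 25, replace=False)
            samples.append(g[take])
            labels.append(np.full(25, d))
            coords.append(
                np.column_stack([np.full(25, 10.0 * d + 1.0),
                                 rng.uniform(0, 5, 25)])
            )
            for _ in range(gens_between):  # drift along the chain
                g = self._drift(g, rng)
        s = make_sample(np.concatenate(samples), np.concatenate(labels),
                        coords=np.concatenate(coords))
        r, p = mantel_ibd(s, metric="edwards", n_perm=199, rng=rng)
        assert r > 0.3
        assert p < 0.05

    def test_permuted_labels_kill_the_signal(self, rng):
        pool = [(np.array([10, 12, 14]), np.array([0.4, 0.4, 0.2]))] * 7
        g = hwe_genotypes(120, pool, rng)
        coords = rng.uniform(0, 60, (120, 2))
        s = make_sample(g, rng.integers(0, 6, 120), coords=coords)
        r, p = mantel_ibd(s, metric="edwards", n_perm=199, rng=rng)
        assert p > 0.05

    def test_distance_metrics_are_symmetric_nonnegative(self, rng):
        g = random_founder_genotype(default_pool(), 0.4, rng, n=45)
        s = make_sample(g, np.repeat([0, 1, 2], 15))
        for metric in ("edwards", "nei", "reynolds", "linearized_fst"):
            m = genetic_distance(s, metric).to_numpy()
            assert np.allclose(m, m.T)
            assert (m >= 0).all()


class TestStatVector:
    def test_vector_is_complete_and_finite(self, rng):
        g = random_founder_genotype(default_pool(), 0.4, rng, n=60)
        s = make_sample(g, np.repeat([0, 1, 2], 20))
        v = stat_vector(s)
        assert list(v) == ["K", "R", "H_E", "F_IS", "F_ST", "NGW"]
        assert all(np.isfinite(x) for x in v.values())
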