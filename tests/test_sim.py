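"""Unit and property tests for the forward simulator."""

import numpy as np
import pytest

from pleiocost.sim import (Design, ExtinctionError, PoolSeqConfig, SimConfig,
                           admix, advance_generation, adapt, evolve,
                           founder_population, individual_fitness,
                           pool_seq_sample, run_experiment)


def _cfg(**kw):
    kw.setdefault("census_size", 100)
    kw.setdefault("n_loci", 1)
    kw.setdefault("effect_sizes", 0.5)
    kw.setdefault("init_freqs", 0.5)
    return SimConfig(**kw)


class TestIndividualFitness:
    def test_no_beneficial_alleles_at_old_optimum_is_neutral(self):
        cfg = _cfg(n_loci=3, effect_sizes=1.0, init_freqs=0.0, cost_per_locus=0.3)
        w = individual_fitness([0, 0, 0], [0, 0, 0], cfg, optimum=0.0)
        assert w == pytest.approx(1.0)

    def test_recessive_cost_is_masked_in_heterozygote(self):
        # heterozygote at the optimum with fully recessive cost: no load
        cfg = _cfg(effect_sizes=1.0, cost_per_locus=0.5, cost_dominance=0.0,
                   trait_dominance=0.5)
        z_het = 1.0  # one copy, additive
        assert individual_fitness([1], [0], cfg, optimum=z_het) == pytest.approx(1.0)

    def test_homozygote_pays_full_cost(self):
        cfg = _cfg(effect_sizes=1.0, cost_per_locus=0.2, cost_dominance=0.0)
        z_hom = 2.0
        assert individual_fitness([1], [1], cfg, optimum=z_hom) == pytest.approx(0.8)

    def test_dominant_cost_expressed_in_heterozygote(self):
        cfg = _cfg(effect_sizes=1.0, cost_per_locus=0.2, cost_dominance=1.0)
        assert individual_fitness([1], [0], cfg, optimum=1.0) == pytest.approx(0.8)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"census_size": 1},
        {"cost_per_locus": 1.0},
        {"cost_per_locus": -0.1},
        {"mix_proportion": 0.0},
        {"mix_proportion": 1.0},
        {"init_freqs": 1.5},
        {"trait_dominance": 2.0},
        {"effect_sizes": np.inf},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            _cfg(**kw)


class TestWrightFisherDrift:
    """Neutral limit: with a flat fitness surface the allele-frequency
    moments must match Wright-Fisher closed forms."""

    N, T, REPS = 100, 20, 2000

    def _neutral_cfg(self):
        return _cfg(census_size=self.N, selection_width=np.inf, cost_per_locus=0.0)

    def test_drift_mean_and_variance_match_closed_form(self):
        cfg = self._neutral_cfg()
        rng = np.random.default_rng(12345)
        p0 = 0.5
        finals = np.empty(self.REPS)
        for r in range(self.REPS):
            haps = (rng.random((self.N, 2, 1)) < p0).astype(np.uint8)
            from pleiocost.sim import PopulationState
            pop = PopulationState(haps)
            p_start = pop.allele_freqs()[0]
            for _ in range(self.T):
                pop = advance_generation(pop, cfg, 0.0, rng)
            finals[r] = pop.allele_freqs()[0] - p_start + p0  # center on realized start
        # mean change within 3 SE of zero
        se = finals.std(ddof=1) / np.sqrt(self.REPS)
        assert abs(finals.mean() - p0) < 3 * se
        expected_var = p0 * (1 - p0) * (1 - (1 - 1 / (2 * self.N)) ** self.T)
        assert finals.var(ddof=1) == pytest.approx(expected_var, rel=0.10)

    def test_population_extinct_when_all_fitness_zero(self):
        # an unreachable optimum with a tiny selection width drives all
        # fitnesses to numerical zero
        cfg = _cfg(census_size=20, selection_width=1e-3)
        pop = founder_population(cfg, np.random.default_rng(0))
        with pytest.raises(ExtinctionError):
            advance_generation(pop, cfg, 1e6, np.random.default_rng(0))


def _codominant_recursion(p0, s, t):
    """Deterministic diploid genic selection, fitnesses (1, 1+s/2, 1+s)."""
    p = p0
    for _ in range(t):
        w11, w12, w22 = 1 + s, 1 + s / 2, 1.0
        wbar = p * p * w11 + 2 * p * (1 - p) * w12 + (1 - p) ** 2 * w22
        p = (p * p * w11 + p * (1 - p) * w12) / wbar
    return p


def test_directional_regime_matches_deterministic_recursion():
    """A distant optimum with a wide fitness surface yields near-exponential
    genic selection; the simulated mean trajectory must track the
    deterministic recursion within 0.01 per generation at large N."""
    a, s_target = 0.5, 0.05
    # log-fitness gradient beta = (theta - z)/omega^2 approx constant when
    # theta >> reachable z; per-copy advantage s = 2*beta*a
    omega, theta = 200.0, (s_target / (2 * a)) * 200.0**2
    cfg = _cfg(census_size=20000, effect_sizes=a, selection_width=omega,
               cost_per_locus=0.0, init_freqs=0.1)
    rng = np.random.default_rng(7)
    pop = founder_population(cfg, rng)
    p = pop.allele_freqs()[0]
    expected = p
    for _ in range(20):
        pop = advance_generation(pop, cfg, theta, rng)
        expected = _codominant_recursion(expected, s_target, 1)
        assert abs(pop.allele_freqs()[0] - expected) < 0.01


class TestAdapt:
    def test_redundant_architecture_gives_divergent_selected_subsets(self):
        cfg = SimConfig(census_size=300, n_loci=60, seed=0)
        sets = []
        for seed in (11, 22):
            rng = np.random.default_rng(seed)
            pop = founder_population(cfg, np.random.default_rng(99))
            traj, _ = adapt(pop, cfg, rng)
            sets.append(set(np.flatnonzero(traj[-1] - traj[0] > 0.3)))
        union = sets[0] | sets[1]
        assert union, "no locus responded to selection"
        jaccard = len(sets[0] & sets[1]) / len(union)
        assert jaccard < 1.0

    @staticmethod
    def _mean_within_3se(traj):
        dp = traj[-1] - traj[0]
        se = dp.std(ddof=1) / np.sqrt(dp.size)
        assert abs(dp.mean()) < 3 * se

    def test_unchanged_optimum_gives_no_systematic_response(self):
        cfg = _cfg(census_size=200, n_loci=50, effect_sizes=0.3, init_freqs=0.5,
                   cost_per_locus=0.0, adapt_generations=30)
        cfg.optimum_new = cfg.optimum_old
        rng = np.random.default_rng(3)
        traj, _ = adapt(founder_population(cfg, rng), cfg, rng)
        self._mean_within_3se(traj)

    def test_flat_fitness_surface_behaves_like_drift(self):
        cfg = _cfg(census_size=200, n_loci=50, selection_width=np.inf,
                   cost_per_locus=0.0, adapt_generations=30)
        rng = np.random.default_rng(4)
        traj, _ = adapt(founder_population(cfg, rng), cfg, rng)
        self._mean_within_3se(traj)


class TestAdmix:
    def test_expected_f1_frequency(self):
        # q=0.8 immigrant, q=0.2 recipient, m=0.15 -> E[F1] = 0.29
        n, L = 400, 1
        imm = founder_population(_cfg(census_size=n, init_freqs=0.8), np.random.default_rng(1))
        rec = founder_population(_cfg(census_size=n, init_freqs=0.2), np.random.default_rng(2))
        rng = np.random.default_rng(3)
        freqs = [admix(imm, rec, 0.15, n, rng).allele_freqs()[0] for _ in range(500)]
        expected = 0.15 * imm.allele_freqs()[0] + 0.85 * rec.allele_freqs()[0]
        se = np.std(freqs, ddof=1) / np.sqrt(len(freqs))
        assert abs(np.mean(freqs) - expected) < 3 * se

    def test_identical_populations_are_symmetric(self):
        n = 300
        pop = founder_population(_cfg(census_size=n, init_freqs=0.4), np.random.default_rng(5))
        rng = np.random.default_rng(6)
        freqs = [admix(pop, pop.copy(), 0.5, n, rng).allele_freqs()[0] for _ in range(300)]
        se = np.std(freqs, ddof=1) / np.sqrt(len(freqs))
        assert abs(np.mean(freqs) - pop.allele_freqs()[0]) < 3 * se

    def test_realized_immigrant_fraction_has_binomial_moments(self):
        n, m = 250, 0.15
        imm = founder_population(_cfg(census_size=n, init_freqs=1.0), np.random.default_rng(1))
        rec = founder_population(_cfg(census_size=n, init_freqs=0.0), np.random.default_rng(2))
        rng = np.random.default_rng(9)
        fracs = np.array([admix(imm, rec, m, n, rng).allele_freqs()[0] for _ in range(500)])
        assert fracs.mean() == pytest.approx(m, abs=3 * np.sqrt(m * (1 - m) / n / 500) * 10)
        assert fracs.var(ddof=1) == pytest.approx(m * (1 - m) / n, rel=0.25)

    def test_invalid_mixture_proportion(self):
        pop = founder_population(_cfg(), np.random.default_rng(0))
        with pytest.raises(ValueError):
            admix(pop, pop.copy(), 1.5, 100, np.random.default_rng(0))

    def test_lineage_labels_mark_immigrant_alleles(self):
        n = 100
        imm = founder_population(_cfg(census_size=n, init_freqs=1.0), np.random.default_rng(1))
        rec = founder_population(_cfg(census_size=n, init_freqs=0.0), np.random.default_rng(2))
        mixed = admix(imm, rec, 0.2, n, np.random.default_rng(3))
        # labels coincide with the beneficial allele because it is fixed in
        # the immigrant and absent in the recipient
        assert np.array_equal(mixed.lineage_labels, mixed.haplotypes)


class TestPoolSeq:
    def test_fixed_locus_yields_saturated_counts(self):
        pop = founder_population(_cfg(init_freqs=1.0), np.random.default_rng(0))
        counts, depth = pool_seq_sample(pop, PoolSeqConfig(coverage=50, coverage_model="fixed"),
                                        np.random.default_rng(1))
        assert counts[0] == 50 and depth[0] == 50

    def test_fixed_coverage_conserves_depth(self):
        pop = founder_population(_cfg(n_loci=200, init_freqs=0.3), np.random.default_rng(0))
        counts, depth = pool_seq_sample(pop, PoolSeqConfig(coverage=50, coverage_model="fixed"),
                                        np.random.default_rng(1))
        assert np.all(depth == 50)
        assert np.all((counts >= 0) & (counts <= depth))

    def test_two_stage_sampling_moments(self):
        # many loci at q=0.5: mean within 3 SE, variance matches the
        # compounded pool + read binomial stages
        n, L, cov, pool = 200, 2000, 50, 100
        pop = founder_population(_cfg(census_size=n, n_loci=L, init_freqs=0.5),
                                 np.random.default_rng(2))
        p_true = pop.allele_freqs()
        counts, depth = pool_seq_sample(
            pop, PoolSeqConfig(coverage=cov, coverage_model="fixed", pool_size=pool),
            np.random.default_rng(3))
        obs = counts / depth
        resid = obs - p_true
        se = resid.std(ddof=1) / np.sqrt(L)
        assert abs(resid.mean()) < 3 * se
        # Var = pool-stage (without replacement) + read-stage binomial
        q = 0.5
        fpc = (n - pool) / (n - 1)
        var_pool = q * (1 - q) / (2 * pool) * fpc
        var_reads = q * (1 - q) / cov
        assert resid.var(ddof=1) == pytest.approx(var_pool + var_reads, rel=0.2)

    def test_pool_larger_than_census_rejected(self):
        pop = founder_population(_cfg(census_size=50), np.random.default_rng(0))
        with pytest.raises(ValueError):
            pool_seq_sample(pop, PoolSeqConfig(coverage=50, pool_size=60),
                            np.random.default_rng(0))


@pytest.fixture(scope="module")
def small():
    cfg = SimConfig(census_size=120, n_loci=30, adapt_generations=30,
                    mix_generations=9, seed=5)
    design = Design(parental_ids=("R1", "R2"), shared_history={},
                    pairs=(("R1", "R2"),), n_mix_replicates=2,
                    parental_extra=(5, 9), mixed_timepoints=(1, 5, 9))
    psc = PoolSeqConfig(coverage=30, coverage_model="fixed")
    return run_experiment(cfg, psc, design, seed=5), cfg, design


class TestRunExperiment:
    def test_dataset_shape_contract(self, small):
        ds, cfg, design = small
        assert set(ds.parental_counts) == {"R1", "R2"}
        assert sorted(ds.parental_counts["R1"]) == [0, 30, 35, 39]
        assert list(ds.mixed_counts) == ["R1->R2"]
        assert len(ds.mixed_counts["R1->R2"]) == 2
        assert sorted(ds.mixed_counts["R1->R2"][0]) == [1, 5, 9]
        freqs = ds.parental_freqs("R1")
        assert freqs.shape == (30, 4)
        assert ((freqs.fillna(0) >= 0) & (freqs.fillna(0) <= 1)).all().all()

    def test_truth_table_selected_loci_rose(self, small):
        ds, cfg, design = small
        for rep in ("R1", "R2"):
            dp = ds.trajectories[rep][-1] - ds.trajectories[rep][0]
            sel = ds.loci[f"selected_{rep}"].to_numpy()
            assert np.all(dp[sel] > 0)

    def test_reproducible_from_seed(self, small):
        ds, cfg, design = small
        ds2 = run_experiment(cfg, PoolSeqConfig(coverage=30, coverage_model="fixed"),
                             design, seed=5)
        for rep in ("R1", "R2"):
            for gen, (c, d) in ds.parental_counts[rep].items():
                c2, d2 = ds2.parental_counts[rep][gen]
                assert np.array_equal(c, c2) and np.array_equal(d, d2)

    def test_unknown_replicate_in_pair_rejected(self):
        with pytest.raises(ValueError, match="unknown replicate"):
            Design(parental_ids=("R1", "R2"), shared_history={},
                   pairs=(("R1", "R9"),))
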