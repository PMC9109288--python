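"""Tests for the selection-coefficient estimator and cost statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pleiocost import selstats
from pleiocost.selstats import (bin_by_start_frequency, control_afc,
                                cost_of_pleiotropy, estimate_s, mean_afc,
                                realized_vs_cost)


def codominant_recursion(p0, s, t):
    """Deterministic diploid genic selection, fitnesses (1, 1+s/2, 1+s):
    the independent oracle for estimator consistency."""
    p = p0
    for _ in range(t):
        wbar = p * p * (1 + s) + 2 * p * (1 - p) * (1 + s / 2) + (1 - p) ** 2
        p = (p * p * (1 + s) + p * (1 - p) * (1 + s / 2)) / wbar
    return p


class TestEstimateS:
    def test_zero_at_equal_frequencies(self):
        assert estimate_s(0.3, 0.3, 10) == 0.0

    def test_printed_formula_value(self):
        # (2/20) * ln( (0.2*0.9) / (0.1*0.8) ) = 0.1 * ln(2.25)
        assert estimate_s(0.1, 0.2, 20) == pytest.approx(0.1 * np.log(2.25), rel=1e-12)

    def test_antisymmetry(self):
        assert estimate_s(0.2, 0.1, 20) == pytest.approx(-estimate_s(0.1, 0.2, 20))

    def test_allele_relabeling_flips_sign(self):
        s1 = estimate_s(0.1, 0.4, 10)
        s2 = estimate_s(0.9, 0.6, 10)
        assert s1 == pytest.approx(-s2)

    def test_zero_delta_t_rejected(self):
        with pytest.raises(ValueError):
            estimate_s(0.1, 0.2, 0)

    def test_boundary_clamping_flagged(self):
        s, clamped = estimate_s(0.0, 0.5, 10, boundary_eps=0.01, return_flags=True)
        assert clamped and np.isfinite(s)
        s2, c2 = estimate_s(0.2, 0.5, 10, boundary_eps=0.01, return_flags=True)
        assert not c2

    @pytest.mark.parametrize("s_true", [0.01, 0.05, 0.1])
    def test_recovers_codominant_selection_within_5_percent(self, s_true):
        q0 = 0.1
        q20 = codominant_recursion(q0, s_true, 20)
        s_hat = estimate_s(q0, q20, 20, boundary_eps=1e-9)
        assert s_hat == pytest.approx(s_true, rel=0.05)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99), st.integers(1, 200))
    def test_antisymmetry_property(self, qb, qf, dt):
        assert estimate_s(qb, qf, dt) == pytest.approx(-estimate_s(qf, qb, dt), abs=1e-12)


class TestMeanAfc:
    def test_no_change_gives_zero_with_degenerate_ci(self):
        out = mean_afc([0.1, 0.5, 0.9], [0.1, 0.5, 0.9], n_boot=200, seed=1)
        assert out["mean"] == 0.0
        assert out["ci_low"] == out["ci_high"] == 0.0

    def test_single_snp(self):
        out = mean_afc([0.2], [0.25], n_boot=100, seed=1)
        assert out["mean"] == pytest.approx(0.05)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            mean_afc([], [])

    def test_ci_brackets_the_mean(self):
        rng = np.random.default_rng(0)
        start = rng.random(200)
        end = np.clip(start + rng.normal(0.02, 0.05, 200), 0, 1)
        out = mean_afc(start, end, n_boot=500, seed=2)
        assert out["ci_low"] <= out["mean"] <= out["ci_high"]


class TestControlAfc:
    def test_zero_window_is_exactly_zero(self):
        f = np.array([0.3, 0.6, 0.8])
        assert control_afc(f, f, n_boot=100)["mean"] == 0.0

    def test_fixed_loci_are_exactly_zero(self):
        f = np.array([1.0, 1.0])
        assert control_afc(f, f, n_boot=100)["mean"] == 0.0


class TestBins:
    def test_zero_change_gives_zero_bins_and_undefined_correlation(self):
        start = np.array([0.1, 0.3, 0.5, 0.7])
        out = bin_by_start_frequency(start, np.zeros(4), bins=2, n_perm=100, seed=0)
        assert np.allclose(out.bin_mean_afc[out.bin_counts > 0], 0.0)
        assert np.isnan(out.correlation)

    def test_perfect_monotone_decay_has_rho_minus_one(self):
        start = np.linspace(0.05, 0.95, 40)
        out = bin_by_start_frequency(start, -start, bins=5, n_perm=300, seed=0)
        assert out.correlation == pytest.approx(-1.0)
        assert out.p_value < 0.05

    def test_counts_sum_to_total(self):
        start = np.linspace(0, 1, 33)
        out = bin_by_start_frequency(start, start**2, bins=5, n_perm=50, seed=0)
        assert out.bin_counts.sum() == out.n == 33


class TestCost:
    def _estimates(self, s_imm, s_rec):
        rows = [("sim1", i, s, "immigrant-beneficial") for i, s in enumerate(s_imm)]
        rows += [("sim1", 100 + i, s, "recipient-beneficial") for i, s in enumerate(s_rec)]
        return pd.DataFrame(rows, columns=["chrom", "pos", "s", "origin_class"])

    def test_zero_selection_gives_zero_cost(self):
        est = self._estimates([0.0, 0.0], [0.0, 0.0])
        assert cost_of_pleiotropy(est, "immigrant", n_boot=100)["cost"] == 0.0
        assert cost_of_pleiotropy(est, "recipient", n_boot=100)["cost"] == 0.0

    def test_sign_conventions(self):
        # immigrant alleles favored (+s), recipient disfavored (-s): both
        # focal readings report a positive cost
        est = self._estimates([0.02, 0.04], [-0.01, -0.03])
        assert cost_of_pleiotropy(est, "immigrant", n_boot=100)["cost"] == pytest.approx(0.03)
        assert cost_of_pleiotropy(est, "recipient", n_boot=100)["cost"] == pytest.approx(0.02)

    def test_empty_focal_class_rejected(self):
        est = self._estimates([0.01], [])
        with pytest.raises(ValueError):
            cost_of_pleiotropy(est, "recipient", n_boot=100)

    def test_unknown_focal_rejected(self):
        with pytest.raises(ValueError):
            cost_of_pleiotropy(self._estimates([0.1], [0.1]), "stranger")


class TestRealizedVsCost:
    def test_identical_inputs_give_ratio_one(self):
        parental = {"A->B": {"mean": 0.03}}
        mixed = {"A->B": {"cost": 0.03}}
        table = realized_vs_cost(parental, mixed)
        assert table.loc[0, "ratio"] == pytest.approx(1.0)

    def test_weak_cost_has_ratio_below_one(self):
        table = realized_vs_cost({"p": 0.05}, {"p": {"cost": 0.01}})
        assert table.loc[0, "ratio"] == pytest.approx(0.2)

    def test_mismatched_pairs_rejected(self):
        with pytest.raises(ValueError):
            realized_vs_cost({"a": 0.1}, {"b": {"cost": 0.1}})


class TestOnReplica:
    """Window ordering on the simulated masking scenario: the immigrant
    advantage is concentrated in the early (F1->F20) phase."""

    def test_early_change_exceeds_late_change(self, replica_report, replica_result):
        from pleiocost import pipeline, polarity
        div = replica_report["diverged_pairs"]
        early = pipeline.pooled_class_afc(replica_result, div,
                                          polarity.ORIGIN_IMMIGRANT, ("F1", "F20"), seed=0)
        late = pipeline.pooled_class_afc(replica_result, div,
                                         polarity.ORIGIN_IMMIGRANT, ("F20", "F29"), seed=0)
        assert early["mean"] > late["mean"]

    def test_parental_control_shows_no_drive(self, replica_report, replica_result):
        for label in replica_report["diverged_pairs"]:
            ctrl = replica_result["pairs"][label]["control"]
            assert ctrl["ci_low"] <= 0.0 <= ctrl["ci_high"]
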