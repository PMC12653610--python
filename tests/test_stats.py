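"""ANOVA, Tukey HSD, precision metrics, uncertainty propagation, ΔE report."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from rubbergrade import (
    GRADE_TABLE,
    Grade,
    LabColor,
    assumption_checks,
    calibration_report,
    one_way_anova,
    precision_metrics,
    propagate_uncertainty,
    tukey_hsd,
)


class TestAnova:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        res = one_way_anova([g, list(g)])
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_computed_f(self):
        """{1,2,3} vs {4,5,6}: SSB=13.5, SSW=4, F = 13.5/(4/4) = 13.5."""
        res = one_way_anova([[1, 2, 3], [4, 5, 6]])
        assert res.f_statistic == pytest.approx(13.5)
        assert res.df_between == 1 and res.df_within == 4
        assert res.ss_between == pytest.approx(13.5)
        assert res.ss_within == pytest.approx(4.0)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_scipy_on_random_groups(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(rng.uniform(-2, 2), 1.0, rng.integers(3, 12)) for _ in range(rng.integers(2, 5))]
        res = one_way_anova(groups)
        f_ref, p_ref = sps.f_oneway(*groups)
        assert res.f_statistic == pytest.approx(f_ref, rel=1e-9)
        assert res.p_value == pytest.approx(p_ref, rel=1e-9, abs=1e-12)

    def test_zero_within_variance_edge(self):
        res = one_way_anova([[5.0, 5.0], [7.0, 7.0]])
        assert np.isinf(res.f_statistic)
        assert res.p_value == 0.0

    def test_null_simulation_mirrors_method_equivalence(self):
        """Two measurement methods drawn from the same white-crepe YI
        distribution are non-significant in >= 90% of replicates."""
        gs = GRADE_TABLE[Grade.WHITE_CREPE]
        rng = np.random.default_rng(99)
        non_sig = 0
        for _ in range(100):
            a = rng.normal(gs.yi[0], gs.yi[1], 20)
            b = rng.normal(gs.yi[0], gs.yi[1], 20)
            if one_way_anova([a, b]).p_value > 0.05:
                non_sig += 1
        assert non_sig >= 90


class TestTukey:
    def test_identical_groups_not_significant(self):
        g = {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0], "c": [1.0, 2.0, 3.0, 4.0]}
        table = tukey_hsd(g)
        assert not table["significant"].any()

    def test_separated_groups_significant(self):
        table = tukey_hsd({"lo": [1.0, 1.1, 0.9, 1.0], "hi": [9.0, 9.1, 8.9, 9.0]})
        assert table["significant"].all()

    def test_two_groups_match_t_test_decision(self, rng):
        for _ in range(10):
            a = rng.normal(0, 1, 10)
            b = rng.normal(rng.uniform(0, 2), 1, 10)
            table = tukey_hsd({"a": a, "b": b})
            _, p_t = sps.ttest_ind(a, b)
            assert table["significant"][0] == (p_t < 0.05)
            assert table["p_value"][0] == pytest.approx(p_t, abs=0.01)

    def test_grade_samples_mirror_pairwise_separation(self):
        """Five-grade YI samples: every pair significant except possibly
        STR5 vs STR5L."""
        rng = np.random.default_rng(55)
        groups = {
            g.value: rng.normal(GRADE_TABLE[g].yi[0], GRADE_TABLE[g].yi[1], 20)
            for g in GRADE_TABLE
        }
        table = tukey_hsd(groups)
        for _, row in table.iterrows():
            pair = {row["group_a"], row["group_b"]}
            if pair != {"STR5", "STR5L"}:
                assert row["significant"], pair


class TestPrecision:
    def test_all_equal_zero_cvs(self):
        rep = precision_metrics([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0]])
        assert rep.repeatability_cv == 0.0
        assert rep.reproducibility_cv == 0.0

    def test_recovers_known_components(self):
        """Two-level simulation with known within/between SDs recovers
        both CVs within 15%."""
        rng = np.random.default_rng(8)
        s_within, s_between, mean = 0.3, 0.6, 50.0
        cells = [
            rng.normal(mean + rng.normal(0, s_between), s_within, 30)
            for _ in range(40)
        ]
        rep = precision_metrics(cells)
        assert rep.repeatability_sd == pytest.approx(s_within, rel=0.15)
        expected_repro = np.hypot(s_within, s_between)
        assert rep.reproducibility_sd == pytest.approx(expected_repro, rel=0.15)
        assert rep.repeatability_cv == pytest.approx(s_within / mean, rel=0.15)

    def test_small_within_sd_meets_repeatability_spec(self):
        """Within-session SD 0.05 on a mean of 8.5 keeps repeatability SD
        below the published 0.1-unit bound."""
        rng = np.random.default_rng(13)
        cells = [rng.normal(8.5, 0.05, 10) for _ in range(5)]
        rep = precision_metrics(cells)
        assert rep.repeatability_sd < 0.1

    def test_single_session_flagged(self):
        rep = precision_metrics([[1.0, 2.0, 3.0]])
        assert not rep.reproducibility_defined
        assert np.isnan(rep.reproducibility_cv)


class TestPropagateUncertainty:
    def test_zero_sd_zero_uncertainty(self):
        u = propagate_uncertainty((124.7, 122.3, 120.2), (0, 0, 0), seed=1)
        assert u == 0.0

    def test_white_crepe_stable_across_seeds(self):
        gs = GRADE_TABLE[Grade.WHITE_CREPE]
        u1 = propagate_uncertainty(gs.rgb_mean, gs.rgb_sd, n_mc=100_000, seed=1)
        u2 = propagate_uncertainty(gs.rgb_mean, gs.rgb_sd, n_mc=100_000, seed=2)
        assert u1 > 0
        assert u1 == pytest.approx(u2, rel=0.05)

    def test_locally_linear_in_input_sd(self):
        gs = GRADE_TABLE[Grade.WHITE_CREPE]
        sd = np.array(gs.rgb_sd) / 10.0  # small-perturbation regime
        u1 = propagate_uncertainty(gs.rgb_mean, sd, n_mc=100_000, seed=3)
        u2 = propagate_uncertainty(gs.rgb_mean, 2 * sd, n_mc=100_000, seed=3)
        assert u2 == pytest.approx(2 * u1, rel=0.05)

    def test_converged_at_1e5_draws(self):
        gs = GRADE_TABLE[Grade.RSS3]
        u1 = propagate_uncertainty(gs.rgb_mean, gs.rgb_sd, n_mc=100_000, seed=5)
        u2 = propagate_uncertainty(gs.rgb_mean, gs.rgb_sd, n_mc=200_000, seed=5)
        assert abs(u2 - u1) / u1 < 0.02

    def test_rejects_tiny_sample(self):
        with pytest.raises(ValueError):
            propagate_uncertainty((100, 100, 100), (1, 1, 1), n_mc=10)


class TestCalibrationReport:
    def test_perfect_measurement(self):
        ref = [LabColor(50, 0, 0), LabColor(70, 10, -10)]
        rep = calibration_report(ref, ref)
        assert rep["mean"] == 0.0
        assert rep["pass_fraction"] == 1.0

    def test_single_offset_patch_flagged(self):
        ref = [LabColor(50, 0, 0), LabColor(70, 10, -10)]
        meas = [LabColor(53, 4, 0), LabColor(70, 10, -10)]
        rep = calibration_report(meas, ref)
        assert rep["max"] == pytest.approx(5.0)
        assert rep["pass_fraction"] == 0.5

    def test_perturbation_regime_matches_rig_calibration(self):
        """Per-axis SD 0.7 perturbations land the mean ΔE in the regime a
        well-calibrated rig reports (~1.2 units) with full pass at 2.0."""
        rng = np.random.default_rng(21)
        ref = [LabColor(*rng.uniform([10, -40, -40], [90, 40, 40])) for _ in range(24)]
        meas = [
            LabColor(c.L_star + rng.normal(0, 0.7),
                     c.a_star + rng.normal(0, 0.7),
                     c.b_star + rng.normal(0, 0.7))
            for c in ref
        ]
        rep = calibration_report(meas, ref)
        assert 0.8 <= rep["mean"] <= 1.6
        assert rep["n_patches"] == 24

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            calibration_report([LabColor(50, 0, 0)], [])


def test_assumption_checks_on_gaussian_grades():
    rng = np.random.default_rng(61)
    groups = {
        g.value: rng.normal(GRADE_TABLE[g].yi[0], GRADE_TABLE[g].yi[1], 20)
        for g in GRADE_TABLE
    }
    out = assumption_checks(groups)
    n_pass = sum(v["pass"] for v in out["normality"].values())
    assert n_pass >= 4  # draws are Gaussian by construction
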