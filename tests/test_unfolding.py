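"""Three-state denaturation: baselines, fractions, LEM/nonlinear fits, ddG."""

import math

import numpy as np
import pytest

from specbind import (
    FitMethod,
    StateFractions,
    Transition,
    TransitionFit,
    UnfoldTruth,
    UnfoldingProfile,
    analyze_profile,
    compare_stability,
    fit_baselines,
    fit_lem,
    fit_nonlinear,
    generate_unfolding,
    per_point_dg,
    state_fractions,
    three_state_populations,
)
from specbind.constants import R_GAS
from specbind.exceptions import (
    DataValidationError,
    DegenerateBaselineError,
    FitConvergenceError,
    InsufficientDataError,
)
from specbind.unfolding import ThreeStateUnfoldingAnalysis

from conftest import SIM_M_VALUES, STABILITY_DG

RT298 = R_GAS * 298.0

#: Well-separated sequential truth: sharp transitions with reachable plateaus.
SEPARATED_TRUTH = UnfoldTruth(40000.0, 16000.0, 80000.0, 11000.0)
SEPARATED_GRID = np.arange(0.0, 12.001, 0.125)
SEPARATED_REGIONS = ((0.0, 0.8), (4.3, 5.0), (9.5, 12.0))


class TestBaselines:
    def test_flat_plateaus_recovered_exactly(self):
        u = np.arange(0.0, 9.01, 0.25)
        y = np.where(u <= 2.2, 1.0, np.where(u <= 5.25, 0.55, 0.15))
        base = fit_baselines(UnfoldingProfile(u, y))
        assert base.line_n == (1.0, 0.0)
        assert base.line_i == (0.55, 0.0)
        assert base.line_u == (0.15, 0.0)

    def test_sloped_baseline_truth_recovered(self, zoned_unfold_truth):
        truth = UnfoldTruth(
            zoned_unfold_truth.dg1_J_per_mol, zoned_unfold_truth.m1_J_per_mol_per_M,
            zoned_unfold_truth.dg2_J_per_mol, zoned_unfold_truth.m2_J_per_mol_per_M,
            baselines=((1.0, -0.01), (0.6, 0.005), (0.2, -0.002)))
        prof = generate_unfolding(truth, composition="two_state_zones")
        base = fit_baselines(prof)
        for line, truth_line in zip((base.line_n, base.line_i, base.line_u),
                                    truth.baselines):
            assert line[0] == pytest.approx(truth_line[0], rel=1e-6)
            assert line[1] == pytest.approx(truth_line[1], rel=1e-6, abs=1e-9)

    def test_overlapping_windows_rejected(self, zoned_profile):
        with pytest.raises(DataValidationError, match="non-overlapping"):
            fit_baselines(zoned_profile, regions=((0, 3.0), (2.5, 5.2), (8, 9)))

    def test_sparse_window_names_region(self, zoned_profile):
        with pytest.raises(InsufficientDataError, match="region I"):
            fit_baselines(zoned_profile, regions=((0, 2.2), (5.05, 5.2), (8, 9)))


class TestStateFractions:
    @staticmethod
    def simple_profile():
        # plateaus at 1 (N), 0.5 (I), 0 (U); one probe point per zone
        u = np.array([0.0, 1.0, 2.0, 3.5, 4.8, 5.0, 5.2, 6.5, 8.0, 9.0])
        y = np.array([1.0, 1.0, 1.0, 1.0, 0.5, 0.5, 0.5, 0.25, 0.0, 0.0])
        prof = UnfoldingProfile(u, y)
        base = fit_baselines(prof, regions=((0.0, 2.0), (4.8, 5.2), (8.0, 9.0)))
        return prof, base

    def test_point_on_native_baseline_gives_zero(self):
        prof, base = self.simple_profile()
        f1, f2 = state_fractions(prof, base)
        assert f1.fraction[0] == pytest.approx(0.0, abs=1e-12)  # y=1 at u=3.5

    def test_point_midway_gives_half(self):
        prof, base = self.simple_profile()
        _, f2 = state_fractions(prof, base)
        assert f2.fraction[0] == pytest.approx(0.5, abs=1e-12)  # y=0.25 at u=6.5

    def test_zoned_fractions_match_isolated_two_state(self, zoned_unfold_truth,
                                                      zoned_profile):
        base = fit_baselines(zoned_profile)
        f1, f2 = state_fractions(zoned_profile, base)
        u1 = np.array(f1.denaturant_M)
        expected = 1.0 / (1.0 + np.exp(
            (zoned_unfold_truth.dg1_J_per_mol
             - zoned_unfold_truth.m1_J_per_mol_per_M * u1) / RT298))
        np.testing.assert_allclose(f1.fraction, expected, rtol=1e-9, atol=1e-12)

    def test_sequential_fractions_match_population_ratio(self):
        """On well-separated sequential data the baseline-chord fraction agrees
        with the conditional population pI/(pN+pI) inside the first zone."""
        prof = generate_unfolding(SEPARATED_TRUTH, SEPARATED_GRID,
                                  composition="sequential")
        base = fit_baselines(prof, SEPARATED_REGIONS)
        f1, _ = state_fractions(prof, base)
        u1 = np.array(f1.denaturant_M)
        p_n, p_i, _ = three_state_populations(SEPARATED_TRUTH, u1)
        np.testing.assert_allclose(f1.fraction, p_i / (p_n + p_i), atol=1e-3)

    def test_degenerate_baselines_rejected(self):
        u = np.arange(0.0, 9.01, 0.5)
        prof = UnfoldingProfile(u, np.ones(u.size))
        base = fit_baselines(prof, regions=((0, 2), (4.5, 5.5), (8, 9)))
        with pytest.raises(DegenerateBaselineError):
            state_fractions(prof, base)

    def test_out_of_band_points_clamped_and_flagged(self):
        fr = StateFractions(Transition.N_TO_I, (3.0,), (0.5,), ())
        assert fr.fraction == (0.5,)
        u = np.array([0.0, 1.0, 2.0, 3.0, 4.9, 5.1, 6.0, 8.0, 9.0])
        y = np.array([1.0, 1.0, 1.0, 1.4, 0.5, 0.5, 0.2, 0.0, 0.0])  # overshoot at 3.0
        prof = UnfoldingProfile(u, y)
        base = fit_baselines(prof, regions=((0.0, 2.0), (4.9, 5.1), (8.0, 9.0)))
        f1, _ = state_fractions(prof, base)
        assert f1.flagged == (0,)
        assert f1.fraction[0] == -0.05  # clamped to the report range


class TestPerPointFreeEnergy:
    def test_half_fraction_gives_zero(self):
        fr = StateFractions(Transition.N_TO_I, (3.0,), (0.5,), ())
        dg = per_point_dg(fr, 298.0)
        assert dg.dg_J_per_mol[0] == pytest.approx(0.0, abs=1e-9)

    def test_direct_evaluation_of_log_ratio(self):
        fr = StateFractions(Transition.N_TO_I, (3.0,), (0.269,), ())
        dg = per_point_dg(fr, 298.0)
        assert dg.dg_J_per_mol[0] == pytest.approx(
            -R_GAS * 298.0 * math.log(0.269 / 0.731), rel=1e-12)
        assert dg.dg_J_per_mol[0] == pytest.approx(2480.0, rel=2e-3)  # ~+2.48 kJ/mol

    def test_band_rule_excludes_extremes(self):
        fr = StateFractions(Transition.N_TO_I, (1.0, 2.0, 3.0), (0.01, 0.5, 0.99), ())
        dg = per_point_dg(fr, 298.0)
        assert dg.n_excluded == 2
        assert len(dg.dg_J_per_mol) == 1

    def test_no_usable_points_is_error(self):
        fr = StateFractions(Transition.N_TO_I, (1.0, 2.0), (0.99, 0.999), ())
        with pytest.raises(InsufficientDataError):
            per_point_dg(fr, 298.0)

    def test_logistic_and_log_ratio_are_mutual_inverses(self):
        for f in (0.05, 0.269, 0.5, 0.8, 0.95):
            dg = -RT298 * math.log(f / (1 - f))
            back = 1.0 / (1.0 + math.exp(dg / RT298))
            assert back == pytest.approx(f, abs=1e-12)


class TestTransitionFits:
    def test_exact_line_fit_is_exact(self):
        from specbind.unfolding import FreeEnergySeries
        u = (2.5, 3.0, 3.5, 4.0)
        dg = tuple(17190.0 - 3500.0 * x for x in u)
        series = FreeEnergySeries(Transition.N_TO_I, u, dg, 0)
        fit = fit_lem(series)
        assert fit.dg_h2o_J_per_mol == pytest.approx(17190.0, rel=1e-12)
        assert fit.m_J_per_mol_per_M == pytest.approx(3500.0, rel=1e-12)
        assert fit.midpoint_M == pytest.approx(17190.0 / 3500.0, rel=1e-12)

    def test_nonlinear_exact_on_noiseless_zoned_data(self, zoned_profile):
        base = fit_baselines(zoned_profile)
        f1, _ = state_fractions(zoned_profile, base)
        fit = fit_nonlinear(f1)
        assert fit.dg_h2o_J_per_mol == pytest.approx(17190.0, rel=1e-6)
        assert fit.m_J_per_mol_per_M == pytest.approx(3500.0, rel=1e-6)

    def test_constant_fraction_is_non_identifiable(self):
        fr = StateFractions(Transition.N_TO_I, (2.5, 3.0, 3.5, 4.0),
                            (0.5, 0.5, 0.5, 0.5), ())
        with pytest.raises(FitConvergenceError, match="non-identifiable"):
            fit_nonlinear(fr)

    def test_fraction_at_fitted_midpoint_is_half(self, zoned_profile):
        from specbind.unfolding import TwoStateDenaturationCurve
        base = fit_baselines(zoned_profile)
        f1, _ = state_fractions(zoned_profile, base)
        est = TwoStateDenaturationCurve().fit(
            np.array(f1.denaturant_M).reshape(-1, 1), np.array(f1.fraction))
        f_mid = est.predict(np.array([[est.midpoint_]]))[0]
        assert f_mid == pytest.approx(0.5, abs=1e-6)

    def test_noisy_estimates_within_three_stderr(self):
        """1% noise, seeded replicates: the nonlinear dG_H2O lands within
        3 reported standard errors of the truth in >= 95% of runs."""
        m1, m2 = SIM_M_VALUES
        dg1, dg2 = STABILITY_DG["nonlinear"]["apo"]
        rng = np.random.default_rng(11)
        hits = trials = 0
        for _ in range(300):
            truth = UnfoldTruth(dg1, m1, dg2, m2, noise_cv=0.01,
                                seed=int(rng.integers(2**31)))
            prof = generate_unfolding(truth, composition="two_state_zones")
            try:
                fit = analyze_profile(prof, method="nonlinear").get(
                    FitMethod.NONLINEAR, Transition.N_TO_I)
            except (FitConvergenceError, InsufficientDataError):
                continue
            trials += 1
            if abs(fit.dg_h2o_J_per_mol - dg1) <= 3 * fit.stderr_dg:
                hits += 1
        assert trials >= 290
        assert hits / trials >= 0.95


class TestFullPipeline:
    def test_zoned_profile_recovered_exactly(self, zoned_profile):
        m1, m2 = SIM_M_VALUES
        dg1, dg2 = STABILITY_DG["nonlinear"]["apo"]
        fits = analyze_profile(zoned_profile)
        for transition, dg_truth, m_truth in ((Transition.N_TO_I, dg1, m1),
                                              (Transition.I_TO_U, dg2, m2)):
            lem = fits.get(FitMethod.LINEAR_LEM, transition)
            nl = fits.get(FitMethod.NONLINEAR, transition)
            assert lem.dg_h2o_J_per_mol == pytest.approx(dg_truth, rel=1e-3)
            assert nl.dg_h2o_J_per_mol == pytest.approx(dg_truth, rel=1e-3)
            assert lem.m_J_per_mol_per_M == pytest.approx(m_truth, rel=1e-3)
            # the two routes fit the same exact model, so they coincide
            assert nl.dg_h2o_J_per_mol == pytest.approx(lem.dg_h2o_J_per_mol,
                                                        rel=1e-6)

    def test_sequential_profile_recovered_when_transitions_separated(self):
        prof = generate_unfolding(SEPARATED_TRUTH, SEPARATED_GRID,
                                  composition="sequential")
        fits = analyze_profile(prof, SEPARATED_REGIONS)
        for transition, dg_truth, m_truth in (
                (Transition.N_TO_I, SEPARATED_TRUTH.dg1_J_per_mol,
                 SEPARATED_TRUTH.m1_J_per_mol_per_M),
                (Transition.I_TO_U, SEPARATED_TRUTH.dg2_J_per_mol,
                 SEPARATED_TRUTH.m2_J_per_mol_per_M)):
            for method in (FitMethod.LINEAR_LEM, FitMethod.NONLINEAR):
                fit = fits.get(method, transition)
                assert fit.dg_h2o_J_per_mol == pytest.approx(dg_truth, rel=1e-3)
                assert fit.m_J_per_mol_per_M == pytest.approx(m_truth, rel=1e-3)

    def test_estimator_wrapper_matches_functions(self, zoned_profile):
        est = ThreeStateUnfoldingAnalysis()
        est.fit(zoned_profile.denaturant_M.reshape(-1, 1), zoned_profile.signal)
        direct = analyze_profile(zoned_profile)
        assert est.fit_set_.pair("nonlinear")[0].dg_h2o_J_per_mol == pytest.approx(
            direct.pair("nonlinear")[0].dg_h2o_J_per_mol, rel=1e-12)


def tfit(dg, transition, method=FitMethod.NONLINEAR):
    return TransitionFit(dg, 3500.0, 0.0, 0.0, method, transition)


class TestCompareStability:
    @pytest.mark.parametrize("method, total_apo, total_cplx, ddg", [
        (FitMethod.NONLINEAR, 32420.0, 34410.0, 1990.0),
        (FitMethod.LINEAR_LEM, 25710.0, 27770.0, 2060.0),
    ])
    def test_published_components_reproduce_published_totals(self, method,
                                                             total_apo,
                                                             total_cplx, ddg):
        key = method.value
        apo = (tfit(STABILITY_DG[key]["apo"][0], Transition.N_TO_I, method),
               tfit(STABILITY_DG[key]["apo"][1], Transition.I_TO_U, method))
        cplx = (tfit(STABILITY_DG[key]["complex"][0], Transition.N_TO_I, method),
                tfit(STABILITY_DG[key]["complex"][1], Transition.I_TO_U, method))
        cmp_ = compare_stability(apo, cplx)
        assert cmp_.total_dg_h2o_apo_J_per_mol == pytest.approx(total_apo, abs=1e-9)
        assert cmp_.total_dg_h2o_complex_J_per_mol == pytest.approx(total_cplx,
                                                                    abs=1e-9)
        assert cmp_.ddg_h2o_J_per_mol == pytest.approx(ddg, abs=1e-9)

    def test_identical_inputs_give_zero(self):
        pair = (tfit(17190.0, Transition.N_TO_I), tfit(15230.0, Transition.I_TO_U))
        assert compare_stability(pair, pair).ddg_h2o_J_per_mol == 0.0

    def test_method_mismatch_rejected(self):
        apo = (tfit(17190.0, Transition.N_TO_I), tfit(15230.0, Transition.I_TO_U))
        cplx = (tfit(19090.0, Transition.N_TO_I, FitMethod.LINEAR_LEM),
                tfit(15320.0, Transition.I_TO_U, FitMethod.LINEAR_LEM))
        with pytest.raises(DataValidationError, match="mix methods"):
            compare_stability(apo, cplx)

    def test_stabilization_localized_to_first_transition(self):
        apo = (tfit(17190.0, Transition.N_TO_I), tfit(15230.0, Transition.I_TO_U))
        cplx = (tfit(19090.0, Transition.N_TO_I), tfit(15320.0, Transition.I_TO_U))
        per = compare_stability(apo, cplx).per_transition_ddg_J_per_mol
        assert per["N_to_I"] == pytest.approx(1900.0)
        assert abs(per["I_to_U"]) < 100.0
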