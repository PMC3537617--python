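"""Generator behavior: exact models before noise, determinism, populations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specbind import (
    QuenchTruth,
    UnfoldTruth,
    generate_quench,
    generate_scattering,
    generate_temperature_series,
    generate_unfolding,
    three_state_populations,
    vant_hoff_ka,
)
from specbind.constants import R_GAS
from specbind.exceptions import DataValidationError


class TestGenerateQuench:
    def test_half_quench_at_inverse_ka(self):
        ka = 6.02e4
        truth = QuenchTruth(ka_assoc_per_M=ka, n_sites=1.0, f0=1000.0)
        grid = np.array([0.0, 1.0 / ka])
        s = generate_quench(truth, grid)
        assert s.intensity[1] == pytest.approx(500.0, rel=1e-12)

    def test_noiseless_n1_is_exactly_stern_volmer_linear(self, quench_grid):
        ka = 4.4e4
        s = generate_quench(QuenchTruth(ka_assoc_per_M=ka), quench_grid)
        y = s.f0 / s.intensity - 1.0
        np.testing.assert_allclose(y, ka * s.ligand_conc_M, rtol=1e-12)

    def test_f0_point_exact_even_with_noise(self, quench_grid):
        truth = QuenchTruth(ka_assoc_per_M=6e4, noise_cv=0.05, seed=3)
        assert generate_quench(truth, quench_grid).f0 == 1000.0

    def test_same_seed_reproducible_different_seed_not(self, quench_grid):
        t = QuenchTruth(ka_assoc_per_M=6e4, noise_cv=0.05, seed=42)
        a = generate_quench(t, quench_grid)
        b = generate_quench(t, quench_grid)
        np.testing.assert_array_equal(a.intensity, b.intensity)
        c = generate_quench(QuenchTruth(ka_assoc_per_M=6e4, noise_cv=0.05, seed=43),
                            quench_grid)
        assert not np.array_equal(a.intensity, c.intensity)

    def test_negative_concentration_rejected(self):
        with pytest.raises(DataValidationError):
            generate_quench(QuenchTruth(ka_assoc_per_M=6e4),
                            np.array([-1e-6, 0.0, 1e-6]))

    def test_implausible_noise_refused(self):
        with pytest.raises(DataValidationError):
            QuenchTruth(ka_assoc_per_M=6e4, noise_cv=0.25)


class TestTemperatureSeries:
    def test_vant_hoff_closed_form(self):
        # hand evaluation of Ka = exp(-dH/(R T) + dS/R)
        dh, ds, t = -15130.0, 40.87, 298.0
        expected = np.exp(15130.0 / (8.3145 * 298.0) + 40.87 / 8.3145)
        assert vant_hoff_ka(dh, ds, t) == pytest.approx(expected, rel=1e-12)

    def test_zero_enthalpy_gives_temperature_independent_ka(self, quench_grid):
        base = QuenchTruth(ka_assoc_per_M=1.0)
        series = generate_temperature_series(0.0, 40.0, [280.0, 300.0, 320.0],
                                             base, quench_grid)
        ratios = [s.intensity[5] for s in series]
        assert ratios[0] == pytest.approx(ratios[1], rel=1e-12)
        assert ratios[1] == pytest.approx(ratios[2], rel=1e-12)

    def test_exothermic_binding_weakens_with_temperature(self, quench_grid):
        base = QuenchTruth(ka_assoc_per_M=1.0)
        series = generate_temperature_series(-15130.0, 0.0, [290.0, 300.0, 310.0],
                                             base, quench_grid)
        # weaker Ka quenches less: intensity at fixed [Q] rises with T
        mid = [s.intensity[9] for s in series]
        assert mid[0] < mid[1] < mid[2]


class TestUnfoldingGenerator:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(dg1=st.floats(5e3, 4e4), m1=st.floats(2e3, 2e4),
           dg2_extra=st.floats(1e3, 4e4), m2=st.floats(1e3, 1e4),
           u=st.floats(0.0, 12.0))
    def test_populations_sum_to_one(self, dg1, m1, dg2_extra, m2, u):
        mid1 = dg1 / m1
        dg2 = m2 * (mid1 + 0.5) + dg2_extra  # force midpoint2 > midpoint1
        truth = UnfoldTruth(dg1, m1, dg2, m2)
        p_n, p_i, p_u = three_state_populations(truth, np.array([u]))
        assert abs(p_n[0] + p_i[0] + p_u[0] - 1.0) < 1e-12

    def test_midpoint_symmetry_of_first_transition(self):
        # at u = dG1/m1 with the second step still locked, pN = pI = 0.5
        truth = UnfoldTruth(17500.0, 3500.0, 80000.0, 8000.0)
        p_n, p_i, p_u = three_state_populations(truth, np.array([5.0]))
        assert p_n[0] == pytest.approx(0.5, abs=1e-3)
        assert p_i[0] == pytest.approx(0.5, abs=1e-3)

    def test_native_dominates_in_water_for_stable_protein(self):
        truth = UnfoldTruth(15000.0, 3500.0, 16000.0, 2500.0)
        p_n, _, _ = three_state_populations(truth, np.array([0.0]))
        # evaluate the population formula by hand for the oracle
        rt = R_GAS * 298.0
        k1 = np.exp(-15000.0 / rt)
        k2 = np.exp(-16000.0 / rt)
        assert p_n[0] == pytest.approx(1.0 / (1.0 + k1 + k1 * k2), rel=1e-12)
        assert p_n[0] > 0.99

    def test_noiseless_flat_baselines_monotone_non_increasing(self):
        truth = UnfoldTruth(17190.0, 3500.0, 15230.0, 2500.0,
                            baselines=((1.0, 0.0), (0.5, 0.0), (0.0, 0.0)))
        prof = generate_unfolding(truth, composition="sequential")
        assert np.all(np.diff(prof.signal) <= 1e-15)

    def test_grid_not_spanning_midpoints_flags_label(self):
        truth = UnfoldTruth(17190.0, 3500.0, 15230.0, 2500.0)
        prof = generate_unfolding(truth, denat_grid_M=np.arange(0.0, 3.0, 0.25))
        assert "warning" in prof.label

    def test_midpoint_ordering_enforced(self):
        with pytest.raises(DataValidationError, match="midpoint"):
            UnfoldTruth(30000.0, 3500.0, 15000.0, 2500.0)

    def test_seeded_noise_reproducible(self):
        truth = UnfoldTruth(17190.0, 3500.0, 15230.0, 2500.0,
                            noise_cv=0.01, seed=9)
        a = generate_unfolding(truth)
        b = generate_unfolding(truth)
        np.testing.assert_array_equal(a.signal, b.signal)


class TestScattering:
    def test_no_threshold_means_flat_series(self):
        grid = np.linspace(0.0, 60e-6, 31)
        s = generate_scattering(grid, cmc_like_threshold_M=None, seed=1)
        slope = np.polyfit(s.ligand_conc_M, s.intensity, 1)[0]
        # slope * full span is small against the mean level
        assert abs(slope) * 60e-6 < 0.05 * s.intensity.mean()

    def test_threshold_produces_detectable_rise(self):
        grid = np.linspace(0.0, 60e-6, 31)
        s = generate_scattering(grid, cmc_like_threshold_M=30e-6, seed=1)
        below = s.intensity[grid <= 30e-6]
        above = s.intensity[grid > 30e-6]
        assert above.mean() > below.mean() + 5 * below.std()

    def test_same_seed_reproducible(self):
        grid = np.linspace(0.0, 60e-6, 11)
        a = generate_scattering(grid, 30e-6, seed=5)
        b = generate_scattering(grid, 30e-6, seed=5)
        np.testing.assert_array_equal(a.intensity, b.intensity)
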