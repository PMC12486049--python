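"""Forward engine: reweighted intensity, sensitivities, EPR/RoR, smoothing."""

import numpy as np
import pytest

from tfosim.optics_model import ConfigError, build_state_pair
from tfosim.photon_mc import DetectorGrid, Geometry, PathlengthTable, simulate_paths
from tfosim.forward_engine import (
    FETAL_LAYER,
    DistributionSummary,
    GeometryMismatchError,
    UndefinedRatioError,
    epr,
    epr_curve,
    fetal_sensitive_intensity,
    fetal_sensitivity,
    intensity,
    interp_epr,
    mu_from_state,
    pathlength_summary,
    ring_intensities,
    ror,
    sensitivity_derivative,
    smooth_epr_curve,
)

from conftest import make_layered_table, reference_hemodynamics


def toy_table(lengths, detector_index=None, weight=None, n_launched=10):
    """Hand-built table over a 2-ring grid for closed-form checks."""
    lengths = np.atleast_2d(np.asarray(lengths, dtype=float))
    n = lengths.shape[0]
    det = np.zeros(n, dtype=np.int32) if detector_index is None else np.asarray(detector_index, dtype=np.int32)
    w = np.ones(n) if weight is None else np.asarray(weight, dtype=float)
    grid = DetectorGrid(sdds=(10.0, 20.0), capture_radius=2.0)
    geometry = Geometry(
        thickness=(5.0, 5.0, 1.0, np.inf),
        mu_s=(10.0, 10.0, 0.1, 10.0),
        g=(0.9, 0.9, 0.9, 0.9),
        n=(1.4, 1.4, 1.33, 1.4),
    )
    return PathlengthTable(
        detector_index=det,
        lengths=lengths,
        weight=w,
        radius=np.full(n, 10.0),
        n_launched=n_launched,
        seed=0,
        detectors=grid,
        geometry=geometry,
    )


class TestIntensity:
    def test_zero_absorption_returns_weight_fraction(self, small_table):
        sdd = small_table.detectors.sdds[2]
        mask = small_table.detector_index == 2
        expected = small_table.weight[mask].sum() / small_table.n_launched
        assert intensity(small_table, np.zeros(4), sdd) == pytest.approx(expected)

    def test_single_record_closed_form(self):
        tab = toy_table([[10.0, 0.0, 0.0, 0.0]], weight=[0.9], n_launched=10)
        got = intensity(tab, [0.05, 0.0, 0.0, 0.0], 10.0)
        assert got == pytest.approx(0.9 * np.exp(-0.5) / 10)

    def test_strictly_decreasing_in_absorption(self, small_table):
        sdd = small_table.detectors.sdds[1]
        lo = intensity(small_table, [0.01, 0.01, 0.01, 0.01], sdd)
        hi = intensity(small_table, [0.05, 0.01, 0.01, 0.01], sdd)
        assert hi < lo

    def test_wavelength_mismatch_is_a_hard_error(self, table_dm14_735):
        _, dia = build_state_pair(14.0, reference_hemodynamics(), 850.0)
        with pytest.raises(GeometryMismatchError):
            intensity(table_dm14_735, mu_from_state(dia), 10.0)

    def test_dm_mismatch_is_a_hard_error(self, table_dm14_735):
        _, dia = build_state_pair(10.0, reference_hemodynamics(), 735.0)
        with pytest.raises(GeometryMismatchError):
            intensity(table_dm14_735, mu_from_state(dia), 10.0)

    def test_ring_intensities_matches_scalar_path(self, small_table):
        mu = np.array([0.05, 0.02, 0.01, 0.08])
        vec = ring_intensities(small_table, mu)
        for k, sdd in enumerate(small_table.detectors.sdds):
            assert vec[k] == pytest.approx(intensity(small_table, mu, sdd), rel=1e-12)


class TestOracleEquivalence:
    def test_white_reweighting_equals_inflight_absorption(self):
        """The acceleration identity: absorption applied after the fact on the
        stored pathlengths equals absorption applied during transport, photon
        path by photon path (same seed, no roulette)."""
        hemo = reference_hemodynamics()
        _, dia = build_state_pair(14.0, hemo, 735.0)
        from tfosim.photon_mc import geometry_from_state

        geometry = geometry_from_state(dia)
        mu = dia.mu_a
        white = simulate_paths(geometry, 30_000, seed=5, max_path_mm=800.0,
                               max_depth_mm=120.0)
        oracle = simulate_paths(geometry, 30_000, seed=5, max_path_mm=800.0,
                                max_depth_mm=120.0, mode="absorb", mu_a=mu)
        assert white.n_detected == oracle.n_detected
        np.testing.assert_array_equal(white.detector_index, oracle.detector_index)
        for sdd in white.detectors.sdds:
            i_white = intensity(white, mu, sdd)
            mask = oracle.detector_index == oracle.detectors.index_of(sdd)
            i_oracle = oracle.weight[mask].sum() / oracle.n_launched
            if i_white > 0:
                assert abs(i_oracle - i_white) / i_white < 1e-10


class TestSensitivityDerivative:
    def test_zero_pathlength_layer_has_zero_derivative(self):
        tab = toy_table([[10.0, 2.0, 0.0, 0.0], [8.0, 1.0, 0.0, 0.0]])
        assert sensitivity_derivative(tab, np.zeros(4), 10.0, 3) == 0.0

    def test_matches_central_finite_difference(self, small_table):
        mu = np.array([0.05, 0.0158, 0.0125, 0.08])
        sdd = small_table.detectors.sdds[2]
        h = 1e-6
        for layer in range(4):
            up, dn = mu.copy(), mu.copy()
            up[layer] += h
            dn[layer] -= h
            fd = (intensity(small_table, up, sdd) - intensity(small_table, dn, sdd)) / (2 * h)
            got = sensitivity_derivative(small_table, mu, sdd, layer)
            assert got == pytest.approx(fd, rel=1e-6)
            assert got <= 0.0

    def test_linear_in_pathlength_at_zero_absorption(self):
        base = toy_table([[10.0, 2.0, 1.0, 3.0]])
        doubled = toy_table([[10.0, 2.0, 1.0, 6.0]])
        d1 = sensitivity_derivative(base, np.zeros(4), 10.0, 3)
        d2 = sensitivity_derivative(doubled, np.zeros(4), 10.0, 3)
        assert d2 == pytest.approx(2 * d1)


class TestFetalSensitivity:
    def test_no_fetal_photons_means_zero(self):
        tab = toy_table([[10.0, 2.0, 1.0, 0.0]])
        assert fetal_sensitivity(tab, np.zeros(4), 10.0) == 0.0

    def test_no_maternal_pathlength_means_one(self):
        tab = toy_table([[0.0, 2.0, 1.0, 5.0]])
        assert fetal_sensitivity(tab, np.zeros(4), 10.0) == 1.0

    def test_empty_ring_is_undefined(self):
        tab = toy_table([[10.0, 2.0, 1.0, 0.0]])
        with pytest.raises(UndefinedRatioError):
            fetal_sensitivity(tab, np.zeros(4), 20.0)

    def test_grows_with_sdd_on_the_layered_model(self, table_dm14_735):
        _, dia = build_state_pair(14.0, reference_hemodynamics(), 735.0)
        mu = mu_from_state(dia)
        near = fetal_sensitivity(table_dm14_735, mu, table_dm14_735.detectors.sdds[1])
        far = fetal_sensitivity(table_dm14_735, mu, table_dm14_735.detectors.sdds[13])
        assert far > near

    def test_sensitive_intensity_bounds_and_convergence(self, table_dm4_735):
        _, dia = build_state_pair(4.0, reference_hemodynamics(), 735.0)
        mu = mu_from_state(dia)
        ratios = []
        for k in (0, 5, 10):
            sens, total = fetal_sensitive_intensity(
                table_dm4_735, mu, table_dm4_735.detectors.sdds[k]
            )
            assert sens <= total + 1e-15
            ratios.append(sens / total)
        assert ratios[0] < ratios[1] < ratios[2]

    def test_all_sensitive_means_equal_pair(self):
        tab = toy_table([[10.0, 2.0, 1.0, 4.0], [9.0, 2.0, 1.0, 2.0]])
        sens, total = fetal_sensitive_intensity(tab, np.zeros(4), 10.0)
        assert sens == pytest.approx(total)


class TestEPR:
    def test_identical_assignments_give_unity(self, small_table):
        mu = np.array([0.05, 0.0158, 0.0125, 0.08])
        assert epr(small_table, mu, mu, small_table.detectors.sdds[0]) == 1.0

    def test_weighted_expectation_identity(self, table_dm14_735):
        """The intensity-ratio EPR equals the expectation form over the fetal
        pathlength distribution, with the non-fetal attenuation folded into
        the weights — exactly, on any table."""
        systole, diastole = build_state_pair(14.0, reference_hemodynamics(), 735.0)
        mu_s, mu_d = systole.mu_a, diastole.mu_a
        sdd = table_dm14_735.detectors.sdds[6]
        got = epr(table_dm14_735, mu_s, mu_d, sdd)

        mask = table_dm14_735.detector_index == 6
        lengths = table_dm14_735.lengths[mask]
        a = table_dm14_735.weight[mask] * np.exp(
            -(lengths[:, :3] @ mu_d[:3])
        )
        lf = lengths[:, FETAL_LAYER]
        expected = (a * np.exp(-mu_d[3] * lf)).sum() / (a * np.exp(-mu_s[3] * lf)).sum()
        assert got == pytest.approx(expected, rel=1e-10)

    def test_epr_at_least_one_and_monotone_in_pulsation_gap(self, table_dm14_735):
        systole, diastole = build_state_pair(14.0, reference_hemodynamics(), 735.0)
        mu_s, mu_d = systole.mu_a.copy(), diastole.mu_a
        sdd = table_dm14_735.detectors.sdds[8]
        small_gap = epr(table_dm14_735, mu_s, mu_d, sdd)
        mu_s2 = mu_s.copy()
        mu_s2[3] = mu_d[3] + 2 * (mu_s[3] - mu_d[3])
        big_gap = epr(table_dm14_735, mu_s2, mu_d, sdd)
        assert 1.0 <= small_gap < big_gap

    def test_non_fetal_difference_warns(self, small_table):
        mu_d = np.array([0.05, 0.0158, 0.0125, 0.08])
        mu_s = mu_d + np.array([0.01, 0, 0, 0.002])
        with pytest.warns(UserWarning, match="outside the fetal layer"):
            epr(small_table, mu_s, mu_d, small_table.detectors.sdds[0])

    def test_empty_ring_is_undefined(self):
        tab = toy_table([[10.0, 0.0, 0.0, 0.0]])
        with pytest.raises(UndefinedRatioError):
            epr(tab, np.zeros(4), np.zeros(4), 20.0)


class TestRoR:
    def test_equal_eprs_give_unity(self):
        assert ror(1.05, 1.05) == pytest.approx(1.0)

    def test_closed_form(self):
        assert ror(np.e, np.e**2) == pytest.approx(0.5)

    def test_unit_reference_epr_is_undefined(self):
        with pytest.raises(UndefinedRatioError):
            ror(1.05, 1.0)

    def test_small_pulsation_limit_matches_ac_over_dc_ratio(self):
        # EPR = (2AC+DC)/DC, so ln EPR ~ 2 AC/DC for small AC and the
        # log-ratio approaches the classic pulsation-ratio quotient
        dc = 1.0
        ac1, ac2 = 1e-5, 2e-5
        epr1 = (2 * ac1 + dc) / dc
        epr2 = (2 * ac2 + dc) / dc
        got = ror(epr1, epr2)
        expected = (ac1 / dc) / (ac2 / dc)
        assert got == pytest.approx(expected, abs=1e-4)


class TestSmoothing:
    def test_constant_curve_unchanged(self):
        x = np.arange(5, dtype=float)
        y = np.full(5, 1.3)
        np.testing.assert_allclose(smooth_epr_curve(x, y), y)

    def test_linear_curve_is_a_fixed_point_on_nonuniform_grid(self):
        x = np.array([10.0, 14.0, 25.0, 31.0, 50.0])
        y = 0.02 * x + 1.0
        np.testing.assert_allclose(smooth_epr_curve(x, y), y, rtol=1e-12)

    def test_hand_worked_zigzag(self):
        # differences [1, 0, 0, 0, -1]; averaged pairs [0.5, 0, 0, -0.5];
        # regenerated from y0=0: [0, 0.5, 0.5, 0.5, 0.0]
        x = np.arange(5, dtype=float)
        y = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
        np.testing.assert_allclose(
            smooth_epr_curve(x, y), [0.0, 0.5, 0.5, 0.5, 0.0]
        )

    def test_short_curve_passthrough_with_warning(self):
        with pytest.warns(UserWarning, match="passthrough"):
            out = smooth_epr_curve(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        np.testing.assert_allclose(out, [3.0, 4.0])

    def test_interp_fills_gaps_and_hits_targets(self):
        x = np.linspace(10, 95, 20)
        y = 1.0 + 0.001 * (x - 10)
        y_holed = y.copy()
        y_holed[7] = np.nan
        got = interp_epr(x, y_holed, [15.0, 46.0, 94.0])
        np.testing.assert_allclose(got, 1.0 + 0.001 * (np.array([15.0, 46.0, 94.0]) - 10),
                                   rtol=1e-10)


class TestPathlengthSummary:
    def test_single_record_collapses(self):
        tab = toy_table([[10.0, 2.0, 1.0, 3.0]])
        s = pathlength_summary(tab, 10.0, "total")
        assert s.q1 == s.median == s.q3 == s.q4 == s.mean == pytest.approx(16.0)

    def test_total_dominates_fetal_component(self, table_dm4_735):
        sdd = table_dm4_735.detectors.sdds[5]
        total = pathlength_summary(table_dm4_735, sdd, "total")
        fetal = pathlength_summary(table_dm4_735, sdd, 3)
        assert total.mean >= fetal.mean
        assert total.q1 <= total.median <= total.q3

    def test_deeper_fetus_shrinks_fetal_pathlength_mass(
        self, table_dm4_735, table_dm14_735
    ):
        sdd = table_dm4_735.detectors.sdds[9]
        shallow = pathlength_summary(table_dm4_735, sdd, 3)
        deep = pathlength_summary(table_dm14_735, sdd, 3)
        assert deep.median < shallow.median

    def test_empty_ring_is_an_error(self):
        tab = toy_table([[10.0, 0.0, 0.0, 0.0]])
        with pytest.raises(UndefinedRatioError):
            pathlength_summary(tab, 20.0, "total")
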