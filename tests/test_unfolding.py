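"""Chemical and thermal unfolding thermodynamics."""

import numpy as np
import pytest

from foldscape import unfolding
from foldscape.synthetic import (
    DSCTruth,
    NoiseSpec,
    TwoStateTruth,
    gen_chemical_unfolding,
    gen_dsc_scan,
    two_state_fraction_unfolded,
)
from foldscape.unfolding import (
    EllipticitySeries,
    compensation_regression,
    compute_mre,
    dg_from_lem,
    fit_dsc,
    fit_two_state_chemical,
    fraction_unfolded,
    refolding_efficiency,
)

NOISELESS = NoiseSpec(model="none", sigma=0.0)


class TestMRE:
    def _series(self, theta):
        return EllipticitySeries(
            x=np.zeros(np.shape(theta) or (1,)),
            theta=np.atleast_1d(theta),
            concentration=0.15, path_length=0.1, molar_mass=31280.0, n_residues=271,
        )

    def test_printed_formula_arithmetic(self):
        mre = compute_mre(self._series(-0.02))
        assert mre[0] == pytest.approx(-15390, abs=5)

    def test_zero_signal_gives_zero(self):
        assert compute_mre(self._series(0.0))[0] == 0.0

    def test_doubling_concentration_halves_mre(self):
        s = self._series(-0.02)
        s2 = EllipticitySeries(
            x=s.x, theta=s.theta, concentration=0.3, path_length=0.1,
            molar_mass=31280.0, n_residues=271,
        )
        assert compute_mre(s2)[0] == pytest.approx(compute_mre(s)[0] / 2)

    def test_zero_concentration_rejected(self):
        with pytest.raises(ValueError):
            EllipticitySeries(
                x=np.zeros(1), theta=np.zeros(1), concentration=0.0,
                path_length=0.1, molar_mass=31280.0, n_residues=271,
            )


class TestFractionUnfolded:
    def test_baseline_endpoints(self):
        c = np.linspace(0, 8, 9)
        y_n, y_u = (-0.02, 0.0), (-0.004, 0.0)
        assert fraction_unfolded(c, np.full(9, -0.02), y_n, y_u)[0] == 0.0
        assert fraction_unfolded(c, np.full(9, -0.004), y_n, y_u)[0] == 1.0
        mid = np.full(9, -0.012)
        assert fraction_unfolded(c, mid, y_n, y_u)[0] == pytest.approx(0.5)

    def test_round_trip_from_generator(self):
        truth = TwoStateTruth(3.02, -0.736)
        c = np.linspace(0, 8, 33)
        s = gen_chemical_unfolding(truth, c, NOISELESS)
        fu = fraction_unfolded(s.x, s.theta, truth.native_baseline,
                               truth.unfolded_baseline)
        np.testing.assert_allclose(
            fu, two_state_fraction_unfolded(3.02, -0.736, c), atol=1e-9
        )

    def test_monotone_for_noiseless_two_state(self):
        truth = TwoStateTruth(3.02, -0.736)
        s = gen_chemical_unfolding(truth, np.linspace(0, 8, 33), NOISELESS)
        fu = fraction_unfolded(s.x, s.theta, truth.native_baseline,
                               truth.unfolded_baseline)
        assert np.all(np.diff(fu) >= 0)

    def test_crossing_baselines_rejected(self):
        c = np.linspace(0, 8, 9)
        with pytest.raises(ValueError):
            # gap y_N - y_U = -0.016 + 0.003 C changes sign at C = 5.3 M
            fraction_unfolded(c, np.zeros(9), (-0.02, 0.003), (-0.004, 0.0))


class TestLinearExtrapolation:
    def test_wild_type_printed_values(self):
        # m = -0.736 kcal/(mol M), midpoint 4.1 M -> dG(H2O) = 3.02 kcal/mol
        assert dg_from_lem(-0.736, 4.1) == pytest.approx(3.02, abs=0.005)

    def test_stabilized_variant_printed_values(self):
        dg = dg_from_lem(-1.416, 4.93)
        assert dg == pytest.approx(6.98, abs=0.005)
        assert dg - dg_from_lem(-0.736, 4.1) == pytest.approx(3.96, abs=0.01)

    def test_noiseless_round_trip_exact(self):
        truth = TwoStateTruth(3.02, -0.736)
        s = gen_chemical_unfolding(truth, np.linspace(0, 8, 33), NOISELESS)
        f = fit_two_state_chemical(s.x, s.theta)
        assert f.dg_h2o == pytest.approx(3.02, rel=1e-6)
        assert f.m_value == pytest.approx(-0.736, rel=1e-6)

    def test_fraction_input_round_trip(self):
        c = np.linspace(0, 8, 33)
        fu = two_state_fraction_unfolded(3.02, -0.736, c)
        f = fit_two_state_chemical(c, fu, signal_is_fraction=True)
        assert f.dg_h2o == pytest.approx(3.02, rel=1e-8)
        assert f.midpoint == pytest.approx(4.103, abs=0.005)

    def test_midpoint_identity_holds(self):
        truth = TwoStateTruth(6.98, -1.416)
        s = gen_chemical_unfolding(truth, np.linspace(0, 8, 33),
                                   NoiseSpec(sigma=0.01, seed=2))
        f = fit_two_state_chemical(s.x, s.theta)
        assert f.midpoint == pytest.approx(-f.dg_h2o / f.m_value, rel=1e-9)

    def test_insufficient_coverage_rejected(self):
        c = np.linspace(0, 2, 11)  # transition at 4.1 M never reached
        fu = two_state_fraction_unfolded(3.02, -0.736, c)
        with pytest.raises(ValueError):
            fit_two_state_chemical(c, fu, signal_is_fraction=True)

    def test_stability_ordering_recovered_on_variant_panel(self):
        # thermodynamic ordering of a synthetic mutant panel survives noisy
        # generation + refitting (rank correlation 1)
        panel = [(1.8, -0.8), (3.02, -0.736), (5.0, -1.1), (6.98, -1.416)]
        fitted = []
        for i, (dg, m) in enumerate(panel):
            s = gen_chemical_unfolding(
                TwoStateTruth(dg, m), np.linspace(0, 9, 37),
                NoiseSpec(sigma=0.01, seed=30 + i),
            )
            fitted.append(fit_two_state_chemical(s.x, s.theta).dg_h2o)
        assert np.all(np.diff(fitted) > 0)


class TestDSCFit:
    def test_wild_type_melting_temperature_recovered(self):
        # Tm = 329.35 K = 56.2 C
        tms = []
        for seed in range(10):
            scan = gen_dsc_scan(
                DSCTruth(tm=329.35, dh_vh=120.0),
                np.arange(298.15, 363.25, 0.1),
                NoiseSpec(sigma=0.01, seed=seed),
            )
            tms.append(fit_dsc(scan).tm - 273.15)
        assert np.median(tms) == pytest.approx(56.2, abs=0.2)

    def test_enthalpy_matches_peak_integral(self):
        scan = gen_dsc_scan(
            DSCTruth(tm=330.0, dh_vh=100.0, baseline=(0.5,)),
            np.linspace(270.0, 400.0, 2000), NOISELESS,
        )
        f = fit_dsc(scan)
        integral = np.trapezoid(
            scan.excess_cp - (f.baseline[0] + f.baseline[1] * scan.temperature),
            scan.temperature,
        )
        assert f.dh_vh == pytest.approx(integral, rel=0.02)

    def test_dg_vanishes_at_tm(self):
        scan = gen_dsc_scan(
            DSCTruth(tm=330.0, dh_vh=100.0), np.linspace(300, 360, 601), NOISELESS
        )
        f = fit_dsc(scan)
        f2 = fit_dsc(scan, reference_temperature=f.tm)
        assert f2.dg_ref == pytest.approx(0.0, abs=1e-9)
        assert f.ds_m * f.tm == pytest.approx(f.dh_vh, rel=1e-9)

    def test_parameter_recovery_over_seeds(self):
        tm_errs, dh_errs = [], []
        for seed in range(50):
            scan = gen_dsc_scan(
                DSCTruth(tm=329.35, dh_vh=120.0),
                np.arange(303.15, 358.15, 0.25),
                NoiseSpec(sigma=0.01, seed=seed),
            )
            f = fit_dsc(scan)
            tm_errs.append(abs(f.tm - 329.35))
            dh_errs.append(abs(f.dh_vh / 120.0 - 1.0))
        assert np.median(tm_errs) < 0.3
        assert np.median(dh_errs) < 0.05

    def test_unbracketed_peak_rejected(self):
        with pytest.warns(RuntimeWarning, match="bracket"):
            scan = gen_dsc_scan(
                DSCTruth(tm=360.0, dh_vh=100.0), np.linspace(300, 340, 100), NOISELESS
            )
        with pytest.raises(ValueError):
            fit_dsc(scan)

    def test_thermal_ordering_recovered_on_variant_panel(self):
        tms_true = [322.35, 329.35, 332.35, 336.35]  # V173D < WT < F133A < V173K
        fitted = []
        for i, tm in enumerate(tms_true):
            scan = gen_dsc_scan(
                DSCTruth(tm=tm, dh_vh=110.0),
                np.arange(293.15, 363.15, 0.2),
                NoiseSpec(sigma=0.01, seed=60 + i),
            )
            fitted.append(fit_dsc(scan).tm)
        assert np.all(np.diff(fitted) > 0)


class TestRefoldingEfficiency:
    def test_identity_and_ratio(self):
        assert refolding_efficiency(-15000.0, -15000.0) == 1.0
        assert refolding_efficiency(-9000.0, -15000.0) == pytest.approx(0.6)

    def test_linear_mixture(self):
        mre_native, mre_unfolded = -15000.0, -3000.0
        mixed = 0.85 * mre_native + 0.15 * mre_unfolded
        re = refolding_efficiency(mixed, mre_native)
        assert re == pytest.approx(0.85 + 0.15 * mre_unfolded / mre_native, rel=1e-12)

    def test_sign_mismatch_flagged(self):
        with pytest.warns(RuntimeWarning):
            refolding_efficiency(5000.0, -15000.0)

    def test_zero_native_rejected(self):
        with pytest.raises(ValueError):
            refolding_efficiency(-1.0, 0.0)


class TestCompensation:
    def test_exact_line_recovered(self):
        ds = np.array([0.30, 0.34, 0.38, 0.42])
        dh = 330.0 * ds + 2.0
        f = compensation_regression(list(zip(dh, ds)))
        assert f.slope == pytest.approx(330.0, rel=1e-9)
        assert f.intercept == pytest.approx(2.0, rel=1e-6)
        assert f.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_outlier_lowers_r_squared(self):
        ds = np.array([0.30, 0.34, 0.38, 0.42])
        dh = 330.0 * ds + 2.0
        dh[2] += 8.0
        assert compensation_regression(list(zip(dh, ds))).r_squared < 1.0

    def test_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        ds = rng.uniform(0.25, 0.45, 12)
        dh = 310.0 * ds + rng.normal(0, 1.0, 12)
        f = compensation_regression(list(zip(dh, ds)))
        # independent OLS via the normal equations
        a = np.vstack([ds, np.ones_like(ds)]).T
        slope, intercept = np.linalg.solve(a.T @ a, a.T @ dh)
        assert f.slope == pytest.approx(slope, abs=1e-10)
        assert f.intercept == pytest.approx(intercept, abs=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            compensation_regression([(100.0, 0.3), (110.0, 0.33)])
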