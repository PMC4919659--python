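"""Calibration and dissociation-constant estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

import flimscreen as fs


def make_cal(slope, fluorophore="x", tag=""):
    return fs.CalibrationCurve(fluorophore=fluorophore, slope=slope,
                               intercept=0.0, r_squared=1.0, n_points=5,
                               settings_tag=tag)


class TestIntensityCalibration:
    def test_exact_line(self):
        cal = fs.fit_intensity_calibration([0.0, 1.0, 2.0], [0.0, 100.0, 200.0])
        assert cal.slope == pytest.approx(100.0)
        assert cal.intercept == pytest.approx(0.0, abs=1e-9)
        assert cal.r_squared == pytest.approx(1.0)

    def test_noisy_slope_within_sampling_error(self):
        rng = np.random.default_rng(0)
        x = np.linspace(1.0, 10.0, 10)
        y = 100.0 * x + rng.normal(0.0, 1.0, 10)
        cal = fs.fit_intensity_calibration(x, y)
        se = 1.0 / np.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(cal.slope - 100.0) < 3 * se

    def test_duplicate_x_is_valid_with_r2_below_one(self):
        cal = fs.fit_intensity_calibration([1.0, 1.0, 2.0], [90.0, 110.0, 200.0])
        assert cal.r_squared < 1.0

    def test_too_few_points_or_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fs.fit_intensity_calibration([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            fs.fit_intensity_calibration([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_large_intercept_warns(self):
        with pytest.warns(UserWarning, match="intercept"):
            cal = fs.fit_intensity_calibration([1.0, 2.0, 3.0],
                                               [150.0, 250.0, 350.0])
        assert cal.intercept_warning


class TestComputeGamma:
    def test_worked_values(self):
        assert fs.compute_gamma(0.5, 2.0, 1.0) == pytest.approx(1.0)
        assert fs.compute_gamma(0.0, 5.0, 1.0) == 0.0
        assert fs.compute_gamma(0.25, 1.0, 2.0) == pytest.approx(0.125)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fs.compute_gamma(0.5, 1.0, 0.0)
        with pytest.raises(ValueError):
            fs.compute_gamma(1.5, 1.0, 1.0)


class TestEstimateKd:
    def test_round_trip_inverts_binding_equilibrium(self):
        """beta_true + exact intensities reproduce kd_true to 1e-10."""
        rng = np.random.default_rng(3)
        d = np.exp(rng.uniform(np.log(50), np.log(5000), 50))
        a = np.exp(rng.uniform(np.log(50), np.log(5000), 50))
        kd_true = 500.0
        da = fs.solve_binding_equilibrium(d, a, kd_true)
        beta = da / d
        c_d, c_a = 0.002, 0.5
        cal_d, cal_a = make_cal(c_d), make_cal(c_a)
        for b, dt, at in zip(beta, d, a):
            kd, flag = fs.estimate_kd_per_cell(b, c_d * dt, c_a * at,
                                               cal_d, cal_a)
            assert flag == "ok"
            assert abs(kd - kd_true) / kd_true < 1e-10

    def test_symmetric_worked_example(self):
        # d = a = 1 uM, beta = 0.5 -> kd = 0.5 uM
        kd, flag = fs.estimate_kd_per_cell(0.5, 0.002 * 1000, 0.5 * 1000,
                                           make_cal(0.002), make_cal(0.5))
        assert flag == "ok" and kd == pytest.approx(500.0, rel=1e-12)

    def test_stoichiometric_limit(self):
        kd, flag = fs.estimate_kd_per_cell(1.0 - 1e-9, 1000.0, 1000.0,
                                           make_cal(1.0), make_cal(1.0))
        assert flag == "ok"
        assert kd < 1e-5

    def test_degenerate_beta_flagged(self):
        for b in (0.0, 1.0):
            kd, flag = fs.estimate_kd_per_cell(b, 100.0, 100.0,
                                               make_cal(1.0), make_cal(1.0))
            assert flag == "beta_degenerate" and np.isnan(kd)

    def test_negative_free_acceptor_flagged(self):
        # beta * d_total = 1000 > a_total = 800
        kd, flag = fs.estimate_kd_per_cell(0.5, 2000.0, 800.0,
                                           make_cal(1.0), make_cal(1.0))
        assert flag in ("negative_free_acceptor", "gamma_out_of_range")
        assert np.isnan(kd)

    def test_gamma_out_of_range_flagged(self):
        # gamma = 0.9 * 2000 / 800 = 2.25 >> 1 + tol
        kd, flag = fs.estimate_kd_per_cell(0.9, 2000.0, 800.0,
                                           make_cal(1.0), make_cal(1.0))
        assert flag == "gamma_out_of_range"

    def test_invariant_under_joint_rescaling(self):
        """Scaling intensity and gain together leaves kd unchanged."""
        kd1, _ = fs.estimate_kd_per_cell(0.3, 2.0, 500.0,
                                         make_cal(0.002), make_cal(0.5))
        kd2, _ = fs.estimate_kd_per_cell(0.3, 2000.0, 50000.0,
                                         make_cal(2.0), make_cal(50.0))
        assert kd1 == pytest.approx(kd2, rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(d=st.floats(100.0, 5000.0), a=st.floats(100.0, 5000.0))
    def test_kd_monotone_decreasing_in_beta(self, d, a):
        assume(0.95 * a / d > 0.06)  # need a non-degenerate beta range
        betas = np.linspace(0.05, min(0.95, 0.95 * a / d), 20)
        kds = [fs.estimate_kd_per_cell(b, d, a, make_cal(1.0), make_cal(1.0))[0]
               for b in betas]
        kds = [k for k in kds if np.isfinite(k)]
        assert all(x > y for x, y in zip(kds, kds[1:]))

    def test_settings_tag_mismatch_rejected(self):
        cal = make_cal(1.0, tag="sectioned")
        with pytest.raises(ValueError, match="settings"):
            fs.estimate_kd_per_cell(0.5, 100.0, 100.0, cal, cal,
                                    settings_tag="widefield")


class TestAggregateKd:
    def _table(self, kds, flags=None, condition="c1"):
        n = len(kds)
        return pd.DataFrame({
            "condition": [condition] * n,
            "kd_nM": kds,
            "kd_flag": flags or ["ok"] * n,
        })

    def test_identical_cells(self):
        out = fs.aggregate_kd(self._table([500.0] * 12))
        assert out.loc[0, "kd_median_nM"] == 500.0
        assert out.loc[0, "kd_iqr_nM"] == 0.0

    def test_below_minimum_withheld(self):
        with pytest.warns(UserWarning, match="withheld"):
            out = fs.aggregate_kd(self._table([500.0] * 3))
        assert np.isnan(out.loc[0, "kd_median_nM"])
        assert out.loc[0, "n_ok"] == 3

    def test_flag_counts_reported(self):
        flags = ["ok"] * 10 + ["negative_free_acceptor", "beta_degenerate"]
        out = fs.aggregate_kd(self._table([500.0] * 12, flags))
        assert out.loc[0, "n_ok"] == 10
        assert out.loc[0, "n_negative_free_acceptor"] == 1
        assert out.loc[0, "n_beta_degenerate"] == 1
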