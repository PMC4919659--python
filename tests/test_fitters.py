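"""Lifetime fitters: closed forms, round trips, oracle equivalence, bias."""

import numpy as np
import pytest
from scipy.optimize import least_squares

import flimscreen as fs
from flimscreen.decay import gate_basis, model_gate_signal


def simulate_decay(amplitude, beta, tau_da, tau_d, scheme, irf, background=0.0):
    fr = [beta, 1.0 - beta] if 0 < beta < 1 else ([1.0] if beta == 1 else [1.0])
    taus = [tau_da, tau_d] if 0 < beta < 1 else ([tau_da] if beta == 1 else [tau_d])
    return model_gate_signal(amplitude, taus, fr, irf, scheme, background=background)


class TestMonoexponential:
    def test_two_gate_closed_form(self, delta_irf):
        """With two noiseless gates the fit equals tau = dt / ln(N1/N2)."""
        sch = fs.GateScheme(gate_delays=(0.0, 1000.0), gate_width=1000.0,
                            rep_period=1e9)
        fit = fs.fit_monoexponential(np.array([1000.0, 1000.0 * np.exp(-1.0)]),
                                     sch, delta_irf)
        assert fit.converged
        assert fit.tau == pytest.approx(1000.0, rel=1e-9)

    def test_noiseless_round_trip_measured_irf(self, scheme, measured_irf):
        y = simulate_decay(4.0, 0.0, None, 2200.0, scheme, measured_irf,
                           background=2.0)
        fit = fs.fit_monoexponential(y, scheme, measured_irf, background=2.0)
        assert fit.tau == pytest.approx(2200.0, rel=1e-3)
        assert fit.i0 == pytest.approx(4.0, rel=5e-3)

    def test_mixture_yields_intermediate_effective_lifetime(self, scheme, delta_irf):
        y = simulate_decay(5.0, 0.5, 1200.0, 2400.0, scheme, delta_irf)
        fit = fs.fit_monoexponential(y, scheme, delta_irf)
        assert 1200.0 < fit.tau < 2400.0

    def test_invariant_to_count_rescaling(self, scheme, delta_irf):
        y = simulate_decay(1.0, 0.3, 1300.0, 2400.0, scheme, delta_irf)
        t1 = fs.fit_monoexponential(y, scheme, delta_irf).tau
        t2 = fs.fit_monoexponential(1e4 * y, scheme, delta_irf).tau
        assert t2 == pytest.approx(t1, rel=1e-4)

    def test_all_background_flagged_unfittable(self, scheme, delta_irf):
        fit = fs.fit_monoexponential(np.full(5, 3.0), scheme, delta_irf,
                                     background=3.0)
        assert not fit.converged
        assert np.isnan(fit.tau)

    def test_pixelwise_matches_single_and_respects_mask(self, scheme, delta_irf):
        amp = np.array([[2.0, 4.0], [8.0, 1.0]])
        basis = gate_basis([2000.0], scheme, delta_irf)[:, 0]
        frames = amp[None] * basis[:, None, None]
        mask = np.array([[True, True], [False, True]])
        res = fs.fit_monoexponential_pixels(frames, scheme, delta_irf, mask=mask)
        assert np.isnan(res.tau[1, 0])
        np.testing.assert_allclose(res.tau[mask], 2000.0, rtol=1e-9)
        np.testing.assert_allclose(res.i0[mask], amp[mask], rtol=1e-9)

    def test_poisson_bias_small_at_1e4_photons(self, scheme, delta_irf):
        """Bias of tau under Poisson noise < 1% at ~1e4 photons, 100 reps."""
        rng = np.random.default_rng(12345)
        tau_true = 2200.0
        y0 = simulate_decay(3.0, 0.0, None, tau_true, scheme, delta_irf)
        scale = 1.0e4 / y0.sum()
        y0 = y0 * scale  # ~1e4 photons total
        taus = []
        ev = fs.GateBasisEvaluator(scheme, delta_irf)
        for _ in range(100):
            y = rng.poisson(y0).astype(float)
            taus.append(fs.fit_monoexponential(y, scheme, delta_irf,
                                               evaluator=ev).tau)
        assert abs(np.mean(taus) - tau_true) / tau_true < 0.01


class TestGlobalBiexponential:
    tau_d, tau_da = 2400.0, 1300.0

    def _cells(self, scheme, irf, betas, amps, noise_rng=None, photons=None):
        basis = gate_basis([self.tau_da, self.tau_d], scheme, irf)
        y = amps[:, None] * (betas[:, None] * basis[:, 0]
                             + (1 - betas)[:, None] * basis[:, 1])
        if photons is not None:
            y = y * (photons / y.sum(axis=1, keepdims=True))
        if noise_rng is not None:
            y = noise_rng.poisson(y).astype(float)
        return y

    def test_matches_brute_force_nonlinear_least_squares(self, scheme, delta_irf):
        """Variable projection equals a full joint NLLS on 3 cells x 5 gates."""
        betas = np.array([0.2, 0.5, 0.8])
        amps = np.array([3.0, 2.0, 1.0])
        y = self._cells(scheme, delta_irf, betas, amps)
        gfit = fs.fit_global_biexponential(y, self.tau_d, scheme, delta_irf)

        wgt = 1.0 / np.maximum(y, 1.0)
        ev = fs.GateBasisEvaluator(scheme, delta_irf)
        g_d = ev(np.array([self.tau_d]))[:, 0]

        def resid(p):
            tau_da, a = p[0], p[1:].reshape(3, 2)
            g_q = ev(np.array([tau_da]))[:, 0]
            model = a[:, :1] * g_q + a[:, 1:] * g_d
            return (np.sqrt(wgt) * (y - model)).ravel()

        x0 = np.concatenate([[1000.0], np.tile([1.0, 1.0], 3)])
        brute = least_squares(resid, x0, bounds=([200.0] + [0.0] * 6,
                                                 [2300.0] + [np.inf] * 6),
                              xtol=1e-15, ftol=1e-15, gtol=1e-15)
        tau_brute = brute.x[0]
        a_brute = brute.x[1:].reshape(3, 2)
        beta_brute = a_brute[:, 0] / a_brute.sum(axis=1)
        assert gfit.tau_da == pytest.approx(tau_brute, abs=1.0)
        np.testing.assert_allclose(gfit.beta, beta_brute, atol=1e-6)

    def test_optimum_beats_every_grid_point(self, scheme, delta_irf):
        """Oracle inequality: pooled residual at the optimum is the minimum."""
        rng = np.random.default_rng(5)
        betas = rng.uniform(0.1, 0.9, 5)
        amps = rng.uniform(1.0, 5.0, 5)
        y = self._cells(scheme, delta_irf, betas, amps, noise_rng=rng,
                        photons=5e3)
        gfit = fs.fit_global_biexponential(y, self.tau_d, scheme, delta_irf)
        ev = fs.GateBasisEvaluator(scheme, delta_irf)
        for tau in np.linspace(300.0, 2200.0, 40):
            alt = fs.fit_global_biexponential(
                y, self.tau_d, scheme, delta_irf,
                tau_bounds=(tau - 1e-6, tau + 1e-6), evaluator=ev)
            assert gfit.chi2_pooled <= alt.chi2_pooled + 1e-9

    def test_parameter_recovery_30_cells(self, scheme, delta_irf):
        """tau_DA within 50 ps and per-cell beta within 0.05.

        5e4 photons/cell: conservative relative to the simulated screening
        cells (median ~6e5 photons over a 300-px mask) while the per-cell
        beta statistical error (~0.01) leaves headroom under the bound.
        """
        rng = np.random.default_rng(777)
        betas = np.tile([0.2, 0.5, 0.8], 10)
        amps = np.ones(30)
        y = self._cells(scheme, delta_irf, betas, amps, noise_rng=rng,
                        photons=5e4)
        gfit = fs.fit_global_biexponential(y, self.tau_d, scheme, delta_irf)
        assert gfit.identifiable
        assert gfit.tau_da == pytest.approx(self.tau_da, abs=50.0)
        np.testing.assert_allclose(gfit.beta, betas, atol=0.05)

    def test_recovery_bias_across_replicates(self, scheme, delta_irf):
        """Across 100 replicates at 1e4 photons/cell: |beta bias| < 0.02,
        |tau_DA bias| < 2%."""
        rng = np.random.default_rng(31)
        betas = np.tile([0.2, 0.5, 0.8], 4)
        amps = np.ones(12)
        ev = fs.GateBasisEvaluator(scheme, delta_irf)
        dbeta, dtau = [], []
        for _ in range(100):
            y = self._cells(scheme, delta_irf, betas, amps, noise_rng=rng,
                            photons=1e4)
            g = fs.fit_global_biexponential(y, self.tau_d, scheme, delta_irf,
                                            evaluator=ev)
            dbeta.append(np.mean(g.beta - betas))
            dtau.append(g.tau_da - self.tau_da)
        assert abs(np.mean(dbeta)) < 0.02
        assert abs(np.mean(dtau)) / self.tau_da < 0.02

    def test_absent_component_flags_unidentifiable(self, scheme, delta_irf):
        rng = np.random.default_rng(4)
        y = self._cells(scheme, delta_irf, np.zeros(10), np.ones(10),
                        noise_rng=rng, photons=2e4)
        with pytest.warns(UserWarning, match="unidentifiable"):
            gfit = fs.fit_global_biexponential(y, self.tau_d, scheme, delta_irf)
        assert not gfit.identifiable
        assert np.all(gfit.beta < 0.02)


class TestSummarizeLifetime:
    def test_arithmetic_and_limits(self):
        g = fs.GlobalFitResult(
            tau_d=2400.0, tau_da=1200.0, beta=np.array([0.0, 0.5, 1.0]),
            i0=np.ones(3), amplitudes=np.zeros((3, 2)),
            chi2_reduced=np.zeros(3), chi2_pooled=0.0, identifiable=True,
            at_bound=False, clipped=np.zeros(3, bool))
        np.testing.assert_allclose(fs.summarize_lifetime(g),
                                   [2400.0, 1800.0, 1200.0])

    def test_monotone_decreasing_in_beta(self):
        beta = np.linspace(0.0, 1.0, 11)
        g = fs.GlobalFitResult(
            tau_d=2400.0, tau_da=1300.0, beta=beta, i0=np.ones(11),
            amplitudes=np.zeros((11, 2)), chi2_reduced=np.zeros(11),
            chi2_pooled=0.0, identifiable=True, at_bound=False,
            clipped=np.zeros(11, bool))
        mean = fs.summarize_lifetime(g)
        assert np.all(np.diff(mean) < 0)

    def test_unconverged_mono_is_nan(self, scheme, delta_irf):
        fit = fs.fit_monoexponential(np.zeros(5), scheme, delta_irf)
        assert np.isnan(fs.summarize_lifetime(fit))
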