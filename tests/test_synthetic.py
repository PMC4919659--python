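"""Synthetic plate generator: determinism, forward-model agreement, noise."""

import numpy as np
import pytest

import flimscreen as fs
from flimscreen.decay import gate_basis
from flimscreen.synthetic import generate_cell_field, render_time_gated_stack


def small_config(**kw):
    defaults = dict(image_shape=(96, 96), cells_per_fov=6, seed=5)
    defaults.update(kw)
    return fs.SyntheticPlateConfig(**defaults)


class TestGenerateCellField:
    def test_zero_cells_gives_empty_field(self):
        cfg = small_config()
        labels, truth = generate_cell_field(cfg, np.random.default_rng(0), n_cells=0)
        assert labels.sum() == 0
        assert truth.n_cells == 0

    def test_fixed_seed_is_bit_identical(self):
        cfg = small_config()
        out1 = generate_cell_field(cfg, np.random.default_rng(42))
        out2 = generate_cell_field(cfg, np.random.default_rng(42))
        np.testing.assert_array_equal(out1[0], out2[0])
        np.testing.assert_array_equal(out1[1].d_total, out2[1].d_total)

    def test_cells_disjoint_and_consistent_with_truth(self):
        cfg = small_config()
        labels, truth = generate_cell_field(cfg, np.random.default_rng(3))
        assert labels.max() == truth.n_cells == cfg.cells_per_fov
        assert np.nanmax(truth.equilibrium_residual()) < 1e-10

    def test_log_spread_expression_gives_wide_ratio_range(self):
        """Uncorrelated log-uniform expression: >= 10-fold ratio spread."""
        cfg = fs.SyntheticPlateConfig(image_shape=(512, 512), cells_per_fov=50, seed=5)
        _, truth = generate_cell_field(cfg, np.random.default_rng(7))
        ratio = truth.a_total / truth.d_total
        assert ratio.max() / ratio.min() >= 10.0

    def test_infeasible_packing_raises(self):
        cfg = small_config(cells_per_fov=500)
        with pytest.raises(RuntimeError, match="could not place"):
            generate_cell_field(cfg, np.random.default_rng(0))


class TestRenderTimeGatedStack:
    def test_noiseless_counts_equal_analytic_gate_integrals(self):
        cfg = small_config(noise=False)
        rng = np.random.default_rng(2)
        labels, truth = generate_cell_field(cfg, rng)
        stack, acceptor = render_time_gated_stack(labels, truth, cfg, rng)
        basis = gate_basis([cfg.tau_da, cfg.tau_d], cfg.scheme, cfg.irf)
        i = 3  # any cell
        beta = truth.beta_true[i - 1]
        expected = cfg.c_d * truth.d_total[i - 1] * (
            beta * basis[:, 0] + (1 - beta) * basis[:, 1]
        ) + np.asarray(cfg.background_donor)
        pix = np.argwhere(labels == i)[0]
        np.testing.assert_allclose(stack.frames[:, pix[0], pix[1]], expected, rtol=1e-12)
        np.testing.assert_allclose(
            acceptor[pix[0], pix[1]],
            cfg.c_a * truth.a_total[i - 1] + cfg.background_acceptor, rtol=1e-12)

    def test_beta_zero_everywhere_is_pure_donor_decay(self):
        cfg = small_config(noise=False)
        rng = np.random.default_rng(4)
        labels, truth = generate_cell_field(cfg, rng, binding=False)
        stack, _ = render_time_gated_stack(labels, truth, cfg, rng)
        pix = np.argwhere(labels == 1)[0]
        y = stack.frames[:, pix[0], pix[1]]
        fit = fs.fit_monoexponential(y, cfg.scheme, cfg.irf,
                                     background=np.asarray(cfg.background_donor))
        assert fit.tau == pytest.approx(cfg.tau_d, rel=1e-6)

    def test_counts_linear_in_donor_gain(self):
        rng_lab = np.random.default_rng(6)
        cfg1 = small_config(noise=False, c_d=0.002)
        cfg2 = small_config(noise=False, c_d=0.004)
        labels, truth = generate_cell_field(cfg1, rng_lab)
        bg = np.asarray(cfg1.background_donor)
        s1, _ = render_time_gated_stack(labels, truth, cfg1, np.random.default_rng(0))
        s2, _ = render_time_gated_stack(labels, truth, cfg2, np.random.default_rng(0))
        np.testing.assert_allclose(s2.frames - bg[:, None, None],
                                   2 * (s1.frames - bg[:, None, None]), atol=1e-9)

    def test_poisson_mean_converges_to_expectation(self):
        """Mean over many noisy replicates approaches the analytic stack."""
        cfg = small_config(image_shape=(32, 32), cells_per_fov=1,
                           radius_range=(8.0, 8.0))
        rng = np.random.default_rng(9)
        labels, truth = generate_cell_field(cfg, rng)
        exact, _ = render_time_gated_stack(labels, truth, cfg, rng, noise=False)
        n_rep = 1000
        acc = np.zeros_like(exact.frames)
        for _ in range(n_rep):
            s, _ = render_time_gated_stack(labels, truth, cfg, rng, noise=True)
            acc += s.frames
        mean = acc / n_rep
        se = np.sqrt(exact.frames / n_rep)
        # allow 5 sigma per pixel: ~5120 pixel-gates, a handful of 3-sigma
        # excursions are expected by chance
        assert np.all(np.abs(mean - exact.frames) < 5 * se + 1e-9)
        # and the summed decay (the fitted quantity) is within 3 SE per gate
        tot = mean.sum(axis=(1, 2))
        tot_exact = exact.frames.sum(axis=(1, 2))
        assert np.all(np.abs(tot - tot_exact) < 3 * np.sqrt(tot_exact / n_rep))


class TestSimulatePlate:
    def test_plate_determinism_and_metadata(self):
        cfg = small_config()
        lay = fs.default_screen_layout(n_test_fov=1, n_donor_fov=1, n_negative_fov=1)
        p1 = fs.simulate_plate(cfg, lay, seed=99)
        p2 = fs.simulate_plate(cfg, lay, seed=99)
        assert p1.config.seed == 99  # seed recorded
        for f1, f2 in zip(p1.fovs, p2.fovs):
            np.testing.assert_array_equal(f1.donor.frames, f2.donor.frames)
            np.testing.assert_array_equal(f1.acceptor, f2.acceptor)

    def test_truth_table_has_one_row_per_cell(self):
        cfg = small_config()
        lay = fs.default_screen_layout(n_test_fov=2, n_donor_fov=1, n_negative_fov=1)
        plate = fs.simulate_plate(cfg, lay)
        tt = plate.truth_table()
        assert len(tt) == 4 * cfg.cells_per_fov
        assert set(tt["role"]) == {"donor_only", "negative_control", "test"}
        # negative control carries no complex
        assert (tt[tt.role == "negative_control"]["beta_true"] == 0).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="tau_da"):
            fs.SyntheticPlateConfig(tau_d=1000.0, tau_da=2000.0)
        with pytest.raises(ValueError, match="gains"):
            fs.SyntheticPlateConfig(c_d=0.0)
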