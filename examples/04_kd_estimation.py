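"""Dissociation constants from FRET fractions and calibrated intensities.

Continues from the analysed plate: fits the intensity-vs-concentration
calibration lines, converts each cell's fitted t=0 donor intensity and mean
acceptor intensity to concentrations, and inverts the binding equilibrium
per cell, K_D = (1 - beta)(A_total - beta * D_total) / beta.
"""

import warnings

import flimscreen as fs

warnings.filterwarnings("ignore")

config = fs.SyntheticPlateConfig(seed=1)
plate = fs.simulate_plate(config, fs.default_screen_layout())
result = fs.analyze_plate(plate)

cal_d, cal_a = result.calibration_donor, result.calibration_acceptor
print(f"donor calibration:    slope {cal_d.slope:.5f} counts/ps/nM "
      f"(true {config.c_d}), R^2 = {cal_d.r_squared:.6f}")
print(f"acceptor calibration: slope {cal_a.slope:.4f} counts/nM "
      f"(true {config.c_a}), R^2 = {cal_a.r_squared:.6f}")

g = result.global_fits["EGFP-RASSF1+mCherry-SARAH"]
print(f"\nglobal fit: tau_DA = {g.tau_da:.0f} ps, "
      f"beta spans {g.beta.min():.2f}-{g.beta.max():.2f} across cells")

summary = result.kd_summary.iloc[0]
print(f"\nper-cell K_D over {summary.n_ok} valid cells "
      f"(of {summary.n_cells}; true K_D = {config.kd_true:.0f} nM):")
print(f"  median {summary.kd_median_nM:.0f} nM, "
      f"IQR {summary.kd_iqr_nM:.0f} nM, mean {summary.kd_mean_nM:.0f} nM")
print(f"  excluded: {summary.n_beta_degenerate} beta-degenerate, "
      f"{summary.n_gamma_out_of_range} gamma>1, "
      f"{summary.n_negative_free_acceptor} negative free acceptor")
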