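"""Per-cell dissociation constants from FRET fractions and calibrated intensities.

The FRET amplitude fraction ``beta`` from the global fit gives the complex
concentration through the donor side, ``[DA] = beta * D_total``; the acceptor
bound fraction follows as ``gamma = beta * D_total / A_total``.  With total
concentrations obtained from calibrated fluorescence intensities
(``D_total = I_D0 / c_D`` from the fitted t = 0 donor intensity,
``A_total = I_A / c_A`` from the background-subtracted mean acceptor
intensity), the dissociation constant per cell is

    K_D = [D][A] / [DA] = (1 - beta) * (A_total - beta * D_total) / beta,

algebraically identical to free-donor x free-acceptor / complex.  The fitted
t = 0 intensity is used for the donor (rather than total intensity) because
FRETing and non-FRETing donors differ in brightness through their lifetimes.

Cells where the algebra breaks down physically — beta at a degenerate value,
negative implied free acceptor, acceptor bound fraction above one — are
flagged and excluded from aggregates rather than truncated, to avoid biasing
the condition medians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "fit_intensity_calibration",
    "compute_gamma",
    "estimate_kd_per_cell",
    "estimate_kd_table",
    "aggregate_kd",
]

#: validity flags, in precedence order
FLAG_OK = "ok"
FLAG_BETA = "beta_degenerate"
FLAG_GAMMA = "gamma_out_of_range"
FLAG_NEG_A = "negative_free_acceptor"


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear intensity-vs-concentration calibration for one fluorophore.

    ``slope`` converts concentration (nM) to mean per-pixel signal; the curve
    only applies to data acquired with the matching ``settings_tag`` (e.g.
    optically sectioned calibrations must not be applied to wide-field data).
    """

    fluorophore: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    settings_tag: str = ""
    intercept_warning: bool = False

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("calibration slope must be positive")

    def to_concentration(self, intensity: np.ndarray | float) -> np.ndarray | float:
        """Invert the line: concentration (nM) for a background-free signal."""
        return (np.asarray(intensity, dtype=float) - self.intercept) / self.slope


def fit_intensity_calibration(
    concentrations: np.ndarray,
    intensities: np.ndarray,
    fluorophore: str = "",
    settings_tag: str = "",
) -> CalibrationCurve:
    """Ordinary least-squares line through dye-solution calibration points.

    Requires at least three points with non-zero concentration variance.
    Emits a warning (and sets ``intercept_warning``) when the fitted
    intercept exceeds 10 % of the mid-range signal, which usually indicates
    an unsubtracted background.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("calibration needs >= 3 matched points")
    if np.ptp(x) == 0:
        raise ValueError("calibration concentrations have zero variance")
    fit = stats.linregress(x, y)
    mid_signal = fit.intercept + fit.slope * 0.5 * (x.min() + x.max())
    warn = abs(fit.intercept) > 0.1 * abs(mid_signal) and mid_signal != 0
    if warn:
        warnings.warn(
            f"calibration intercept {fit.intercept:.3g} exceeds 10% of the "
            f"mid-range signal {mid_signal:.3g}; check background subtraction",
            stacklevel=2)
    return CalibrationCurve(
        fluorophore=fluorophore, slope=float(fit.slope),
        intercept=float(fit.intercept), r_squared=float(fit.rvalue ** 2),
        n_points=int(x.size), settings_tag=settings_tag,
        intercept_warning=bool(warn),
    )


def compute_gamma(beta, d_total, a_total):
    """Bound fraction of acceptor molecules, ``gamma = beta * D_total / A_total``.

    Values above one are physically impossible (more complex than acceptor)
    and signal a measurement inconsistency; they are returned as-is so the
    caller can flag them.
    """
    b = np.asarray(beta, dtype=float)
    d = np.asarray(d_total, dtype=float)
    a = np.asarray(a_total, dtype=float)
    if np.any(a <= 0):
        raise ValueError("a_total must be positive")
    if np.any((b < 0) | (b > 1)):
        raise ValueError("beta must lie in [0, 1]")
    out = b * d / a
    if np.isscalar(beta) and np.isscalar(d_total) and np.isscalar(a_total):
        return float(out)
    return out


def estimate_kd_per_cell(
    beta: float,
    i_d0: float,
    i_a: float,
    cal_d: CalibrationCurve,
    cal_a: CalibrationCurve,
    gamma_tol: float = 0.05,
    settings_tag: str | None = None,
) -> tuple[float, str]:
    """K_D (nM) for one cell with a validity flag; NaN when not estimable.

    ``i_d0`` is the fitted t = 0 donor intensity, ``i_a`` the
    background-subtracted mean acceptor intensity.  ``settings_tag``, when
    given, must match both calibrations' acquisition-settings tags.
    """
    kd, flag = _kd_core(np.atleast_1d(float(beta)), np.atleast_1d(float(i_d0)),
                        np.atleast_1d(float(i_a)), cal_d, cal_a, gamma_tol,
                        settings_tag)
    return float(kd[0]), str(flag[0])


def _check_tag(cal: CalibrationCurve, settings_tag: str | None) -> None:
    if settings_tag is not None and cal.settings_tag and cal.settings_tag != settings_tag:
        raise ValueError(
            f"calibration for {cal.fluorophore!r} was acquired with settings "
            f"{cal.settings_tag!r}, data with {settings_tag!r}")


def _kd_core(beta, i_d0, i_a, cal_d, cal_a, gamma_tol, settings_tag):
    _check_tag(cal_d, settings_tag)
    _check_tag(cal_a, settings_tag)
    d_total = np.asarray(cal_d.to_concentration(i_d0), dtype=float)
    a_total = np.asarray(cal_a.to_concentration(i_a), dtype=float)
    beta = np.asarray(beta, dtype=float)

    kd = np.full(beta.shape, np.nan)
    flags = np.full(beta.shape, FLAG_OK, dtype=object)

    degenerate = ~((beta > 0) & (beta < 1)) | ~(d_total > 0)
    flags[degenerate] = FLAG_BETA

    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where((a_total > 0) & ~degenerate, beta * d_total / np.where(a_total > 0, a_total, 1.0), np.inf)
    bad_gamma = ~degenerate & (gamma > 1.0 + gamma_tol)
    flags[bad_gamma] = FLAG_GAMMA

    free_a = a_total - beta * d_total
    neg_a = ~degenerate & ~bad_gamma & (free_a <= 0)
    flags[neg_a] = FLAG_NEG_A

    ok = flags == FLAG_OK
    kd[ok] = (1.0 - beta[ok]) * free_a[ok] / beta[ok]
    return kd, flags


def estimate_kd_table(
    cells: pd.DataFrame,
    cal_d: CalibrationCurve,
    cal_a: CalibrationCurve,
    beta_col: str = "beta",
    i_d0_col: str = "i_d0",
    i_a_col: str = "i_a",
    gamma_tol: float = 0.05,
    settings_tag: str | None = None,
) -> pd.DataFrame:
    """Vectorised per-cell K_D over a cell table.

    Returns a copy of ``cells`` with ``d_total_nM``, ``a_total_nM``,
    ``gamma``, ``kd_nM`` and ``kd_flag`` columns appended.
    """
    out = cells.copy()
    beta = out[beta_col].to_numpy(dtype=float)
    i_d0 = out[i_d0_col].to_numpy(dtype=float)
    i_a = out[i_a_col].to_numpy(dtype=float)
    kd, flags = _kd_core(beta, i_d0, i_a, cal_d, cal_a, gamma_tol, settings_tag)
    d_total = np.asarray(cal_d.to_concentration(i_d0), dtype=float)
    a_total = np.asarray(cal_a.to_concentration(i_a), dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(a_total > 0, beta * d_total / np.where(a_total > 0, a_total, 1.0), np.nan)
    out["d_total_nM"] = d_total
    out["a_total_nM"] = a_total
    out["gamma"] = gamma
    out["kd_nM"] = kd
    out["kd_flag"] = flags.astype(str)
    return out


def aggregate_kd(
    kd_table: pd.DataFrame,
    group_cols: str | list[str] = "condition",
    min_ok_cells: int = 10,
) -> pd.DataFrame:
    """Condition-level K_D summary over flagged-ok cells.

    Reports the median (robust to the heavy right tail of per-cell K_D),
    interquartile range and mean per group, plus counts of cells excluded by
    each flag.  Aggregates for groups with fewer than ``min_ok_cells`` valid
    cells are withheld (NaN) with a warning.
    """
    if isinstance(group_cols, str):
        group_cols = [group_cols]
    rows = []
    for key, grp in kd_table.groupby(group_cols, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        ok = grp[grp["kd_flag"] == FLAG_OK]["kd_nM"].to_numpy()
        row = dict(zip(group_cols, key))
        row["n_cells"] = len(grp)
        row["n_ok"] = len(ok)
        for flag in (FLAG_BETA, FLAG_GAMMA, FLAG_NEG_A):
            row[f"n_{flag}"] = int((grp["kd_flag"] == flag).sum())
        if len(ok) >= min_ok_cells:
            q1, med, q3 = np.percentile(ok, [25, 50, 75])
            row.update(kd_median_nM=med, kd_iqr_nM=q3 - q1, kd_q1_nM=q1,
                       kd_q3_nM=q3, kd_mean_nM=float(np.mean(ok)))
        else:
            warnings.warn(
                f"group {key}: only {len(ok)} valid cells "
                f"(< {min_ok_cells}); K_D aggregate withheld", stacklevel=2)
            row.update(kd_median_nM=np.nan, kd_iqr_nM=np.nan, kd_q1_nM=np.nan,
                       kd_q3_nM=np.nan, kd_mean_nM=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
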