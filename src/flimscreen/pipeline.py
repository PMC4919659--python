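"""Plate-scale orchestration: from gate stacks to interaction calls and K_D.

`analyze_plate` runs the full chain on a (simulated or loaded) plate:

1. per-gate time-varying background from the blank (buffer-only) well;
2. plate-level ``t0`` from the reference-dye well (known lifetime, fixed);
3. per FOV: segmentation, pixel-wise monoexponential fits, per-cell
   aggregation of intensities and summed decays;
4. the unquenched donor lifetime ``tau_d`` per donor construct from
   donor-only wells, then a global double-exponential fit per co-transfected
   condition (shared ``tau_da``, per-cell ``beta``);
5. the plate-level significance threshold (twice the largest donor-only vs.
   negative-control mean-lifetime difference) and per-condition calls;
6. intensity calibrations from dye dilution wells and per-cell K_D for the
   co-transfected conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decay import GateBasisEvaluator, T0Estimate, estimate_background, \
    estimate_t0_from_reference
from .fitters import GlobalFitResult, fit_global_biexponential, \
    fit_monoexponential_pixels
from .kd import CalibrationCurve, aggregate_kd, estimate_kd_table, \
    fit_intensity_calibration
from .segmentation import segment_cells
from .synthetic import SimulatedPlate

__all__ = [
    "AnalysisParams",
    "PlateResult",
    "aggregate_per_cell",
    "significance_threshold",
    "call_interactions",
    "analyze_plate",
    "render_outputs",
]


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable analysis settings (defaults match the screening protocol)."""

    k_sigma: float = 5.0           # segmentation threshold in robust sigmas
    min_area: int = 100            # px; smaller objects dropped
    exclude_border: bool = True
    tau_bounds: tuple[float, float] = (200.0, 8000.0)   # mono fit search, ps
    tau_da_margin: float = 100.0   # global fit upper bound: tau_d - margin
    tau_da_min: float = 200.0
    reference_lifetime: float | None = None  # required if reference wells exist
    min_ok_cells: int = 10
    gamma_tol: float = 0.05
    settings_tag: str = ""


# ---------------------------------------------------------------------------
# per-cell aggregation
# ---------------------------------------------------------------------------

def aggregate_per_cell(
    frames: np.ndarray,
    acceptor_image: np.ndarray | None,
    labels: np.ndarray,
    donor_background: np.ndarray,
    acceptor_background: float = 0.0,
    tau_map: np.ndarray | None = None,
    i0_map: np.ndarray | None = None,
    min_area: int = 1,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Per-cell records plus summed decays for global fitting.

    Returns ``(table, decays, decay_backgrounds)`` where ``decays`` is the
    raw gate-count sum over each retained cell mask (shape ``(n, G)``) and
    ``decay_backgrounds`` the matching per-gate background scaled by pixel
    count.  The table carries pixel count, mean background-subtracted gate-0
    donor intensity ``i_d_gate0``, per-pixel mean fitted t = 0 intensity
    ``i_d0``, mean background-subtracted acceptor intensity ``i_a``, the
    acceptor/donor ratio (NaN when the donor mean is not positive), the mean
    pixel-wise mono lifetime, and a border flag.  Labels smaller than
    ``min_area`` are dropped with a log entry.
    """
    frames = np.asarray(frames, dtype=float)
    G = frames.shape[0]
    lab = np.asarray(labels)
    n = int(lab.max())
    bg = np.asarray(donor_background, dtype=float).reshape(G)
    if n == 0:
        empty = pd.DataFrame(columns=[
            "cell", "n_pixels", "i_d_gate0", "i_d0", "i_a", "ratio",
            "tau_mono", "border"])
        return empty, np.empty((0, G)), np.empty((0, G))

    flat = lab.ravel()
    npix = np.bincount(flat, minlength=n + 1)[1:]
    sums = np.stack([np.bincount(flat, weights=frames[g].ravel(),
                                 minlength=n + 1)[1:] for g in range(G)], axis=1)

    border = np.zeros(n + 1, dtype=bool)
    for edge in (lab[0], lab[-1], lab[:, 0], lab[:, -1]):
        border[np.unique(edge)] = True
    border = border[1:]

    i_d_gate0 = sums[:, 0] / npix - bg[0]
    if acceptor_image is not None:
        acc_sums = np.bincount(flat, weights=np.asarray(acceptor_image, float).ravel(),
                               minlength=n + 1)[1:]
        i_a = acc_sums / npix - acceptor_background
    else:
        i_a = np.full(n, np.nan)

    def masked_mean(img):
        if img is None:
            return np.full(n, np.nan)
        v = np.asarray(img, dtype=float).ravel()
        good = np.isfinite(v)
        cnt = np.bincount(flat[good], minlength=n + 1)[1:]
        tot = np.bincount(flat[good], weights=v[good], minlength=n + 1)[1:]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)

    tau_mono = masked_mean(tau_map)
    i_d0 = masked_mean(i0_map)

    keep = npix >= min_area
    dropped = np.flatnonzero(~keep)
    if dropped.size:
        warnings.warn(f"dropped {dropped.size} labels below min_area={min_area}",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(i_d_gate0 > 0, i_a / np.where(i_d_gate0 > 0, i_d_gate0, 1.0), np.nan)
    table = pd.DataFrame({
        "cell": np.arange(1, n + 1)[keep],
        "n_pixels": npix[keep],
        "i_d_gate0": i_d_gate0[keep],
        "i_d0": i_d0[keep],
        "i_a": i_a[keep],
        "ratio": ratio[keep],
        "tau_mono": tau_mono[keep],
        "border": border[keep],
    })
    decays = sums[keep]
    decay_bg = np.outer(npix[keep], bg)
    return table, decays, decay_bg


# ---------------------------------------------------------------------------
# interaction calling
# ---------------------------------------------------------------------------

def significance_threshold(control_deltas) -> float:
    """Plate-level lifetime-shift threshold: twice the largest control shift.

    ``control_deltas`` are the donor-only minus negative-control mean
    lifetime differences (ps), one per donor construct; their spread is the
    biological noise floor of the assay, and doubling the worst case gives a
    conservative significance cut.
    """
    deltas = np.asarray(list(control_deltas), dtype=float)
    if deltas.size == 0:
        raise ValueError("at least one control delta is required")
    return float(2.0 * np.max(np.abs(deltas)))


def call_interactions(
    condition_means: dict[str, float],
    baselines: dict[str, str],
    threshold: float,
) -> dict[str, str]:
    """Per-condition interaction call from mean-lifetime reductions.

    A condition is called ``positive`` when its donor-only baseline mean
    lifetime minus its own mean lifetime is at least ``threshold`` ps (the
    boundary case counts as positive), ``negative`` otherwise, and
    ``unscored`` (with a warning) when the baseline is missing.
    """
    calls: dict[str, str] = {}
    for cond, baseline in baselines.items():
        if baseline not in condition_means or cond not in condition_means:
            warnings.warn(f"condition {cond!r}: missing baseline {baseline!r}; unscored",
                          stacklevel=2)
            calls[cond] = "unscored"
            continue
        delta = condition_means[baseline] - condition_means[cond]
        calls[cond] = "positive" if delta >= threshold else "negative"
    return calls


# ---------------------------------------------------------------------------
# full plate analysis
# ---------------------------------------------------------------------------

@dataclass
class PlateResult:
    """Everything the plate analysis computes."""

    cells: pd.DataFrame                      # one row per segmented cell
    conditions: pd.DataFrame                 # per-condition summary
    wells: pd.DataFrame                      # per-well mean lifetimes
    threshold_ps: float | None
    control_deltas: dict[str, float]
    calls: dict[str, str]
    t0: T0Estimate | None
    background_donor: np.ndarray
    background_acceptor: float
    tau_d_by_donor: dict[str, float]
    global_fits: dict[str, GlobalFitResult]
    calibration_donor: CalibrationCurve | None
    calibration_acceptor: CalibrationCurve | None
    kd_cells: pd.DataFrame | None
    kd_summary: pd.DataFrame | None
    kd_summary_by_fov: pd.DataFrame | None


_IMAGING_ROLES = ("donor_only", "negative_control", "test")


def analyze_plate(plate: SimulatedPlate, params: AnalysisParams | None = None) -> PlateResult:
    """Run the complete screening analysis on one plate.

    ``plate`` provides gate stacks, acceptor images and the layout; results
    never consult the simulation ground truth.
    """
    params = params or AnalysisParams()
    scheme = plate.config.scheme
    irf = plate.config.irf

    # 1. background from blank wells
    blank = [f for f in plate.iter_fovs(role="blank")]
    if blank:
        bg_donor = np.mean([estimate_background(f.donor.frames) for f in blank], axis=0)
        bg_acceptor = float(np.mean([np.median(f.acceptor) for f in blank]))
    else:
        warnings.warn("no blank well on the plate; assuming zero background",
                      stacklevel=2)
        bg_donor = np.zeros(scheme.n_gates)
        bg_acceptor = 0.0

    # 2. t0 from the reference dye
    t0_est: T0Estimate | None = None
    refs = [f for f in plate.iter_fovs(role="reference_dye")]
    if refs:
        tau_ref = params.reference_lifetime
        if tau_ref is None:
            tau_ref = getattr(plate.config, "reference_lifetime", None)
        if tau_ref is None:
            raise ValueError("reference wells present but no reference_lifetime given")
        f = refs[0]
        npx = f.donor.frames[0].size
        decay = f.donor.frames.reshape(scheme.n_gates, -1).sum(axis=1)
        t0_est = estimate_t0_from_reference(decay, tau_ref, scheme, irf,
                                            background=bg_donor * npx)
        if t0_est.converged and not t0_est.flagged:
            scheme = scheme.with_t0(t0_est.t0)
        else:
            warnings.warn("t0 calibration flagged; keeping the nominal time origin",
                          stacklevel=2)

    evaluator = GateBasisEvaluator(scheme, irf, tau_range=params.tau_bounds)

    # 3. segmentation + per-cell aggregation per FOV
    records: list[pd.DataFrame] = []
    decays: list[np.ndarray] = []
    decay_bgs: list[np.ndarray] = []
    for f in plate.fovs:
        if f.role not in _IMAGING_ROLES:
            continue
        has_acceptor = f.role != "donor_only"
        labels = segment_cells(
            f.donor.frames[0],
            f.acceptor if has_acceptor else None,
            donor_background=bg_donor[0],
            acceptor_background=bg_acceptor,
            k=params.k_sigma, min_area=params.min_area,
            exclude_border=params.exclude_border,
        )
        mono = fit_monoexponential_pixels(
            f.donor.frames, scheme, irf, background=bg_donor,
            mask=labels > 0, tau_bounds=params.tau_bounds, evaluator=evaluator)
        table, dec, dec_bg = aggregate_per_cell(
            f.donor.frames, f.acceptor if has_acceptor else None, labels,
            bg_donor, bg_acceptor, tau_map=mono.tau, i0_map=mono.i0,
            min_area=params.min_area)
        table.insert(0, "well", f.well)
        table.insert(1, "fov", f.fov)
        table.insert(2, "condition", f.condition)
        table.insert(3, "role", f.role)
        records.append(table)
        decays.append(dec)
        decay_bgs.append(dec_bg)

    if records:
        cells = pd.concat(records, ignore_index=True)
        all_decays = np.concatenate(decays, axis=0)
        all_decay_bgs = np.concatenate(decay_bgs, axis=0)
    else:
        cells = pd.DataFrame()
        all_decays = np.empty((0, scheme.n_gates))
        all_decay_bgs = np.empty((0, scheme.n_gates))

    # 4. tau_d per donor construct, then global fits per co-transfected condition
    donor_of = {c.condition: c.donor for c in plate.layout.values()}
    role_of = {c.condition: c.role for c in plate.layout.values()}
    tau_d_by_donor: dict[str, float] = {}
    if len(cells):
        donor_only = cells[cells["role"] == "donor_only"]
        for cond, grp in donor_only.groupby("condition"):
            tau_d_by_donor[donor_of[cond]] = float(grp["tau_mono"].mean())

    global_fits: dict[str, GlobalFitResult] = {}
    cells["beta"] = np.nan
    cells["i_d0_global"] = np.nan  # per-pixel t=0 amplitude from the global fit
    if len(cells):
        for cond in cells["condition"].unique():
            if role_of.get(cond) not in ("test", "negative_control"):
                continue
            tau_d = tau_d_by_donor.get(donor_of.get(cond))
            if tau_d is None or not np.isfinite(tau_d):
                warnings.warn(f"no donor-only tau_d for {cond!r}; skipping global fit",
                              stacklevel=2)
                continue
            sel = (cells["condition"] == cond).to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # beta=0 identifiability handled below
                gfit = fit_global_biexponential(
                    all_decays[sel], tau_d, scheme, irf,
                    background=all_decay_bgs[sel],
                    tau_bounds=(params.tau_da_min, tau_d - params.tau_da_margin),
                    evaluator=evaluator)
            global_fits[cond] = gfit
            cells.loc[sel, "beta"] = gfit.beta
            # the global fit's t=0 amplitude is the donor-concentration proxy:
            # a mono fit to a two-component decay misestimates the true t=0
            # intensity, so the biexponential amplitudes are used instead
            cells.loc[sel, "i_d0_global"] = gfit.i0 / cells.loc[sel, "n_pixels"].to_numpy()

    # 5. per-well / per-condition summaries, threshold, calls
    wells_rows = []
    if len(cells):
        for (well, cond), grp in cells.groupby(["well", "condition"]):
            wells_rows.append({"well": well, "condition": cond,
                               "mean_tau_ps": grp["tau_mono"].mean(),
                               "n_cells": len(grp)})
    wells_df = pd.DataFrame(wells_rows)

    cond_rows = []
    if len(cells):
        for cond, grp in cells.groupby("condition"):
            cond_rows.append({
                "condition": cond, "role": role_of.get(cond, ""),
                "donor": donor_of.get(cond, ""),
                "n_cells": len(grp),
                "mean_tau_ps": grp["tau_mono"].mean(),
                "median_tau_ps": grp["tau_mono"].median(),
                "mean_beta": grp["beta"].mean(),
                "tau_da_ps": global_fits[cond].tau_da if cond in global_fits else np.nan,
            })
    conditions = pd.DataFrame(cond_rows)

    cond_mean = {r["condition"]: r["mean_tau_ps"] for r in cond_rows}
    control_deltas: dict[str, float] = {}
    for cond, role in role_of.items():
        if role != "negative_control" or cond not in cond_mean:
            continue
        base = plate.layout.baseline_for(cond)
        if base in cond_mean:
            control_deltas[cond] = cond_mean[base] - cond_mean[cond]
    threshold = significance_threshold(control_deltas.values()) if control_deltas else None

    calls: dict[str, str] = {}
    if threshold is not None:
        baselines = {c: plate.layout.baseline_for(c)
                     for c, role in role_of.items()
                     if role == "test" and c in cond_mean}
        calls = call_interactions(cond_mean, baselines, threshold)

    # 6. calibrations and K_D
    cal_d = _fit_donor_calibration(plate, scheme, irf, bg_donor, params, evaluator)
    cal_a = _fit_acceptor_calibration(plate, bg_acceptor, params)
    kd_cells = kd_summary = kd_by_fov = None
    if cal_d is not None and cal_a is not None and len(cells):
        fret = cells[cells["condition"].isin(global_fits)].copy()
        fret = fret[fret["role"] == "test"]
        if len(fret):
            kd_cells = estimate_kd_table(
                fret, cal_d, cal_a, i_d0_col="i_d0_global",
                gamma_tol=params.gamma_tol,
                settings_tag=params.settings_tag or None)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                kd_summary = aggregate_kd(kd_cells, "condition",
                                          min_ok_cells=params.min_ok_cells)
                kd_by_fov = aggregate_kd(kd_cells, ["condition", "well", "fov"],
                                         min_ok_cells=1)

    return PlateResult(
        cells=cells, conditions=conditions, wells=wells_df,
        threshold_ps=threshold, control_deltas=control_deltas, calls=calls,
        t0=t0_est, background_donor=bg_donor, background_acceptor=bg_acceptor,
        tau_d_by_donor=tau_d_by_donor, global_fits=global_fits,
        calibration_donor=cal_d, calibration_acceptor=cal_a,
        kd_cells=kd_cells, kd_summary=kd_summary, kd_summary_by_fov=kd_by_fov,
    )


def _fit_donor_calibration(plate, scheme, irf, bg_donor, params, evaluator):
    """Donor curve: mean fitted t=0 intensity per pixel vs. dye concentration."""
    concs, signals = [], []
    for f in plate.iter_fovs(role="calibration_donor"):
        conc = plate.layout[f.well].dye_concentration
        mono = fit_monoexponential_pixels(
            f.donor.frames, scheme, irf, background=bg_donor,
            tau_bounds=params.tau_bounds, evaluator=evaluator)
        concs.append(conc)
        signals.append(float(np.nanmean(mono.i0)))
    if len(concs) < 3:
        return None
    return fit_intensity_calibration(np.array(concs), np.array(signals),
                                     fluorophore="donor",
                                     settings_tag=params.settings_tag)


def _fit_acceptor_calibration(plate, bg_acceptor, params):
    """Acceptor curve: background-subtracted mean image intensity vs. concentration."""
    concs, signals = [], []
    for f in plate.iter_fovs(role="calibration_acceptor"):
        concs.append(plate.layout[f.well].dye_concentration)
        signals.append(float(np.mean(f.acceptor)) - bg_acceptor)
    if len(concs) < 3:
        return None
    return fit_intensity_calibration(np.array(concs), np.array(signals),
                                     fluorophore="acceptor",
                                     settings_tag=params.settings_tag)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def render_outputs(result: PlateResult, outdir) -> dict[str, str]:
    """Write deterministic plate-level outputs; returns {name: path}.

    Produces a colour-coded per-well mean-lifetime plate map (CSV + PNG), a
    per-condition box-plot summary (median, quartiles, 1/99 percentiles,
    mean, SD), a per-cell scatter table (lifetime vs. acceptor/donor ratio)
    and the interaction-call table.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    wells = result.wells.copy()
    if len(wells):
        wells["row"] = wells["well"].str[0]
        wells["col"] = wells["well"].str[1:].astype(int)
    p = outdir / "platemap.csv"
    wells.to_csv(p, index=False)
    paths["platemap_csv"] = str(p)

    if len(wells):
        rows = sorted(wells["row"].unique())
        cols = sorted(wells["col"].unique())
        grid = np.full((len(rows), len(cols)), np.nan)
        for _, r in wells.iterrows():
            grid[rows.index(r["row"]), cols.index(r["col"])] = r["mean_tau_ps"]
        fig, ax = plt.subplots(figsize=(1.2 + 0.8 * len(cols), 1.0 + 0.8 * len(rows)))
        im = ax.imshow(grid, cmap="viridis")
        ax.set_xticks(range(len(cols)), cols)
        ax.set_yticks(range(len(rows)), rows)
        fig.colorbar(im, ax=ax, label="mean donor lifetime (ps)")
        ax.set_title("per-well mean donor lifetime")
        p = outdir / "platemap.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths["platemap_png"] = str(p)

    box_rows = []
    for cond, grp in result.cells.groupby("condition"):
        tau = grp["tau_mono"].dropna().to_numpy()
        if tau.size == 0:
            continue
        p01, q1, med, q3, p99 = np.percentile(tau, [1, 25, 50, 75, 99])
        box_rows.append({"condition": cond, "n_cells": tau.size,
                         "median_ps": med, "q1_ps": q1, "q3_ps": q3,
                         "p01_ps": p01, "p99_ps": p99,
                         "mean_ps": tau.mean(), "sd_ps": tau.std(ddof=1) if tau.size > 1 else 0.0})
    p = outdir / "boxplot_summary.csv"
    pd.DataFrame(box_rows).to_csv(p, index=False)
    paths["boxplot_csv"] = str(p)

    scatter_cols = [c for c in ("well", "fov", "cell", "condition", "role",
                                "tau_mono", "ratio", "beta") if c in result.cells.columns]
    p = outdir / "cells_scatter.csv"
    result.cells[scatter_cols].to_csv(p, index=False)
    paths["scatter_csv"] = str(p)

    call_rows = [{"condition": c, "call": v,
                  "threshold_ps": result.threshold_ps} for c, v in result.calls.items()]
    p = outdir / "calls.csv"
    pd.DataFrame(call_rows).to_csv(p, index=False)
    paths["calls_csv"] = str(p)
    return paths
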