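"""On-disk plate convention: multi-page TIFFs + YAML metadata + CSV tables.

Each FOV is stored as ``<well>_f<k>_donor.tif`` (one page per gate, page
order = gate order), ``<well>_f<k>_acceptor.tif`` and, for simulated plates,
``<well>_f<k>_labels.tif`` (uint16 ground-truth label mask).  The gate
scheme, IRF, layout and resolved simulation config live in
``plate_metadata.yaml``; the per-cell ground truth in ``ground_truth.csv``.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .binding import BindingGroundTruth
from .gating import IRF, GateScheme
from .synthetic import FovData, PlateLayout, SimulatedPlate, \
    SyntheticPlateConfig, TimeGatedStack, WellCondition

__all__ = ["write_plate", "read_plate"]


def _scheme_to_dict(s: GateScheme) -> dict:
    return {"gate_delays": list(s.gate_delays), "gate_width": s.gate_width,
            "rep_period": s.rep_period, "t0": s.t0,
            "integration_times": list(s.integration_times) if s.integration_times else None}


def _scheme_from_dict(d: dict) -> GateScheme:
    return GateScheme(gate_delays=tuple(d["gate_delays"]), gate_width=d["gate_width"],
                      rep_period=d["rep_period"], t0=d["t0"],
                      integration_times=tuple(d["integration_times"]) if d.get("integration_times") else None)


def _irf_to_dict(irf: IRF) -> dict:
    d = {"kind": irf.kind}
    if irf.kind == "gaussian":
        d.update(center=irf.center, fwhm=irf.fwhm)
    elif irf.kind == "measured":
        d.update(times=[float(t) for t in irf.times],
                 amplitudes=[float(a) for a in irf.amplitudes])
    return d


def _irf_from_dict(d: dict) -> IRF:
    if d["kind"] == "delta":
        return IRF.delta()
    if d["kind"] == "gaussian":
        return IRF.gaussian(d["center"], d["fwhm"])
    return IRF.measured(d["times"], d["amplitudes"])


def write_plate(plate: SimulatedPlate, outdir) -> Path:
    """Write a plate to ``outdir``; returns the directory path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = asdict(plate.config)
    cfg["scheme"] = _scheme_to_dict(plate.config.scheme)
    cfg["irf"] = _irf_to_dict(plate.config.irf)
    meta = {
        "scheme": _scheme_to_dict(plate.config.scheme),
        "irf": _irf_to_dict(plate.config.irf),
        "seed": plate.config.seed,
        "config": cfg,
        "layout": {well: asdict(cond) for well, cond in plate.layout.items()},
        "fovs": [{"well": f.well, "fov": f.fov, "role": f.role,
                  "condition": f.condition, "kd_true": float(f.truth.kd_true)}
                 for f in plate.fovs],
    }
    with open(outdir / "plate_metadata.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    for f in plate.fovs:
        stem = f"{f.well}_f{f.fov}"
        tifffile.imwrite(outdir / f"{stem}_donor.tif",
                         f.donor.frames.astype(np.float32))
        tifffile.imwrite(outdir / f"{stem}_acceptor.tif",
                         f.acceptor.astype(np.float32))
        tifffile.imwrite(outdir / f"{stem}_labels.tif",
                         f.labels.astype(np.uint16))
    plate.truth_table().to_csv(outdir / "ground_truth.csv", index=False)
    return outdir


def read_plate(indir) -> SimulatedPlate:
    """Read a plate previously written by :func:`write_plate`."""
    indir = Path(indir)
    with open(indir / "plate_metadata.yaml") as fh:
        meta = yaml.safe_load(fh)
    scheme = _scheme_from_dict(meta["scheme"])
    irf = _irf_from_dict(meta["irf"])
    cfg = dict(meta["config"])
    cfg["scheme"] = scheme
    cfg["irf"] = irf
    for key in ("image_shape", "radius_range", "expression_range_d",
                "expression_range_a", "background_donor"):
        cfg[key] = tuple(cfg[key])
    config = SyntheticPlateConfig(**cfg)
    layout = PlateLayout()
    for well, cond in meta["layout"].items():
        cond = dict(cond)
        for key in ("expression_range_d", "expression_range_a"):
            if cond.get(key) is not None:
                cond[key] = tuple(cond[key])
        layout[well] = WellCondition(**cond)

    import pandas as pd
    truth_df = pd.read_csv(indir / "ground_truth.csv") \
        if (indir / "ground_truth.csv").exists() else None

    fovs = []
    for rec in meta["fovs"]:
        stem = f"{rec['well']}_f{rec['fov']}"
        frames = tifffile.imread(indir / f"{stem}_donor.tif").astype(float)
        acceptor = tifffile.imread(indir / f"{stem}_acceptor.tif").astype(float)
        labels = tifffile.imread(indir / f"{stem}_labels.tif").astype(np.int32)
        if truth_df is not None:
            sub = truth_df[(truth_df["well"] == rec["well"])
                           & (truth_df["fov"] == rec["fov"])].sort_values("cell")
            truth = BindingGroundTruth(
                kd_true=rec.get("kd_true", np.inf),
                d_total=sub["d_total_nM"].to_numpy(),
                a_total=sub["a_total_nM"].to_numpy(),
                da=sub["da_nM"].to_numpy())
        else:
            truth = BindingGroundTruth(kd_true=np.inf, d_total=np.empty(0),
                                       a_total=np.empty(0), da=np.empty(0))
        fovs.append(FovData(well=rec["well"], fov=rec["fov"], role=rec["role"],
                            condition=rec["condition"],
                            donor=TimeGatedStack(frames, scheme),
                            acceptor=acceptor, labels=labels, truth=truth))
    return SimulatedPlate(config=config, layout=layout, fovs=fovs)
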