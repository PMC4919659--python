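"""Synthetic multiwell FLIM-FRET plates with known ground truth.

Emulates the screening acquisition: per well, several fields of view (FOV) of
fixed cells co-expressing a donor-tagged and an acceptor-tagged protein from
separate plasmids (hence uncorrelated expression levels), imaged with
time-gated detection (five 1-ns gates, 60 MHz excitation).  The donor decay of
each cell is a two-component mixture whose interacting amplitude fraction is
set by a bimolecular binding equilibrium at a chosen true K_D; detection adds
a time-varying background and Poisson counting noise.

Cells are uniform disks: the downstream analysis is per cell, so sub-cellular
structure is deliberately not modelled.  Neither optics (PSF, sectioning
residuals) nor photobleaching are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .binding import BindingGroundTruth, solve_binding_equilibrium
from .decay import gate_basis
from .gating import IRF, GateScheme

__all__ = [
    "SyntheticPlateConfig",
    "WellCondition",
    "PlateLayout",
    "FovData",
    "SimulatedPlate",
    "TimeGatedStack",
    "default_screen_layout",
    "generate_cell_field",
    "render_time_gated_stack",
    "simulate_plate",
]

#: well roles understood by the pipeline
ROLES = ("donor_only", "negative_control", "test", "reference_dye", "blank",
         "calibration_donor", "calibration_acceptor")

# The first gate opens before the decay start (t0 = 300 ps on the trigger
# axis) and straddles the rising edge, as on the real instrument; without
# that overlap t0 and amplitude would be exactly degenerate for a sharp IRF
# and the reference-dye t0 calibration could not work.
DEFAULT_SCHEME = GateScheme(
    gate_delays=(0.0, 1000.0, 2000.0, 3000.0, 4000.0),
    gate_width=1000.0,
    t0=300.0,
    integration_times=(1.0,) * 5,
)


@dataclass(frozen=True)
class TimeGatedStack:
    """Gate-resolved count images for one FOV: ``frames[g]`` is gate ``g``."""

    frames: np.ndarray  # (n_gates, H, W)
    scheme: GateScheme

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3 or f.shape[0] != self.scheme.n_gates:
            raise ValueError("frames must be (n_gates, H, W) matching the scheme")
        object.__setattr__(self, "frames", f)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class SyntheticPlateConfig:
    """Study conditions for a simulated plate.

    Times are ps, concentrations nM.  ``c_d`` converts donor concentration to
    instantaneous intensity at the start of the decay (counts/ps per pixel per
    nM); ``c_a`` converts acceptor concentration to gated acceptor image
    counts (counts per pixel per nM).  Expression levels are drawn
    log-uniformly and independently for donor and acceptor, reflecting
    co-transfection from separate plasmids.
    """

    image_shape: tuple[int, int] = (256, 256)
    cells_per_fov: int = 25
    radius_range: tuple[float, float] = (7.0, 12.0)
    min_separation: float = 6.0
    margin: float = 4.0
    expression_range_d: tuple[float, float] = (50.0, 5000.0)
    expression_range_a: tuple[float, float] = (50.0, 5000.0)
    kd_true: float = 500.0
    tau_d: float = 2400.0
    tau_da: float = 1300.0
    scheme: GateScheme = DEFAULT_SCHEME
    irf: IRF = field(default_factory=IRF.delta)
    c_d: float = 0.002
    c_a: float = 0.5
    background_donor: tuple[float, ...] = (2.0, 1.8, 1.6, 1.4, 1.2)
    background_acceptor: float = 5.0
    reference_lifetime: float = 4080.0  # rhodamine 6G in water
    reference_amplitude: float = 2.0    # counts/ps per pixel
    excess_variance: float = 1.0
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.tau_d > 0 and self.tau_da > 0):
            raise ValueError("lifetimes must be positive")
        if not self.tau_da < self.tau_d:
            raise ValueError("tau_da must be shorter than tau_d")
        if not (self.c_d > 0 and self.c_a > 0):
            raise ValueError("gains must be positive")
        if len(self.background_donor) != self.scheme.n_gates:
            raise ValueError("background_donor needs one value per gate")
        if self.excess_variance < 1.0:
            raise ValueError("excess_variance must be >= 1")
        for name in ("radius_range", "expression_range_d", "expression_range_a"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi")


@dataclass(frozen=True)
class WellCondition:
    """Role and (for cell-bearing wells) construct labels of one well.

    ``kd`` overrides the plate-wide true K_D for this well; ``binding=False``
    forces a non-interacting pair (the negative control).  ``dye_concentration``
    applies to calibration wells only (a uniform fluorophore solution).
    Expression-range overrides let a condition emulate, e.g., acceptor excess.
    """

    role: str
    condition: str
    donor: str | None = None
    acceptor: str | None = None
    n_fov: int = 1
    kd: float | None = None
    binding: bool = True
    expression_range_d: tuple[float, float] | None = None
    expression_range_a: tuple[float, float] | None = None
    dye_concentration: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


class PlateLayout(dict):
    """Mapping well name -> :class:`WellCondition` with pairing helpers."""

    def wells_with_role(self, role: str) -> list[str]:
        return [w for w, c in self.items() if c.role == role]

    def conditions(self) -> dict[str, list[str]]:
        """condition name -> wells, in layout order."""
        out: dict[str, list[str]] = {}
        for w, c in self.items():
            out.setdefault(c.condition, []).append(w)
        return out

    def baseline_for(self, condition: str) -> str | None:
        """Donor-only condition sharing the donor construct, if present."""
        donors = {c.condition: c.donor for c in self.values()}
        donor = donors.get(condition)
        if donor is None:
            return None
        for c in self.values():
            if c.role == "donor_only" and c.donor == donor:
                return c.condition
        return None

    def validate(self) -> None:
        for c in self.values():
            if c.role == "test" and self.baseline_for(c.condition) is None:
                raise ValueError(
                    f"test condition {c.condition!r} has no donor-only baseline on the plate"
                )


def default_screen_layout(
    donor: str = "EGFP-RASSF1",
    acceptor: str = "mCherry-SARAH",
    negative_acceptor: str = "mCherry-dSARAH",
    n_test_fov: int = 8,
    n_donor_fov: int = 4,
    n_negative_fov: int = 4,
    donor_cal_concs: Sequence[float] = (250.0, 500.0, 1000.0, 2000.0, 4000.0),
    acceptor_cal_concs: Sequence[float] = (250.0, 500.0, 1000.0, 2000.0, 4000.0),
) -> PlateLayout:
    """A minimal plate exercising every role the analysis needs.

    One blank (buffer-only) well, one reference-dye well, a donor-only well, a
    negative-control well (acceptor present, binding disabled), a test well,
    and dilution series for donor and acceptor intensity calibration.
    """
    layout = PlateLayout()
    layout["A1"] = WellCondition(role="blank", condition="blank")
    layout["A2"] = WellCondition(role="reference_dye", condition="reference")
    layout["B1"] = WellCondition(role="donor_only", condition=donor,
                                 donor=donor, n_fov=n_donor_fov)
    layout["C1"] = WellCondition(role="negative_control",
                                 condition=f"{donor}+{negative_acceptor}",
                                 donor=donor, acceptor=negative_acceptor,
                                 binding=False, n_fov=n_negative_fov)
    layout["D1"] = WellCondition(role="test", condition=f"{donor}+{acceptor}",
                                 donor=donor, acceptor=acceptor, n_fov=n_test_fov)
    for i, conc in enumerate(donor_cal_concs, start=1):
        layout[f"E{i}"] = WellCondition(role="calibration_donor",
                                        condition=f"cal_donor_{conc:g}",
                                        dye_concentration=float(conc))
    for i, conc in enumerate(acceptor_cal_concs, start=1):
        layout[f"F{i}"] = WellCondition(role="calibration_acceptor",
                                        condition=f"cal_acceptor_{conc:g}",
                                        dye_concentration=float(conc))
    layout.validate()
    return layout


# ---------------------------------------------------------------------------
# field generation
# ---------------------------------------------------------------------------

def generate_cell_field(
    config: SyntheticPlateConfig,
    rng: np.random.Generator,
    n_cells: int | None = None,
    kd: float | None = None,
    binding: bool = True,
    expression_range_d: tuple[float, float] | None = None,
    expression_range_a: tuple[float, float] | None = None,
) -> tuple[np.ndarray, BindingGroundTruth]:
    """Place non-overlapping disk cells and draw their expression levels.

    Returns a label image (0 = background, cells labelled 1..n) and the
    per-cell :class:`BindingGroundTruth`.  Cell centres are rejection-sampled
    so that disk edges stay ``min_separation`` pixels apart; if the requested
    count cannot be placed a descriptive error is raised.
    """
    n = config.cells_per_fov if n_cells is None else int(n_cells)
    H, W = config.image_shape
    labels = np.zeros((H, W), dtype=np.int32)
    if n == 0:
        truth = BindingGroundTruth(kd_true=np.inf, d_total=np.empty(0),
                                   a_total=np.empty(0), da=np.empty(0))
        return labels, truth

    r_lo, r_hi = config.radius_range
    centres: list[tuple[float, float]] = []
    radii: list[float] = []
    max_attempts = 2000 * n
    attempts = 0
    while len(centres) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} cells of radius {config.radius_range} with "
                f"separation {config.min_separation} in a {H}x{W} field after "
                f"{max_attempts} attempts; reduce cell count or size"
            )
        attempts += 1
        r = rng.uniform(r_lo, r_hi)
        pad = r + config.margin
        cy = rng.uniform(pad, H - pad)
        cx = rng.uniform(pad, W - pad)
        ok = all(
            np.hypot(cy - oy, cx - ox) >= r + orr + config.min_separation
            for (oy, ox), orr in zip(centres, radii)
        )
        if ok:
            centres.append((cy, cx))
            radii.append(r)

    yy, xx = np.mgrid[0:H, 0:W]
    for i, ((cy, cx), r) in enumerate(zip(centres, radii), start=1):
        labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = i

    rd = expression_range_d or config.expression_range_d
    ra = expression_range_a or config.expression_range_a
    d_total = np.exp(rng.uniform(np.log(rd[0]), np.log(rd[1]), size=n))
    a_total = np.exp(rng.uniform(np.log(ra[0]), np.log(ra[1]), size=n))
    kd_eff = config.kd_true if kd is None else float(kd)
    if binding:
        da = solve_binding_equilibrium(d_total, a_total, kd_eff)
    else:
        kd_eff = np.inf
        da = np.zeros(n)
    truth = BindingGroundTruth(kd_true=kd_eff, d_total=d_total,
                               a_total=a_total, da=da)
    return labels, truth


def render_time_gated_stack(
    labels: np.ndarray,
    truth: BindingGroundTruth,
    config: SyntheticPlateConfig,
    rng: np.random.Generator,
    has_acceptor: bool = True,
    noise: bool | None = None,
) -> tuple[TimeGatedStack, np.ndarray]:
    """Render the donor gate stack and the acceptor intensity image of a field.

    Per pixel of cell *i* the expected donor gate counts follow the
    two-component forward model with amplitude ``c_d * d_total[i]`` and
    amplitude fractions ``(beta_true, 1 - beta_true)`` on lifetimes
    ``(tau_da, tau_d)``, plus the per-gate background.  The acceptor image
    expectation is ``c_a * a_total[i]`` plus its background (zero acceptor
    signal in donor-only wells).  Observed counts are Poisson draws unless
    noise is disabled.
    """
    use_noise = config.noise if noise is None else noise
    scheme, irf = config.scheme, config.irf
    G = scheme.n_gates
    basis = gate_basis([config.tau_da, config.tau_d], scheme, irf)  # (G, 2)

    beta = truth.beta_true
    amp = config.c_d * truth.d_total  # (n,)
    per_cell = amp[:, None] * (beta[:, None] * basis[:, 0][None, :]
                               + (1 - beta)[:, None] * basis[:, 1][None, :])  # (n, G)
    table = np.vstack([np.zeros((1, G)), per_cell])  # row 0 = background
    donor_mean = np.moveaxis(table[labels], -1, 0)  # (G, H, W)
    donor_mean = donor_mean + np.asarray(config.background_donor, float)[:, None, None]

    if has_acceptor:
        a_table = np.concatenate([[0.0], config.c_a * truth.a_total])
        acceptor_mean = a_table[labels] + config.background_acceptor
    else:
        acceptor_mean = np.full(labels.shape, config.background_acceptor, dtype=float)

    donor = _draw(donor_mean, rng, use_noise, config.excess_variance)
    acceptor = _draw(acceptor_mean, rng, use_noise, config.excess_variance)
    return TimeGatedStack(frames=donor, scheme=scheme), acceptor


def _draw(mean: np.ndarray, rng: np.random.Generator, noise: bool,
          excess_variance: float) -> np.ndarray:
    if not noise:
        return mean.copy()
    counts = rng.poisson(mean).astype(float)
    if excess_variance > 1.0:
        # fold multiplicative intensifier gain noise into inflated variance
        counts = mean + (counts - mean) * np.sqrt(excess_variance)
    return counts


# ---------------------------------------------------------------------------
# plate assembly
# ---------------------------------------------------------------------------

@dataclass
class FovData:
    """One simulated field of view with its ground truth."""

    well: str
    fov: int
    role: str
    condition: str
    donor: TimeGatedStack
    acceptor: np.ndarray
    labels: np.ndarray
    truth: BindingGroundTruth


@dataclass
class SimulatedPlate:
    """A full simulated plate: config, layout and every rendered FOV."""

    config: SyntheticPlateConfig
    layout: PlateLayout
    fovs: list[FovData]

    def iter_fovs(self, role: str | None = None,
                  condition: str | None = None) -> Iterator[FovData]:
        for f in self.fovs:
            if role is not None and f.role != role:
                continue
            if condition is not None and f.condition != condition:
                continue
            yield f

    def truth_table(self) -> pd.DataFrame:
        """Ground truth, one row per generated cell."""
        rows = []
        for f in self.fovs:
            t = f.truth
            for i in range(t.n_cells):
                rows.append({
                    "well": f.well, "fov": f.fov, "cell": i + 1,
                    "condition": f.condition, "role": f.role,
                    "d_total_nM": t.d_total[i], "a_total_nM": t.a_total[i],
                    "da_nM": t.da[i], "beta_true": t.beta_true[i],
                    "gamma_true": t.gamma_true[i],
                })
        return pd.DataFrame(rows)


def _fov_rng(seed: int, well: str, fov: int) -> np.random.Generator:
    """Independent, reproducible stream per FOV derived from the master seed."""
    well_key = [ord(ch) for ch in well]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *well_key, int(fov)]))


def _uniform_field(config: SyntheticPlateConfig, amplitude: float, lifetime: float,
                   rng: np.random.Generator, noise: bool) -> TimeGatedStack:
    """Uniform single-exponential solution (reference dye or donor dye)."""
    basis = gate_basis([lifetime], config.scheme, config.irf)[:, 0]
    mean = (amplitude * basis)[:, None, None] + \
        np.asarray(config.background_donor, float)[:, None, None]
    mean = np.broadcast_to(mean, (config.scheme.n_gates, *config.image_shape)).copy()
    frames = _draw(mean, rng, noise, config.excess_variance)
    return TimeGatedStack(frames=frames, scheme=config.scheme)


def simulate_plate(
    config: SyntheticPlateConfig,
    layout: PlateLayout | None = None,
    seed: int | None = None,
) -> SimulatedPlate:
    """Simulate every FOV of a plate according to the layout.

    The master seed (``seed`` argument, falling back to ``config.seed``) is
    combined with the well name and FOV index to derive independent random
    streams, so regenerating any single FOV is reproducible in isolation.
    """
    if layout is None:
        layout = default_screen_layout()
    layout.validate()
    master = config.seed if seed is None else int(seed)
    config = replace(config, seed=master)
    H, W = config.image_shape
    empty = BindingGroundTruth(kd_true=np.inf, d_total=np.empty(0),
                               a_total=np.empty(0), da=np.empty(0))
    fovs: list[FovData] = []
    for well, cond in layout.items():
        for k in range(cond.n_fov):
            rng = _fov_rng(master, well, k)
            if cond.role == "blank":
                mean = np.broadcast_to(
                    np.asarray(config.background_donor, float)[:, None, None],
                    (config.scheme.n_gates, H, W)).copy()
                donor = TimeGatedStack(_draw(mean, rng, config.noise,
                                             config.excess_variance), config.scheme)
                acceptor = _draw(np.full((H, W), config.background_acceptor),
                                 rng, config.noise, config.excess_variance)
                labels, truth = np.zeros((H, W), np.int32), empty
            elif cond.role == "reference_dye":
                donor = _uniform_field(config, config.reference_amplitude,
                                       config.reference_lifetime, rng, config.noise)
                acceptor = _draw(np.full((H, W), config.background_acceptor),
                                 rng, config.noise, config.excess_variance)
                labels, truth = np.zeros((H, W), np.int32), empty
            elif cond.role == "calibration_donor":
                amp = config.c_d * cond.dye_concentration
                donor = _uniform_field(config, amp, config.tau_d, rng, config.noise)
                acceptor = _draw(np.full((H, W), config.background_acceptor),
                                 rng, config.noise, config.excess_variance)
                labels, truth = np.zeros((H, W), np.int32), empty
            elif cond.role == "calibration_acceptor":
                mean = np.broadcast_to(
                    np.asarray(config.background_donor, float)[:, None, None],
                    (config.scheme.n_gates, H, W)).copy()
                donor = TimeGatedStack(_draw(mean, rng, config.noise,
                                             config.excess_variance), config.scheme)
                acc_mean = np.full((H, W), config.background_acceptor
                                   + config.c_a * cond.dye_concentration)
                acceptor = _draw(acc_mean, rng, config.noise, config.excess_variance)
                labels, truth = np.zeros((H, W), np.int32), empty
            else:
                has_acceptor = cond.acceptor is not None
                labels, truth = generate_cell_field(
                    config, rng, kd=cond.kd,
                    binding=cond.binding and has_acceptor,
                    expression_range_d=cond.expression_range_d,
                    expression_range_a=cond.expression_range_a,
                )
                donor, acceptor = render_time_gated_stack(
                    labels, truth, config, rng, has_acceptor=has_acceptor)
            fovs.append(FovData(well=well, fov=k, role=cond.role,
                                condition=cond.condition, donor=donor,
                                acceptor=acceptor, labels=labels, truth=truth))
    return SimulatedPlate(config=config, layout=layout, fovs=fovs)
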