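"""Temporal detection model for time-gated FLIM.

A gated optical intensifier (GOI) samples the fluorescence decay by opening a
~ns electronic shutter at a set of delays after each excitation pulse.  The
:class:`GateScheme` records that timing (gate delays, gate width, laser
repetition period and the per-plate time origin ``t0``); :class:`IRF` holds
the instrument response that must be convolved with any decay model before
comparing to measured gate counts.

All times are picoseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Repetition period of a 60 MHz pulsed source, in ps.
REP_PERIOD_60MHZ = 1.0e6 / 60.0


@dataclass(frozen=True)
class GateScheme:
    """Timing of a time-gated acquisition.

    Parameters
    ----------
    gate_delays:
        Opening times of each gate relative to the laser trigger (ps),
        strictly increasing.
    gate_width:
        Width of the (rectangular) gate, ps.
    rep_period:
        Laser repetition period, ps.  Delays may exceed it; the periodic
        wrap-around of incomplete decays is part of the signal model.
    t0:
        Start of the decay profile on the trigger axis (ps), calibrated per
        plate from a reference dye.  Model evaluations shift by this offset.
    integration_times:
        Optional per-gate CCD integration times in seconds (bookkeeping only).
    """

    gate_delays: tuple[float, ...]
    gate_width: float
    rep_period: float = REP_PERIOD_60MHZ
    t0: float = 0.0
    integration_times: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        delays = tuple(float(d) for d in self.gate_delays)
        object.__setattr__(self, "gate_delays", delays)
        if len(delays) == 0:
            raise ValueError("at least one gate delay is required")
        if any(b <= a for a, b in zip(delays, delays[1:])):
            raise ValueError("gate delays must be strictly increasing")
        if not self.gate_width > 0:
            raise ValueError("gate_width must be positive")
        if not self.rep_period > 0:
            raise ValueError("rep_period must be positive")
        if self.integration_times is not None:
            its = tuple(float(t) for t in self.integration_times)
            if len(its) != len(delays):
                raise ValueError("integration_times must match gate_delays")
            if any(t <= 0 for t in its):
                raise ValueError("integration times must be positive")
            object.__setattr__(self, "integration_times", its)

    @property
    def n_gates(self) -> int:
        return len(self.gate_delays)

    @property
    def delays(self) -> np.ndarray:
        return np.asarray(self.gate_delays, dtype=float)

    def with_t0(self, t0: float) -> "GateScheme":
        """Return a copy with the plate-level time origin replaced."""
        return replace(self, t0=float(t0))


@dataclass(frozen=True)
class IRF:
    """Instrument response function: a delta, a Gaussian, or a measured trace.

    Measured IRFs are given on a uniform time grid (ps) with non-negative
    amplitudes and are normalised to unit area on construction.
    """

    kind: str = "delta"
    center: float = 0.0
    fwhm: float = 0.0
    times: np.ndarray | None = field(default=None, repr=False)
    amplitudes: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("delta", "gaussian", "measured"):
            raise ValueError(f"unknown IRF kind {self.kind!r}")
        if self.kind == "gaussian" and not self.fwhm > 0:
            raise ValueError("Gaussian IRF requires fwhm > 0")
        if self.kind == "measured":
            t = np.asarray(self.times, dtype=float)
            a = np.asarray(self.amplitudes, dtype=float)
            if t.ndim != 1 or a.shape != t.shape or t.size < 2:
                raise ValueError("measured IRF needs matching 1-D times/amplitudes")
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("measured IRF grid must be uniform")
            if np.any(a < 0):
                raise ValueError("measured IRF amplitudes must be non-negative")
            area = np.trapezoid(a, t)
            if area <= 0:
                raise ValueError("measured IRF must have positive area")
            object.__setattr__(self, "times", t)
            object.__setattr__(self, "amplitudes", a / area)

    # -- constructors ------------------------------------------------------
    @classmethod
    def delta(cls) -> "IRF":
        """Idealised instantaneous response."""
        return cls(kind="delta")

    @classmethod
    def gaussian(cls, center: float, fwhm: float) -> "IRF":
        """Parametric Gaussian response centred at ``center`` ps."""
        return cls(kind="gaussian", center=float(center), fwhm=float(fwhm))

    @classmethod
    def measured(cls, times: Sequence[float], amplitudes: Sequence[float]) -> "IRF":
        """Measured response (e.g. from a scattering sample)."""
        return cls(kind="measured", times=np.asarray(times, float),
                   amplitudes=np.asarray(amplitudes, float))

    def sample(self, t: np.ndarray, period: float) -> np.ndarray:
        """Sample the IRF on grid ``t`` (covering one period), wrapped mod period.

        Returns amplitudes normalised so that ``sum(h) * dt`` is unity.
        """
        if self.kind == "delta":
            raise ValueError("delta IRF has no finite samples; handled analytically")
        if self.kind == "gaussian":
            sigma = self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            h = np.zeros_like(t)
            for k in (-1, 0, 1):
                h += np.exp(-0.5 * ((t - self.center - k * period) / sigma) ** 2)
        else:
            # measured IRFs are assumed to lie within one period of the grid
            h = np.interp(t, self.times, self.amplitudes, left=0.0, right=0.0)
        dt = t[1] - t[0]
        area = h.sum() * dt
        if area <= 0:
            raise ValueError("IRF has no support on the sampling grid")
        return h / area
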