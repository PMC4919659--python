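"""Shared fixtures: schemes, IRFs and session-scoped simulated plates.

The expensive full-plate simulations and analyses are computed once per
session and shared between the pipeline tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import flimscreen as fs


@pytest.fixture(scope="session")
def scheme():
    """Five 1-ns gates at 60 MHz with the decay starting 300 ps into gate 0."""
    return fs.SyntheticPlateConfig().scheme


@pytest.fixture(scope="session")
def delta_irf():
    return fs.IRF.delta()


@pytest.fixture(scope="session")
def measured_irf():
    """A Gaussian-shaped measured IRF trace (10 ps grid, 250 ps FWHM).

    Centred well inside the recorded window so essentially no tail is
    truncated (+-4.7 sigma covered).
    """
    t = np.arange(0.0, 1200.0, 10.0)
    sigma = 250.0 / (2 * np.sqrt(2 * np.log(2)))
    return fs.IRF.measured(t, np.exp(-0.5 * ((t - 500.0) / sigma) ** 2))


@pytest.fixture(scope="session")
def noiseless_plate():
    cfg = fs.SyntheticPlateConfig(noise=False, seed=11)
    return fs.simulate_plate(cfg, fs.default_screen_layout())


@pytest.fixture(scope="session")
def noiseless_result(noiseless_plate):
    return fs.analyze_plate(noiseless_plate)


@pytest.fixture(scope="session")
def noisy_plate():
    cfg = fs.SyntheticPlateConfig(seed=17)
    return fs.simulate_plate(cfg, fs.default_screen_layout())


@pytest.fixture(scope="session")
def noisy_result(noisy_plate):
    return fs.analyze_plate(noisy_plate)


def calling_layout() -> fs.PlateLayout:
    """A plate with one true-positive and one true-negative test condition.

    The positive condition uses acceptor excess and a tight K_D so every
    cell's interacting fraction exceeds 0.2; the negative condition presents
    an acceptor that does not bind (beta_true = 0 everywhere).
    """
    layout = fs.PlateLayout()
    layout["A1"] = fs.WellCondition(role="blank", condition="blank")
    layout["A2"] = fs.WellCondition(role="reference_dye", condition="reference")
    layout["B1"] = fs.WellCondition(role="donor_only", condition="donorA",
                                    donor="donorA", n_fov=2)
    layout["C1"] = fs.WellCondition(role="negative_control",
                                    condition="donorA+ctrl", donor="donorA",
                                    acceptor="ctrl", binding=False, n_fov=2)
    layout["D1"] = fs.WellCondition(
        role="test", condition="donorA+binder", donor="donorA",
        acceptor="binder", kd=100.0, n_fov=3,
        expression_range_d=(200.0, 5000.0), expression_range_a=(2000.0, 5000.0))
    layout["D2"] = fs.WellCondition(
        role="test", condition="donorA+nonbinder", donor="donorA",
        acceptor="nonbinder", binding=False, n_fov=3)
    layout.validate()
    return layout


@pytest.fixture(scope="session")
def calling_result():
    cfg = fs.SyntheticPlateConfig(seed=23)
    plate = fs.simulate_plate(cfg, calling_layout())
    return plate, fs.analyze_plate(plate)
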