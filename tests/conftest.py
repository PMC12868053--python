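"""Shared fixtures.

The expensive coupled-model artefacts (calibration + baseline run) are
session-scoped and shared between the acceptance tests.
"""
from __future__ import annotations

import numpy as np
import pytest

from hemotherm import load_standard_person
from hemotherm.calibration import FlowTargets, calibrate_peripheral_resistances
from hemotherm.driver import ScenarioConfig, run_baseline
from hemotherm.parameters.types import ArteryRecord, BloodProperties


@pytest.fixture(scope="session")
def params():
    return load_standard_person()


@pytest.fixture()
def fresh_params():
    """A mutable copy for tests that modify parameters."""
    return load_standard_person()


@pytest.fixture(scope="session")
def blood():
    return BloodProperties(density=1050.0, specific_heat=3850.0,
                           kinematic_viscosity=3.3e-6, boundary_layer=9.0e-4)


def make_tube(length=1.0, r=0.005, E=4.0e5, h_rel=0.2, taper=1.0, aid=1,
              parent=None) -> ArteryRecord:
    return ArteryRecord(id=aid, name=f"tube{aid}", side="", length=length,
                        r_prox=r, r_dist=r * taper, h_rel=h_rel,
                        youngs_modulus=E, parent=parent)


@pytest.fixture(scope="session")
def calibrated():
    """Calibrated standard person, the warm coupled model, the calibration
    report, and the converged baseline result bundle."""
    p = load_standard_person()
    config = ScenarioConfig()
    targets = FlowTargets.from_parameter_set(p)
    p, report, model = calibrate_peripheral_resistances(targets, p, config)
    bundle = run_baseline(config, p, model=model)
    return {"params": p, "model": model, "report": report, "bundle": bundle,
            "config": config, "targets": targets}


def assert_close(actual, expected, rel, msg=""):
    assert np.isfinite(actual), f"{msg}: non-finite value"
    assert abs(actual - expected) <= rel * abs(expected), (
        f"{msg}: {actual} vs {expected} (rel {abs(actual - expected) / abs(expected):.4g} "
        f"> {rel})")
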