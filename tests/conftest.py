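"""Shared fixtures.

The two expensive session fixtures — a reduced-resolution 126-day baseline
healing run and a coarse sensitivity sweep — are shared by the acceptance
tests so the whole suite stays within a modest runtime on one CPU.
"""

from __future__ import annotations

import numpy as np
import pytest

from callusim.geometry import GeometrySpec
from callusim.orchestrator import (
    Simulation,
    SimulationConfig,
    sensitivity_sweep,
)

#: element size (mm) of the reduced baseline run (~400 elements)
BASELINE_H = 0.75
#: element size (mm) of the sweep runs (~240 elements)
SWEEP_H = 1.0


def coarse_config(h: float = SWEEP_H, **kwargs) -> SimulationConfig:
    return SimulationConfig(
        geometry=GeometrySpec(target_element_size=h), **kwargs
    )


@pytest.fixture(scope="session")
def baseline_sim() -> Simulation:
    """Reduced-mesh baseline healing run over the full simulated period."""
    sim = Simulation(coarse_config(BASELINE_H))
    sim.run()
    return sim


@pytest.fixture(scope="session")
def sweep_rows():
    """Directional sensitivity sweep on the coarse mesh."""
    base = coarse_config(SWEEP_H)
    grid = (
        [("transport.gamma_angio", g) for g in (2.0, 4.0, 6.0, 8.0)]
        + [("load.peak_axial_force", 800.0)]
        + [("transport.H", h) for h in (0.25, 1.0, 2.0)]
        + [("rules.tfr", t) for t in (0.5, 2.0)]
    )
    return sensitivity_sweep(base, grid)
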