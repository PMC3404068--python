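"""Angiogenesis (vessel concentration) and oxygen transport fields.

Angiogenesis is a strain-gated diffusive process: the vessel concentration
``A`` (percent, 0-100) diffuses with coefficient ``H`` through elements
whose octahedral shear strain is at or below the inhibition threshold
``gamma_angio``; above the threshold the local diffusivity is zero, so
vessel progression stops in highly strained tissue.  Nodes on the vessel
source surfaces are held at 100 %.  An element with mean nodal
concentration strictly greater than 90 % carries a functional blood supply.

Oxygen tension (mmHg) obeys diffusion-consumption: cells consume oxygen at
a constant rate ``Q`` per cell, scaled by the local normalised cell density
``n`` times the maximum cell density ``n_max``; nodes of supplied elements
are clamped at the initial oxygen tension.  Consumption is much faster than
daily dynamics (dissolved oxygen turns over in seconds), so the field
relaxes to a quasi-steady balance within each daily step; a small
fixed-point loop switches consumption off in fully depleted elements so
that the floor at 0 mmHg does not distort the profile near sources.

The oxygen solubility ``alpha`` converts dissolved-oxygen amounts to
tensions; 1 umol/(L mmHg) equals 1000 fmol/(mm^3 mmHg), so the consumption
sink in tension units is ``Q * 24 * n * n_max / (1000 * alpha)`` mmHg/day
(about 1.1e4 mmHg/day at full cell density — dissolved oxygen turns over in
minutes, giving an anoxic penetration depth of about 1.6 mm around a
source).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diffusion import ScalarDiffusion
from .geometry import Mesh

__all__ = [
    "TransportParams",
    "VesselField",
    "update_vessels",
    "supplied_elements",
    "update_oxygen",
]

SUPPLY_THRESHOLD_PCT = 90.0

SECONDS_PER_DAY = 86400.0
MM2_PER_M2 = 1e6
ATMOSPHERE_MMHG = 760.0


@dataclass
class TransportParams:
    """Angiogenesis and oxygen model parameters (input units as printed).

    ``H`` mm^2/day; ``gamma_angio`` percent strain; ``G`` m^2/s (converted
    to mm^2/day internally); ``Q`` fmol/cell/hr; ``n_max`` cells/mm^3;
    ``o2_initial`` mmHg; ``alpha`` umol/(L*mmHg) (Henry-law solubility of
    oxygen in aqueous medium at 37 C); ``o2_cartilage_pct`` percent of one
    atmosphere, converted to mmHg for the hypoxia threshold.
    """

    H: float = 0.5
    gamma_angio: float = 6.0
    G: float = 2.2e-9
    Q: float = 98.0
    n_max: float = 5e3
    o2_initial: float = 74.1
    alpha: float = 1.0268
    o2_cartilage_pct: float = 3.0
    smooth_gate: bool = False
    gate_width: float = 0.5   # percent strain, sigmoid width if smooth_gate

    def __post_init__(self) -> None:
        for name in ("H", "gamma_angio", "G", "Q", "n_max", "o2_initial",
                     "alpha", "o2_cartilage_pct", "gate_width"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")

    @property
    def G_mm2_per_day(self) -> float:
        return self.G * MM2_PER_M2 * SECONDS_PER_DAY

    @property
    def o2_cartilage_mmhg(self) -> float:
        return self.o2_cartilage_pct / 100.0 * ATMOSPHERE_MMHG

    def consumption_mmhg_per_day(self, n_elem: np.ndarray) -> np.ndarray:
        """Oxygen sink in mmHg/day for normalised cell density ``n_elem``.

        ``Q`` fmol/cell/hr times 24 and ``n * n_max`` cells/mm^3 gives
        fmol/mm^3/day; dividing by the solubility in fmol/(mm^3 mmHg)
        (``1000 * alpha`` for ``alpha`` in umol/(L mmHg)) yields mmHg/day.
        """
        return (
            (self.Q * 24.0) * np.asarray(n_elem) * self.n_max
            / (1000.0 * self.alpha)
        )


@dataclass
class VesselField:
    """Nodal vessel concentration (percent) plus the clamped source nodes."""

    A: np.ndarray
    source_nodes: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.source_nodes = np.asarray(self.source_nodes, dtype=np.int64)
        if np.any(self.A < -1e-9) or np.any(self.A > 100.0 + 1e-9):
            raise ValueError("vessel concentration outside [0, 100]")
        self.A[self.source_nodes] = 100.0


def _gated_diffusivity(params: TransportParams, gamma_pct: np.ndarray) -> np.ndarray:
    gamma_pct = np.asarray(gamma_pct, dtype=float)
    if params.smooth_gate:
        return params.H / (
            1.0 + np.exp((gamma_pct - params.gamma_angio) / params.gate_width)
        )
    return np.where(gamma_pct <= params.gamma_angio, params.H, 0.0)


def update_vessels(
    field: VesselField,
    gamma_pct: np.ndarray,
    params: TransportParams,
    dt: float,
    diffusion: ScalarDiffusion,
    n_substeps: int = 10,
) -> VesselField:
    """One daily strain-gated diffusion update of the vessel field."""
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    if gamma_pct is None:
        raise ValueError("strain field required for the angiogenic gate")
    D = _gated_diffusivity(params, gamma_pct)
    A = diffusion.step(
        field.A,
        D,
        dt,
        dirichlet_nodes=field.source_nodes,
        dirichlet_value=100.0,
        n_substeps=n_substeps,
    )
    np.clip(A, 0.0, 100.0, out=A)
    return VesselField(A=A, source_nodes=field.source_nodes)


def supplied_elements(field: VesselField, mesh: Mesh) -> np.ndarray:
    """Blood-supply mask: element mean concentration strictly above 90 %."""
    means = field.A[mesh.elems].mean(axis=1)
    return means > SUPPLY_THRESHOLD_PCT


def update_oxygen(
    o2: np.ndarray,
    supplied: np.ndarray,
    n_elem: np.ndarray,
    params: TransportParams,
    dt: float,
    diffusion: ScalarDiffusion,
    n_substeps: int = 3,
    max_obstacle_iter: int = 30,
) -> np.ndarray:
    """Implicit diffusion-consumption update of nodal oxygen tension.

    Nodes of supplied elements are Dirichlet-clamped at the initial tension.
    Because the constant-rate sink is orders of magnitude faster than the
    daily time scale, depleted regions would be driven far below zero; the
    floor O2 >= 0 is enforced as a discrete obstacle problem by an
    active-set iteration: nodes whose solution goes negative are clamped to
    zero and the step is re-solved, so the profile between a source and the
    anoxic front keeps the correct diffusion-consumption balance.
    """
    n_elem = np.asarray(n_elem, dtype=float)
    if np.any(n_elem < -1e-12) or np.any(n_elem > 1.0 + 1e-9):
        raise ValueError("cell density outside [0, 1]")
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    mesh = diffusion.mesh
    supplied = np.asarray(supplied, dtype=bool)
    src_nodes = (
        np.unique(mesh.elems[supplied].ravel()) if supplied.any() else
        np.empty(0, dtype=np.int64)
    )
    sink = params.consumption_mmhg_per_day(n_elem)
    sink_vec = -diffusion.element_source_vector(sink)
    D = np.full(mesh.n_elems, params.G_mm2_per_day)
    phi = np.asarray(o2, dtype=float).copy()
    dts = dt / n_substeps
    values = np.zeros(mesh.n_nodes)
    values[src_nodes] = params.o2_initial
    for _ in range(n_substeps):
        clamped = np.zeros(mesh.n_nodes, dtype=bool)
        for _ in range(max_obstacle_iter):
            dirichlet = np.union1d(src_nodes, np.nonzero(clamped)[0])
            nxt = diffusion.step(
                phi,
                D,
                dts,
                dirichlet_nodes=dirichlet,
                dirichlet_value=0.0,
                nodal_source=sink_vec,
                n_substeps=1,
                dirichlet_values=values,
            )
            negative = nxt < -1e-10
            negative[src_nodes] = False
            if not negative.any():
                break
            clamped |= negative
        phi = np.maximum(nxt, 0.0)
    return phi
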