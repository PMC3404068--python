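"""Mesenchymal stem cell colonisation of the callus.

Normalised cell density ``n`` (0 to 1) spreads from origin surfaces — the
marrow-body surface, the periosteal cortex surface and the external callus
boundary, the same surfaces that seed blood vessels — by diffusion with
logistic proliferation (Fisher-KPP dynamics):

    dn/dt = D_cell lap(n) + p_rate n (1 - n),  n = 1 on origin surfaces.

The travelling colonisation front moves at asymptotic speed
``2 sqrt(D_cell p_rate)`` (about 0.9 mm/day at the defaults), which sets
how quickly consumption-driven hypoxia can develop ahead of the vascular
front.  Diffusion is stepped implicitly, the logistic source explicitly per
substep, and the result is clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diffusion import ScalarDiffusion

__all__ = ["CellParams", "CellField", "update_cells"]


@dataclass
class CellParams:
    """Cell migration/proliferation coefficients (mm^2/day, 1/day)."""

    D_cell: float = 0.34
    p_rate: float = 0.6

    def __post_init__(self) -> None:
        if self.D_cell <= 0.0:
            raise ValueError("D_cell must be positive")
        if self.p_rate < 0.0:
            raise ValueError("p_rate must be non-negative")


@dataclass
class CellField:
    """Nodal normalised MSC density with saturated origin nodes."""

    n: np.ndarray
    origin_nodes: np.ndarray

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        self.origin_nodes = np.asarray(self.origin_nodes, dtype=np.int64)
        if np.any(self.n < -1e-9) or np.any(self.n > 1.0 + 1e-9):
            raise ValueError("cell density outside [0, 1]")
        if self.origin_nodes.size:
            self.n[self.origin_nodes] = 1.0


def update_cells(
    field: CellField,
    params: CellParams,
    dt: float,
    diffusion: ScalarDiffusion,
    n_substeps: int = 10,
) -> CellField:
    """One daily Fisher-KPP update (implicit diffusion, explicit logistic)."""
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    mesh = diffusion.mesh
    D = np.full(mesh.n_elems, params.D_cell)
    n = field.n.copy()
    dts = dt / n_substeps
    origins = field.origin_nodes if field.origin_nodes.size else None
    for _ in range(n_substeps):
        logistic = params.p_rate * n * (1.0 - n)
        n = diffusion.step(
            n,
            D,
            dts,
            dirichlet_nodes=origins,
            dirichlet_value=1.0,
            nodal_source=diffusion.lumped_mass * logistic,
            n_substeps=1,
        )
        np.clip(n, 0.0, 1.0, out=n)
    return CellField(n=n, origin_nodes=field.origin_nodes)
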