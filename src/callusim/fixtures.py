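"""Deterministic small meshes and states for tests and benchmarks.

Four fixture kinds:

* ``strip_1d`` — a pseudo-one-dimensional strip of elements stacked along z
  at a large radius, so the axisymmetric face-area/volume ratio is exactly
  that of a 1D column.  Used by the diffusion-front and tissue-front
  oracles.
* ``slab_2d`` — a small rectangular patch for 2D kernel checks.
* ``terzaghi_column`` — a laterally confined soft biphasic column, drained
  at the top and loaded axially: the classic consolidation benchmark.
* ``toy_callus`` — a coarse version of the full callus geometry for
  end-to-end smoke runs that finish in well under a minute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .differentiation import TissueState
from .geometry import GeometrySpec, Mesh, build_callus_mesh, build_rect_mesh
from .materials import MaterialTable, Phenotype

__all__ = ["FixtureSpec", "Fixture", "make_fixture"]

_KINDS = ("strip_1d", "slab_2d", "terzaghi_column", "toy_callus")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a test fixture.

    ``size`` is the element count along the strip/column (or the target
    element size in mm for ``toy_callus``); ``length`` the physical extent
    in mm; ``material`` a phenotype name used as the uniform preset;
    ``source`` places the transport/cell source (``z_min`` or ``z_max``).
    """

    kind: str = "strip_1d"
    size: int = 20
    length: float = 10.0
    material: str = "granulation"
    source: str = "z_min"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unrecognized fixture kind '{self.kind}'")
        if self.size <= 0 or self.length <= 0.0:
            raise ValueError("fixture sizes must be positive")
        if self.source not in ("z_min", "z_max"):
            raise ValueError("source must be z_min or z_max")


@dataclass
class Fixture:
    mesh: Mesh
    state: TissueState
    source_nodes: np.ndarray
    materials: MaterialTable
    phenotype: Phenotype


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Build the mesh + initial state for a :class:`FixtureSpec`."""
    mat = MaterialTable()
    phen = Phenotype[spec.material.upper()]
    if spec.kind == "strip_1d":
        h = spec.length / spec.size
        mesh = build_rect_mesh(1000.0, 1000.0 + h, 0.0, spec.length, 1, spec.size)
    elif spec.kind == "slab_2d":
        h = spec.length / spec.size
        mesh = build_rect_mesh(
            1000.0, 1000.0 + spec.length, 0.0, spec.length, spec.size, spec.size
        )
    elif spec.kind == "terzaghi_column":
        h = spec.length / spec.size
        mesh = build_rect_mesh(10.0, 10.0 + h, 0.0, spec.length, 1, spec.size)
    else:  # toy_callus
        geo = GeometrySpec(target_element_size=max(1.0, spec.length / spec.size))
        mesh = build_callus_mesh(geo)
    state = TissueState.initial(mesh)
    if spec.kind != "toy_callus":
        state.phenotype[:] = int(phen)
    src = mesh.node_sets.get(spec.source)
    if src is None:
        src = mesh.node_sets["symmetry"]
    return Fixture(
        mesh=mesh,
        state=state,
        source_nodes=np.asarray(src, dtype=np.int64),
        materials=mat,
        phenotype=phen,
    )
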