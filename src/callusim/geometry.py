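"""Axisymmetric fracture-callus geometry and structured quadrilateral meshing.

The model domain is the half-model of a fractured cylindrical diaphysis with
an external callus, in (r, z) coordinates: r is radial distance from the bone
axis, z runs along the bone axis with z = 0 at the fracture mid-plane.  All
lengths are in millimetres.  Three regions are labelled: ``cortical_bone``
(the intact cortex beyond the fracture gap), ``marrow`` (the undamaged marrow
body of the medullary cavity), and ``callus`` (everything initially filled
with granulation tissue: the fracture gap, the endosteal callus inside the
cavity, and the external/periosteal callus ring).

The external callus boundary is an elliptical-arc profile running from the
maximum callus radius at the fracture plane back towards the cortex surface,
with a small blunt face at its axial end so that every element keeps a
strictly positive width.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict

import numpy as np

__all__ = [
    "GeometrySpec",
    "Mesh",
    "build_callus_mesh",
    "build_rect_mesh",
    "boundary_sets",
    "REGION_CALLUS",
    "REGION_CORTICAL",
    "REGION_MARROW",
    "REGION_NAMES",
]

REGION_CALLUS = 0
REGION_CORTICAL = 1
REGION_MARROW = 2
REGION_NAMES = {
    REGION_CALLUS: "callus",
    REGION_CORTICAL: "cortical_bone",
    REGION_MARROW: "marrow",
}

_TOL = 1e-9


@dataclass(frozen=True)
class GeometrySpec:
    """Dimensions of the idealised fractured diaphysis + callus (mm).

    Defaults correspond to an ovine tibia-scale geometry: cortex internal
    diameter 14 mm, external diameter 20 mm, external callus diameter 28 mm
    and a 3 mm fracture gap.  ``modelled_cortex_length`` is the length of
    cortical shaft represented beyond the gap; ``callus_axial_extent`` and
    ``endosteal_extent`` set how far the external callus and the endosteal
    (intramedullary) callus reach along the axis, measured from the fracture
    mid-plane.  ``callus_tip_fraction`` is the blunt-end width of the external
    callus as a fraction of its maximum width.
    """

    cortex_inner_diameter: float = 14.0
    cortex_outer_diameter: float = 20.0
    callus_outer_diameter: float = 28.0
    gap_length: float = 3.0
    modelled_cortex_length: float = 15.0
    callus_axial_extent: float = 14.0
    endosteal_extent: float = 5.0
    callus_tip_fraction: float = 0.15
    target_element_size: float = 0.25

    def __post_init__(self) -> None:
        d_in, d_out, d_cal = (
            self.cortex_inner_diameter,
            self.cortex_outer_diameter,
            self.callus_outer_diameter,
        )
        if not (0.0 < d_in < d_out < d_cal):
            raise ValueError(
                "diameter ordering violated: need 0 < inner < outer < callus, "
                f"got {d_in}/{d_out}/{d_cal}"
            )
        for name in (
            "gap_length",
            "modelled_cortex_length",
            "callus_axial_extent",
            "endosteal_extent",
            "target_element_size",
        ):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.callus_tip_fraction < 1.0):
            raise ValueError("callus_tip_fraction must lie in (0, 1)")
        if self.target_element_size > self.half_gap:
            raise ValueError(
                "target_element_size larger than the gap half-length "
                f"({self.target_element_size} > {self.half_gap})"
            )
        if not (self.half_gap < self.endosteal_extent < self.callus_axial_extent):
            raise ValueError(
                "need half gap < endosteal_extent < callus_axial_extent"
            )
        if self.callus_axial_extent >= self.z_top:
            raise ValueError("callus_axial_extent must end before the shaft top")

    # --- derived dimensions -------------------------------------------------
    @property
    def r_inner(self) -> float:
        return 0.5 * self.cortex_inner_diameter

    @property
    def r_outer(self) -> float:
        return 0.5 * self.cortex_outer_diameter

    @property
    def r_callus(self) -> float:
        return 0.5 * self.callus_outer_diameter

    @property
    def half_gap(self) -> float:
        return 0.5 * self.gap_length

    @property
    def z_top(self) -> float:
        return self.half_gap + self.modelled_cortex_length

    def callus_profile(self, z):
        """Outer callus radius R(z) (vectorised).

        Elliptical arc from ``r_callus`` at z = 0 down to a blunt face of
        relative width ``callus_tip_fraction`` at ``z = callus_axial_extent``;
        beyond that the profile collapses onto the cortex surface.
        """
        z = np.asarray(z, dtype=float)
        s = np.clip(z / self.callus_axial_extent, 0.0, 1.0)
        w = np.sqrt(np.clip(1.0 - s * s, 0.0, None))
        w = np.maximum(w, self.callus_tip_fraction)
        w = np.where(z <= self.callus_axial_extent + _TOL, w, 0.0)
        return self.r_outer + (self.r_callus - self.r_outer) * w

    # --- analytic (r,z)-plane region areas, used as meshing oracles ---------
    def analytic_region_areas(self) -> Dict[str, float]:
        """Closed-form areas (mm^2, in the r-z plane) of the three regions."""
        delta = self.callus_tip_fraction
        s0 = np.sqrt(1.0 - delta * delta)
        # integral of max(delta, sqrt(1 - s^2)) over s in [0, 1]
        arc = 0.5 * (s0 * delta + np.arcsin(s0)) + delta * (1.0 - s0)
        ring = (self.r_callus - self.r_outer) * self.callus_axial_extent * arc
        gap = (self.r_outer - self.r_inner) * self.half_gap
        endosteal = self.r_inner * self.endosteal_extent
        marrow = self.r_inner * (self.z_top - self.endosteal_extent)
        cortex = (self.r_outer - self.r_inner) * (self.z_top - self.half_gap)
        return {
            "callus": ring + gap + endosteal,
            "cortical_bone": cortex,
            "marrow": marrow,
        }


@dataclass
class Mesh:
    """Conforming quadrilateral mesh with region labels and named node sets.

    ``elems`` lists corner nodes counter-clockwise in the (r, z) plane.
    Derived quantities (plane areas, axisymmetric volumes ``2*pi*int r dA``,
    face areas ``2*pi*r_bar*L``, and the face-neighbour table) are computed
    once at construction.
    """

    nodes: np.ndarray          # (N, 2) float, columns (r, z)
    elems: np.ndarray          # (E, 4) int
    region: np.ndarray         # (E,) int region codes
    node_sets: Dict[str, np.ndarray]
    spec: GeometrySpec | None = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elems = np.asarray(self.elems, dtype=np.int64)
        self.region = np.asarray(self.region, dtype=np.int64)
        if np.any(self.nodes[:, 0] < -_TOL):
            raise ValueError("mesh has nodes with negative radius")
        if self.region.shape[0] != self.elems.shape[0]:
            raise ValueError("one region label per element required")
        self._compute_derived()

    # number helpers
    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    def _compute_derived(self) -> None:
        r = self.nodes[self.elems, 0]   # (E,4)
        z = self.nodes[self.elems, 1]
        # plane area via the shoelace formula (positive for CCW quads)
        area2 = (
            r[:, 0] * z[:, 1] - r[:, 1] * z[:, 0]
            + r[:, 1] * z[:, 2] - r[:, 2] * z[:, 1]
            + r[:, 2] * z[:, 3] - r[:, 3] * z[:, 2]
            + r[:, 3] * z[:, 0] - r[:, 0] * z[:, 3]
        )
        self.area = 0.5 * area2
        if np.any(self.area <= 0.0):
            raise ValueError("mesh contains inverted or degenerate elements")
        # corner-triangle signed areas catch non-convex (inverted-corner) quads
        for a, b, c in ((3, 0, 1), (0, 1, 2), (1, 2, 3), (2, 3, 0)):
            tri = (r[:, b] - r[:, a]) * (z[:, c] - z[:, a]) - (
                r[:, c] - r[:, a]
            ) * (z[:, b] - z[:, a])
            if np.any(tri <= 0.0):
                raise ValueError("mesh contains a non-convex element corner")
        self.centroid = np.stack([r.mean(axis=1), z.mean(axis=1)], axis=1)
        # axisymmetric element volume: 2*pi * int r dA, exact via 2x2 Gauss
        g = 1.0 / np.sqrt(3.0)
        vol = np.zeros(self.n_elems)
        for xi in (-g, g):
            for eta in (-g, g):
                N = 0.25 * np.array(
                    [
                        (1 - xi) * (1 - eta),
                        (1 + xi) * (1 - eta),
                        (1 + xi) * (1 + eta),
                        (1 - xi) * (1 + eta),
                    ]
                )
                dNdxi = 0.25 * np.array(
                    [-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)]
                )
                dNdeta = 0.25 * np.array(
                    [-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)]
                )
                J11 = r @ dNdxi
                J12 = z @ dNdxi
                J21 = r @ dNdeta
                J22 = z @ dNdeta
                detJ = J11 * J22 - J12 * J21
                vol += (r @ N) * detJ
        self.volume = 2.0 * np.pi * vol
        self._build_adjacency()

    def _build_adjacency(self) -> None:
        faces = ((0, 1), (1, 2), (2, 3), (3, 0))
        edge_map: Dict[tuple, list] = {}
        for e in range(self.n_elems):
            for f, (a, b) in enumerate(faces):
                key = tuple(sorted((int(self.elems[e, a]), int(self.elems[e, b]))))
                edge_map.setdefault(key, []).append((e, f))
        neighbors = np.full((self.n_elems, 4), -1, dtype=np.int64)
        for key, owners in edge_map.items():
            if len(owners) > 2:
                raise ValueError("non-manifold edge (shared by >2 elements)")
            if len(owners) == 2:
                (e1, f1), (e2, f2) = owners
                neighbors[e1, f1] = e2
                neighbors[e2, f2] = e1
        self.neighbors = neighbors
        # axisymmetric face areas 2*pi*r_bar*L for every local face
        fa = np.zeros((self.n_elems, 4))
        for f, (a, b) in enumerate(faces):
            pa = self.nodes[self.elems[:, a]]
            pb = self.nodes[self.elems[:, b]]
            L = np.linalg.norm(pb - pa, axis=1)
            rbar = 0.5 * (pa[:, 0] + pb[:, 0])
            fa[:, f] = 2.0 * np.pi * rbar * L
        self.face_area = fa
        self._edge_map = edge_map

    def interior_edge_counts(self) -> Dict[int, int]:
        """Histogram of how many elements share each edge (watertightness)."""
        counts: Dict[int, int] = {}
        for owners in self._edge_map.values():
            counts[len(owners)] = counts.get(len(owners), 0) + 1
        return counts

    def region_areas(self) -> Dict[str, float]:
        out: Dict[str, float] = {}
        for code, name in REGION_NAMES.items():
            out[name] = float(self.area[self.region == code].sum())
        return out

    def permuted(self, perm: np.ndarray) -> "Mesh":
        """Return a copy with nodes renumbered by ``perm`` (old -> new)."""
        perm = np.asarray(perm)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(perm.size)
        nodes = self.nodes[inv]
        elems = perm[self.elems]
        sets = {k: np.sort(perm[v]) for k, v in self.node_sets.items()}
        return Mesh(nodes, elems, self.region.copy(), sets, spec=self.spec)


def _segment_lines(z0: float, z1: float, h: float) -> np.ndarray:
    n = max(1, int(round((z1 - z0) / h)))
    return np.linspace(z0, z1, n + 1)


def build_rect_mesh(
    r0: float,
    r1: float,
    z0: float,
    z1: float,
    nr: int,
    nz: int,
    region: int = REGION_CALLUS,
) -> Mesh:
    """Structured mesh of a rectangle in the (r, z) plane with one region.

    Used by the test fixtures (strips, slabs, consolidation columns).  Node
    sets mark the four sides: ``r_min``, ``r_max``, ``z_min``, ``z_max``.
    """
    if r0 < 0 or r1 <= r0 or z1 <= z0 or nr < 1 or nz < 1:
        raise ValueError("invalid rectangle specification")
    rl = np.linspace(r0, r1, nr + 1)
    zl = np.linspace(z0, z1, nz + 1)
    R, Z = np.meshgrid(rl, zl, indexing="ij")
    nodes = np.stack([R.ravel(), Z.ravel()], axis=1)

    def nid(i, j):
        return i * (nz + 1) + j

    elems = []
    for i in range(nr):
        for j in range(nz):
            elems.append([nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)])
    elems = np.array(elems, dtype=np.int64)
    tol = 1e-9 * max(r1 - r0, z1 - z0, 1.0)
    sets = {
        "r_min": np.nonzero(np.abs(nodes[:, 0] - r0) < tol)[0],
        "r_max": np.nonzero(np.abs(nodes[:, 0] - r1) < tol)[0],
        "z_min": np.nonzero(np.abs(nodes[:, 1] - z0) < tol)[0],
        "z_max": np.nonzero(np.abs(nodes[:, 1] - z1) < tol)[0],
    }
    return Mesh(nodes, elems, np.full(len(elems), region), sets)


def build_callus_mesh(spec: GeometrySpec) -> Mesh:
    """Build the half-model callus mesh for a :class:`GeometrySpec`.

    The grid is structured: fixed radial lines through the marrow and cortex
    bands, and a radially scaled band of lines between the cortex surface and
    the external callus profile.  The outer band only exists for axial
    positions within the callus extent, so the mesh conforms to the profile
    without degenerate elements.
    """
    h = spec.target_element_size
    # radial lines of the two fixed bands
    n_marrow = max(2, int(round(spec.r_inner / h)))
    n_cortex = max(2, int(round((spec.r_outer - spec.r_inner) / h)))
    n_ring = max(2, int(round((spec.r_callus - spec.r_outer) / h)))
    r_marrow = np.linspace(0.0, spec.r_inner, n_marrow + 1)
    r_cortex = np.linspace(spec.r_inner, spec.r_outer, n_cortex + 1)[1:]
    ring_frac = np.linspace(0.0, 1.0, n_ring + 1)[1:]

    # grid line at the slope break where the elliptical arc meets the blunt
    # tip, so the profile is smooth within every element column
    z_knee = spec.callus_axial_extent * float(
        np.sqrt(1.0 - spec.callus_tip_fraction**2)
    )
    z_breaks = sorted(
        {spec.half_gap, spec.endosteal_extent, z_knee, spec.callus_axial_extent}
    )
    segs = [_segment_lines(0.0, z_breaks[0], h)]
    for a, b in zip(z_breaks, z_breaks[1:] + [spec.z_top]):
        segs.append(_segment_lines(a, b, h)[1:])
    z_lines = np.concatenate(segs)
    nz = z_lines.size - 1
    j_cal = int(np.argmin(np.abs(z_lines - spec.callus_axial_extent)))

    n_inner = r_marrow.size + r_cortex.size   # radial node count of fixed bands
    node_ids = []  # per z-line arrays of node ids (length varies)
    nodes = []
    for j, zj in enumerate(z_lines):
        ids = []
        rads = list(r_marrow) + list(r_cortex)
        if j <= j_cal:
            Rj = float(spec.callus_profile(zj))
            rads += list(spec.r_outer + ring_frac * (Rj - spec.r_outer))
        for r in rads:
            ids.append(len(nodes))
            nodes.append((r, zj))
        node_ids.append(np.array(ids, dtype=np.int64))
    nodes = np.array(nodes, dtype=float)

    elems = []
    region = []
    for j in range(nz):
        zc = 0.5 * (z_lines[j] + z_lines[j + 1])
        has_ring = j + 1 <= j_cal
        n_rows = n_inner - 1 + (n_ring if has_ring else 0)
        for i in range(n_rows):
            n00 = node_ids[j][i]
            n10 = node_ids[j][i + 1]
            n01 = node_ids[j + 1][i]
            n11 = node_ids[j + 1][i + 1]
            elems.append([n00, n10, n11, n01])
            if i < n_marrow:  # marrow band
                region.append(
                    REGION_CALLUS if zc < spec.endosteal_extent else REGION_MARROW
                )
            elif i < n_marrow + n_cortex:  # cortex band
                region.append(
                    REGION_CALLUS if zc < spec.half_gap else REGION_CORTICAL
                )
            else:
                region.append(REGION_CALLUS)
    elems = np.array(elems, dtype=np.int64)
    region = np.array(region, dtype=np.int64)

    tol = 1e-6 * spec.r_callus
    r = nodes[:, 0]
    z = nodes[:, 1]
    Rz = spec.callus_profile(np.clip(z, 0.0, spec.callus_axial_extent))
    on_profile = (np.abs(r - Rz) < tol) & (r > spec.r_outer + tol) & (
        z <= spec.callus_axial_extent + tol
    )
    sets = {
        "axis": np.nonzero(r < tol)[0],
        "symmetry": np.nonzero(z < tol)[0],
        "load_face": np.nonzero(
            (np.abs(z - spec.z_top) < tol)
            & (r > spec.r_inner - tol)
            & (r < spec.r_outer + tol)
        )[0],
        "medullary_source": np.nonzero(
            (np.abs(z - spec.endosteal_extent) < tol) & (r < spec.r_inner + tol)
        )[0],
        "periosteal_source": np.nonzero(
            (np.abs(r - spec.r_outer) < tol)
            & (z > spec.half_gap - tol)
            & (z < spec.callus_axial_extent + tol)
        )[0],
        "external_boundary": np.nonzero(on_profile)[0],
    }
    mesh = Mesh(nodes, elems, region, sets, spec=spec)
    return mesh


def boundary_sets(mesh: Mesh) -> Dict[str, np.ndarray]:
    """Return the named boundary node sets, checking none is empty."""
    for name, ids in mesh.node_sets.items():
        if ids.size == 0:
            raise ValueError(f"boundary set '{name}' is empty")
    return dict(mesh.node_sets)


def refine(spec: GeometrySpec, factor: float = 2.0) -> GeometrySpec:
    """Spec with the target element size divided by ``factor``."""
    return replace(spec, target_element_size=spec.target_element_size / factor)
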