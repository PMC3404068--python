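"""Axisymmetric biphasic (poroelastic) finite elements.

Solves the u-p consolidation problem for a single quasi-static ramp-load
event: linear-elastic solid skeleton plus incompressible pore fluid with a
small storage term from fluid compressibility (porosity / K_fluid).  The
displacement field uses biquadratic (9-node) Lagrange elements and the pore
pressure bilinear (4-node) elements on the same quads (Taylor-Hood pairing,
inf-sup stable).  Unit system: mm, N, s, MPa; permeability mm^2; viscosity
N s/mm^2; Darcy mobility kappa = permeability / viscosity.

Discretisation per backward-Euler time step::

    [ K   -C ] [u]   [ f(t) ]
    [ C^T  Sm + dt*Kp ] [p] = [ C^T u_prev + Sm p_prev ]

with K the elastic stiffness, C the pressure-displacement coupling
(volumetric operator), Kp the Darcy flow matrix and Sm the storage matrix.
Mechanical stimuli (octahedral shear strain, relative fluid velocity from
Darcy's law) are extracted at element centroids at the end of the ramp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import Mesh

__all__ = [
    "LoadCase",
    "FieldSolution",
    "BiphasicFEM",
    "octahedral_shear_strain",
    "WATER_BULK_MODULUS_MPA",
]

WATER_BULK_MODULUS_MPA = 2300.0

# local Q9 nodes: corners, edge midpoints (edge i between corners i, i+1), centre
_Q9_LOCAL = [
    (-1, -1), (1, -1), (1, 1), (-1, 1),
    (0, -1), (1, 0), (0, 1), (-1, 0),
    (0, 0),
]


def _lag1d(a: int, x: np.ndarray) -> np.ndarray:
    if a == -1:
        return 0.5 * x * (x - 1.0)
    if a == 0:
        return 1.0 - x * x
    return 0.5 * x * (x + 1.0)


def _dlag1d(a: int, x: np.ndarray) -> np.ndarray:
    if a == -1:
        return x - 0.5
    if a == 0:
        return -2.0 * x
    return x + 0.5


def _shape_q9(xi: float, eta: float):
    N = np.array([_lag1d(a, xi) * _lag1d(b, eta) for a, b in _Q9_LOCAL])
    dN = np.array(
        [
            [_dlag1d(a, xi) * _lag1d(b, eta), _lag1d(a, xi) * _dlag1d(b, eta)]
            for a, b in _Q9_LOCAL
        ]
    )
    return N, dN  # (9,), (9, 2)


def _shape_q4(xi: float, eta: float):
    N = 0.25 * np.array(
        [
            (1 - xi) * (1 - eta),
            (1 + xi) * (1 - eta),
            (1 + xi) * (1 + eta),
            (1 - xi) * (1 + eta),
        ]
    )
    dN = 0.25 * np.array(
        [
            [-(1 - eta), -(1 - xi)],
            [(1 - eta), -(1 + xi)],
            [(1 + eta), (1 + xi)],
            [-(1 + eta), (1 - xi)],
        ]
    )
    return N, dN


def octahedral_shear_strain(strain: np.ndarray) -> np.ndarray:
    """Octahedral shear strain of axisymmetric strain tensors.

    ``strain[..., :]`` holds (eps_rr, eps_zz, eps_tt, gamma_rz) with the
    engineering shear component.  Returns
    ``(2/3) * sqrt((e1-e2)^2 + (e2-e3)^2 + (e3-e1)^2)`` over the principal
    strains; zero for any purely volumetric state.
    """
    strain = np.asarray(strain, dtype=float)
    err, ezz, ett, grz = (strain[..., i] for i in range(4))
    mean = 0.5 * (err + ezz)
    rad = np.sqrt((0.5 * (err - ezz)) ** 2 + (0.5 * grz) ** 2)
    e1 = mean + rad
    e2 = mean - rad
    e3 = ett
    return (2.0 / 3.0) * np.sqrt(
        (e1 - e2) ** 2 + (e2 - e3) ** 2 + (e3 - e1) ** 2
    )


@dataclass(frozen=True)
class LoadCase:
    """Daily loading event: an axial ramp to ``peak_axial_force`` Newtons."""

    peak_axial_force: float = 300.0
    ramp_duration: float = 0.5   # s
    time_step: float = 0.05      # s

    def __post_init__(self) -> None:
        if self.peak_axial_force < 0.0:
            raise ValueError("peak_axial_force must be >= 0")
        if self.ramp_duration <= 0.0:
            raise ValueError("ramp_duration must be positive")
        if not (0.0 < self.time_step <= self.ramp_duration):
            raise ValueError("time_step must lie in (0, ramp_duration]")


@dataclass
class FieldSolution:
    """Element-centroid stimuli and nodal fields from one load event."""

    gamma_pct: np.ndarray          # octahedral shear strain, percent
    fluid_velocity: np.ndarray     # relative fluid velocity magnitude, um/s
    displacement: np.ndarray       # (N9, 2) mm at end of ramp
    pressure: np.ndarray           # (N4,) MPa at end of ramp
    strain: np.ndarray             # (E, 4) centroid strain components

    def __post_init__(self) -> None:
        for name in ("gamma_pct", "fluid_velocity"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(f"non-finite values in {name}")


class BiphasicFEM:
    """Assembler/solver bound to one mesh.

    Geometry-dependent integrals (strain-displacement matrices at Gauss
    points, coupling and unit flow/storage matrices, the sparse pattern) are
    precomputed once; per-solve work is scaling by material properties,
    sparse assembly, one LU factorisation and the ramp time steps.
    """

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        self._build_q9()
        self._precompute()

    # ------------------------------------------------------------------
    def _build_q9(self) -> None:
        mesh = self.mesh
        n4 = mesh.n_nodes
        coords = [mesh.nodes]
        edge_mid: Dict[tuple, int] = {}
        extra = []
        nid = n4
        elems9 = np.empty((mesh.n_elems, 9), dtype=np.int64)
        elems9[:, :4] = mesh.elems
        for e in range(mesh.n_elems):
            quad = mesh.elems[e]
            for k in range(4):
                a, b = int(quad[k]), int(quad[(k + 1) % 4])
                key = (min(a, b), max(a, b))
                if key not in edge_mid:
                    edge_mid[key] = nid
                    extra.append(0.5 * (mesh.nodes[a] + mesh.nodes[b]))
                    nid += 1
                elems9[e, 4 + k] = edge_mid[key]
            elems9[e, 8] = nid
            extra.append(mesh.nodes[quad].mean(axis=0))
            nid += 1
        self.nodes9 = np.vstack([mesh.nodes, np.array(extra)])
        self.elems9 = elems9
        self.n9 = nid
        self._edge_mid = edge_mid

    def q9_nodes_where(self, predicate) -> np.ndarray:
        """Ids of displacement nodes whose (r, z) satisfies ``predicate``."""
        mask = predicate(self.nodes9[:, 0], self.nodes9[:, 1])
        return np.nonzero(mask)[0]

    def expand_node_set(self, corner_ids: np.ndarray) -> np.ndarray:
        """Q9 node set spanned by a corner-node set (adds edge midpoints)."""
        corner = set(int(i) for i in np.asarray(corner_ids).ravel())
        out = sorted(corner)
        for (a, b), mid in self._edge_mid.items():
            if a in corner and b in corner:
                out.append(mid)
        return np.array(sorted(out), dtype=np.int64)

    # ------------------------------------------------------------------
    def _precompute(self) -> None:
        mesh = self.mesh
        E = mesh.n_elems
        gl = np.sqrt(0.6)
        pts1d = np.array([-gl, 0.0, gl])
        w1d = np.array([5.0, 8.0, 5.0]) / 9.0
        gps = [(xi, eta, wx * we) for xi, wx in zip(pts1d, w1d)
               for eta, we in zip(pts1d, w1d)]
        G = len(gps)

        rc = mesh.nodes[mesh.elems, 0]   # (E, 4)
        zc = mesh.nodes[mesh.elems, 1]

        B = np.zeros((G, E, 4, 18))
        Np = np.zeros((G, E, 4))
        gNp = np.zeros((G, E, 2, 4))
        W = np.zeros((G, E))

        for g, (xi, eta, w) in enumerate(gps):
            N4, dN4 = _shape_q4(xi, eta)
            N9, dN9 = _shape_q9(xi, eta)
            J = np.empty((E, 2, 2))
            J[:, 0, 0] = rc @ dN4[:, 0]
            J[:, 0, 1] = zc @ dN4[:, 0]
            J[:, 1, 0] = rc @ dN4[:, 1]
            J[:, 1, 1] = zc @ dN4[:, 1]
            detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
            invJ = np.empty_like(J)
            invJ[:, 0, 0] = J[:, 1, 1] / detJ
            invJ[:, 0, 1] = -J[:, 0, 1] / detJ
            invJ[:, 1, 0] = -J[:, 1, 0] / detJ
            invJ[:, 1, 1] = J[:, 0, 0] / detJ
            r_g = rc @ N4
            # physical derivatives: dN/dx_k = invJ[k, l] * dN/dxi_l
            dN9x = np.einsum("ekl,nl->enk", invJ, dN9)   # (E, 9, 2)
            dN4x = np.einsum("ekl,nl->enk", invJ, dN4)   # (E, 4, 2)
            for n in range(9):
                B[g, :, 0, 2 * n] = dN9x[:, n, 0]            # eps_rr
                B[g, :, 1, 2 * n + 1] = dN9x[:, n, 1]        # eps_zz
                B[g, :, 2, 2 * n] = N9[n] / r_g              # eps_tt
                B[g, :, 3, 2 * n] = dN9x[:, n, 1]            # gamma_rz
                B[g, :, 3, 2 * n + 1] = dN9x[:, n, 0]
            Np[g] = N4[None, :]
            gNp[g] = np.swapaxes(dN4x, 1, 2)
            W[g] = w * detJ * 2.0 * np.pi * r_g

        self._B = B
        self._W = W
        m = np.array([1.0, 1.0, 1.0, 0.0])
        Bm = np.einsum("geai,a->gei", B, m)
        self._Ce = np.einsum("gei,gej,ge->eij", Bm, Np, W)           # (E,18,4)
        self._Kpe_unit = np.einsum("gekn,gekm,ge->enm", gNp, gNp, W)  # (E,4,4)
        self._Sme_unit = np.einsum("gen,gem,ge->enm", Np, Np, W)

        # centroid evaluation operators
        N4c, dN4c = _shape_q4(0.0, 0.0)
        N9c, dN9c = _shape_q9(0.0, 0.0)
        Jc = np.empty((E, 2, 2))
        Jc[:, 0, 0] = rc @ dN4c[:, 0]
        Jc[:, 0, 1] = zc @ dN4c[:, 0]
        Jc[:, 1, 0] = rc @ dN4c[:, 1]
        Jc[:, 1, 1] = zc @ dN4c[:, 1]
        detJc = Jc[:, 0, 0] * Jc[:, 1, 1] - Jc[:, 0, 1] * Jc[:, 1, 0]
        invJc = np.empty_like(Jc)
        invJc[:, 0, 0] = Jc[:, 1, 1] / detJc
        invJc[:, 0, 1] = -Jc[:, 0, 1] / detJc
        invJc[:, 1, 0] = -Jc[:, 1, 0] / detJc
        invJc[:, 1, 1] = Jc[:, 0, 0] / detJc
        rcen = rc @ N4c
        dN9xc = np.einsum("ekl,nl->enk", invJc, dN9c)
        B0 = np.zeros((E, 4, 18))
        for n in range(9):
            B0[:, 0, 2 * n] = dN9xc[:, n, 0]
            B0[:, 1, 2 * n + 1] = dN9xc[:, n, 1]
            B0[:, 2, 2 * n] = N9c[n] / rcen
            B0[:, 3, 2 * n] = dN9xc[:, n, 1]
            B0[:, 3, 2 * n + 1] = dN9xc[:, n, 0]
        self._B0 = B0
        self._gNp0 = np.einsum("ekl,nl->ekn", invJc, dN4c)  # (E,2,4)

        # sparse pattern (COO index arrays), u block then p block
        eu = np.empty((self.mesh.n_elems, 18), dtype=np.int64)
        eu[:, 0::2] = 2 * self.elems9
        eu[:, 1::2] = 2 * self.elems9 + 1
        self._edof_u = eu
        self._edof_p = 2 * self.n9 + self.mesh.elems
        self.ndof = 2 * self.n9 + self.mesh.n_nodes

        # COO row/col arrays for each block
        self._iK = np.repeat(eu[:, :, None], 18, axis=2)
        self._jK = np.repeat(eu[:, None, :], 18, axis=1)
        self._iC = np.repeat(eu[:, :, None], 4, axis=2)
        self._jC = np.repeat(self._edof_p[:, None, :], 18, axis=1)
        self._iP = np.repeat(self._edof_p[:, :, None], 4, axis=2)
        self._jP = np.repeat(self._edof_p[:, None, :], 4, axis=1)

    # ------------------------------------------------------------------
    def _elastic_matrices(self, young, poisson):
        lam = young * poisson / ((1 + poisson) * (1 - 2 * poisson))
        mu = young / (2 * (1 + poisson))
        D = np.zeros((self.mesh.n_elems, 4, 4))
        for i in range(3):
            for j in range(3):
                D[:, i, j] = lam
            D[:, i, i] = lam + 2 * mu
        D[:, 3, 3] = mu
        return D

    def assemble(
        self,
        young: np.ndarray,
        poisson: np.ndarray,
        permeability: np.ndarray,
        porosity: np.ndarray,
        viscosity: float,
        dt: float,
    ):
        """Assemble the monolithic backward-Euler system matrix blocks."""
        young = np.asarray(young, dtype=float)
        if np.any(young <= 0.0):
            bad = int(np.argmax(young <= 0.0))
            raise ValueError(f"zero-stiffness element {bad}")
        D = self._elastic_matrices(young, np.asarray(poisson, dtype=float))
        Ke = np.einsum("geai,eab,gebj,ge->eij", self._B, D, self._B, self._W,
                       optimize=True)
        mob = np.asarray(permeability, dtype=float) / viscosity
        stor = np.asarray(porosity, dtype=float) / WATER_BULK_MODULUS_MPA
        Kpe = self._Kpe_unit * mob[:, None, None]
        Sme = self._Sme_unit * stor[:, None, None]
        n = self.ndof
        A = sp.coo_matrix(
            (
                np.concatenate(
                    [
                        Ke.ravel(),
                        -self._Ce.ravel(),
                        np.swapaxes(self._Ce, 1, 2).ravel(),
                        (Sme + dt * Kpe).ravel(),
                    ]
                ),
                (
                    np.concatenate(
                        [
                            self._iK.ravel(),
                            self._iC.ravel(),
                            np.swapaxes(self._jC, 1, 2).ravel(),
                            self._iP.ravel(),
                        ]
                    ),
                    np.concatenate(
                        [
                            self._jK.ravel(),
                            self._jC.ravel(),
                            np.swapaxes(self._iC, 1, 2).ravel(),
                            self._jP.ravel(),
                        ]
                    ),
                ),
            ),
            shape=(n, n),
        ).tocsc()
        # C^T and Sm are needed for the time-stepping right-hand side
        CT = sp.coo_matrix(
            (
                np.swapaxes(self._Ce, 1, 2).ravel(),
                (
                    np.swapaxes(self._jC, 1, 2).ravel(),
                    np.swapaxes(self._iC, 1, 2).ravel(),
                ),
            ),
            shape=(n, n),
        ).tocsr()
        Sm = sp.coo_matrix(
            (Sme.ravel(), (self._iP.ravel(), self._jP.ravel())), shape=(n, n)
        ).tocsr()
        return A, CT, Sm, mob

    # ------------------------------------------------------------------
    def traction_load_vector(
        self, load_nodes: np.ndarray, total_force: float,
        direction: Sequence[float] = (0.0, -1.0),
    ) -> np.ndarray:
        """Consistent nodal forces for a uniform traction on boundary faces.

        ``load_nodes`` is a corner-node set; every exterior element face with
        both corners in the set is loaded.  The traction magnitude is
        ``total_force`` divided by the total (axisymmetric) loaded area.
        """
        mesh = self.mesh
        faces = ((0, 1), (1, 2), (2, 3), (3, 0))
        nodeset = set(int(i) for i in np.asarray(load_nodes).ravel())
        loaded = []
        area = 0.0
        for e in range(mesh.n_elems):
            for f, (a, b) in enumerate(faces):
                if mesh.neighbors[e, f] != -1:
                    continue
                na, nb = int(mesh.elems[e, a]), int(mesh.elems[e, b])
                if na in nodeset and nb in nodeset:
                    loaded.append((e, f, na, nb))
                    area += mesh.face_area[e, f]
        if not loaded:
            raise ValueError("load face matched no boundary faces")
        trac = total_force / area
        dirv = np.asarray(direction, dtype=float)
        fvec = np.zeros(self.ndof)
        gl = np.sqrt(0.6)
        pts = np.array([-gl, 0.0, gl])
        wts = np.array([5.0, 8.0, 5.0]) / 9.0
        for e, f, na, nb in loaded:
            mid = self._edge_mid[(min(na, nb), max(na, nb))]
            ra, rb = self.nodes9[na, 0], self.nodes9[nb, 0]
            L = np.linalg.norm(self.nodes9[nb] - self.nodes9[na])
            for x, w in zip(pts, wts):
                N = np.array([0.5 * x * (x - 1), 1 - x * x, 0.5 * x * (x + 1)])
                r = N @ np.array([ra, self.nodes9[mid, 0], rb])
                scale = trac * w * (L / 2.0) * 2.0 * np.pi * r
                for n_loc, nid in zip(N, (na, mid, nb)):
                    fvec[2 * nid] += scale * n_loc * dirv[0]
                    fvec[2 * nid + 1] += scale * n_loc * dirv[1]
        return fvec

    # ------------------------------------------------------------------
    def solve_ramp(
        self,
        young: np.ndarray,
        poisson: np.ndarray,
        permeability: np.ndarray,
        porosity: np.ndarray,
        viscosity: float,
        load: LoadCase,
        load_nodes: np.ndarray,
        fix_ur: np.ndarray,
        fix_uz: np.ndarray,
        drained_nodes: np.ndarray,
        n_hold_steps: int = 0,
        record_history: bool = False,
    ) -> FieldSolution:
        """Time-step one ramp-load event and extract centroid stimuli.

        ``fix_ur``/``fix_uz`` are displacement (Q9) node ids with zero radial
        or axial displacement; ``drained_nodes`` are pressure (corner) node
        ids held at p = 0.  ``n_hold_steps`` continues time stepping at peak
        load after the ramp (used by consolidation benchmarks).
        """
        dt = load.time_step
        A, CT, Sm, mob = self.assemble(
            young, poisson, permeability, porosity, viscosity, dt
        )
        f_full = (
            self.traction_load_vector(load_nodes, load.peak_axial_force)
            if load.peak_axial_force > 0.0
            else np.zeros(self.ndof)
        )

        fixed = np.concatenate(
            [
                2 * np.asarray(fix_ur, dtype=np.int64).ravel(),
                2 * np.asarray(fix_uz, dtype=np.int64).ravel() + 1,
                2 * self.n9 + np.asarray(drained_nodes, dtype=np.int64).ravel(),
            ]
        )
        fixed = np.unique(fixed)
        free = np.setdiff1d(np.arange(self.ndof), fixed)
        Aff = A[free][:, free].tocsc()
        lu = splu(Aff)

        x = np.zeros(self.ndof)
        nsteps = int(round(load.ramp_duration / dt))
        history = []
        for step in range(1, nsteps + n_hold_steps + 1):
            t = step * dt
            scale = min(t / load.ramp_duration, 1.0)
            rhs = scale * f_full + CT @ x + Sm @ x
            xnew = np.zeros(self.ndof)
            xnew[free] = lu.solve(rhs[free])
            x = xnew
            if record_history:
                history.append(x.copy())

        u = x[: 2 * self.n9].reshape(-1, 2)
        p = x[2 * self.n9:]
        strain = np.einsum("eij,ej->ei", self._B0, x[self._edof_u])
        gamma = octahedral_shear_strain(strain) * 100.0
        gradp = np.einsum("ekn,en->ek", self._gNp0, p[self.mesh.elems])
        v = mob * np.linalg.norm(gradp, axis=1) * 1e3  # mm/s -> um/s
        sol = FieldSolution(
            gamma_pct=gamma,
            fluid_velocity=v,
            displacement=u,
            pressure=p,
            strain=strain,
        )
        if record_history:
            sol.raw_history = history  # type: ignore[attr-defined]
        return sol
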