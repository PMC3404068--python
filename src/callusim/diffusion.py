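"""Axisymmetric bilinear-quad FE kernel for scalar reaction-diffusion fields.

One implicit (backward-Euler) step of

    d(phi)/dt = div(D grad phi) + s

with element-wise diffusivity ``D``, element-wise source density ``s``,
Dirichlet node clamps and a lumped (row-sum) mass matrix.  The lumped mass
keeps the update monotone (a discrete maximum principle) on meshes of
near-unit aspect ratio, which the bound-preserving transport fields rely on.

All three transported fields of the healing model (vessel concentration,
oxygen tension, cell density) share this kernel; their modules add the
gating, sink and logistic terms.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import Mesh

__all__ = ["ScalarDiffusion"]


class ScalarDiffusion:
    """Precomputed per-element diffusion/mass matrices on a quad mesh."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        E = mesh.n_elems
        rc = mesh.nodes[mesh.elems, 0]
        zc = mesh.nodes[mesh.elems, 1]
        g = 1.0 / np.sqrt(3.0)
        Ke = np.zeros((E, 4, 4))
        Me = np.zeros((E, 4))
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
                dN = 0.25 * np.array(
                    [
                        [-(1 - eta), -(1 - xi)],
                        [(1 - eta), -(1 + xi)],
                        [(1 + eta), (1 + xi)],
                        [-(1 + eta), (1 - xi)],
                    ]
                )
                J = np.empty((E, 2, 2))
                J[:, 0, 0] = rc @ dN[:, 0]
                J[:, 0, 1] = zc @ dN[:, 0]
                J[:, 1, 0] = rc @ dN[:, 1]
                J[:, 1, 1] = zc @ dN[:, 1]
                detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
                invJ = np.empty_like(J)
                invJ[:, 0, 0] = J[:, 1, 1] / detJ
                invJ[:, 0, 1] = -J[:, 0, 1] / detJ
                invJ[:, 1, 0] = -J[:, 1, 0] / detJ
                invJ[:, 1, 1] = J[:, 0, 0] / detJ
                dNx = np.einsum("ekl,nl->enk", invJ, dN)  # (E, 4, 2)
                w = detJ * (rc @ N) * 2.0 * np.pi
                Ke += np.einsum("enk,emk,e->enm", dNx, dNx, w)
                Me += np.outer(np.ones(E), N) * w[:, None]
        self._Ke_unit = Ke
        self._Me_lumped = Me  # per-element lumped mass shares (E, 4)
        self._rows = np.repeat(mesh.elems[:, :, None], 4, axis=2).ravel()
        self._cols = np.repeat(mesh.elems[:, None, :], 4, axis=1).ravel()
        self.lumped_mass = np.zeros(mesh.n_nodes)
        np.add.at(self.lumped_mass, mesh.elems.ravel(), Me.ravel())

    # ------------------------------------------------------------------
    def stiffness(self, diffusivity: np.ndarray) -> sp.csr_matrix:
        """Global diffusion matrix for element-wise diffusivity."""
        vals = (self._Ke_unit * np.asarray(diffusivity)[:, None, None]).ravel()
        n = self.mesh.n_nodes
        return sp.coo_matrix((vals, (self._rows, self._cols)), shape=(n, n)).tocsr()

    def element_source_vector(self, source_density: np.ndarray) -> np.ndarray:
        """Nodal load vector for an element-wise volumetric source density."""
        f = np.zeros(self.mesh.n_nodes)
        contrib = self._Me_lumped * np.asarray(source_density)[:, None]
        np.add.at(f, self.mesh.elems.ravel(), contrib.ravel())
        return f

    def step(
        self,
        field: np.ndarray,
        diffusivity: np.ndarray,
        dt: float,
        dirichlet_nodes: Optional[np.ndarray] = None,
        dirichlet_value: float = 0.0,
        source_density: Optional[np.ndarray] = None,
        nodal_source: Optional[np.ndarray] = None,
        n_substeps: int = 1,
        dirichlet_values: Optional[np.ndarray] = None,
    ) -> np.ndarray:
        """Advance ``field`` by ``dt`` with ``n_substeps`` implicit substeps.

        ``source_density`` is per-element (volumetric), ``nodal_source`` a
        pre-assembled nodal vector; both are held constant over the step.
        ``dirichlet_values`` optionally gives per-node clamp values (full
        length array) instead of the scalar ``dirichlet_value``.
        """
        if dt <= 0.0:
            raise ValueError("dt must be positive")
        if n_substeps < 1:
            raise ValueError("n_substeps must be >= 1")
        phi = np.asarray(field, dtype=float).copy()
        dts = dt / n_substeps
        K = self.stiffness(diffusivity)
        Minv_dt = self.lumped_mass / dts
        A = sp.diags(Minv_dt) + K
        f = np.zeros(self.mesh.n_nodes)
        if source_density is not None:
            f += self.element_source_vector(source_density)
        if nodal_source is not None:
            f += nodal_source
        if dirichlet_nodes is not None and len(dirichlet_nodes) > 0:
            dn = np.asarray(dirichlet_nodes, dtype=np.int64)
            A = A.tolil()
            A[dn, :] = 0.0
            A[dn, dn] = 1.0
            A = A.tocsc()
        else:
            dn = None
            A = A.tocsc()
        lu = splu(A)
        for _ in range(n_substeps):
            rhs = Minv_dt * phi + f
            if dn is not None:
                rhs[dn] = (
                    dirichlet_values[dn]
                    if dirichlet_values is not None
                    else dirichlet_value
                )
            phi = lu.solve(rhs)
        return phi

    def element_means(self, nodal_field: np.ndarray) -> np.ndarray:
        """Mean of the four corner-node values per element."""
        return np.asarray(nodal_field)[self.mesh.elems].mean(axis=1)
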