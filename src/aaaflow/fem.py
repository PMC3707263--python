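"""P1 finite-element assembly on simplex meshes (vectorized, scipy.sparse).

Linear (P1) basis functions have constant gradients per element, so mass,
stiffness, gradient and (linearized) convection operators reduce to small
per-element dense blocks assembled with one ``coo_matrix`` call each.
Exact quadrature is used throughout (all integrands are polynomials).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
import scipy.sparse as sp

__all__ = ["P1Basis", "apply_dirichlet"]


@dataclass
class P1Basis:
    """Precomputed element geometry and constant operators for one mesh."""

    mesh: object
    volumes: np.ndarray      # (ne,)
    grads: np.ndarray        # (ne, nv, dim) basis gradients
    h_elem: np.ndarray       # (ne,) element size (longest edge)

    def __init__(self, mesh):
        self.mesh = mesh
        pts = mesh.points
        elems = mesh.elements
        x = pts[elems]                       # (ne, nv, dim)
        dim = pts.shape[1]
        nv = dim + 1
        e = x[:, 1:, :] - x[:, :1, :]        # (ne, dim, dim)
        det = np.linalg.det(e)
        self.volumes = det / (2.0 if dim == 2 else 6.0)
        if np.any(self.volumes <= 0):
            raise ValueError("mesh has non-positively oriented elements")
        # barycentric gradients: with edge rows e_i = x_i - x0,
        # grad lambda_i is the i-th row of inv(e)^T and lambda_0 closes
        # the partition of unity
        inv_t = np.transpose(np.linalg.inv(e), (0, 2, 1))
        grads = np.empty((len(elems), nv, dim))
        grads[:, 1:, :] = inv_t
        grads[:, 0, :] = -inv_t.sum(axis=1)
        self.grads = grads
        # longest edge as element size
        h2 = np.zeros(len(elems))
        for i in range(nv):
            for j in range(i + 1, nv):
                d = x[:, i, :] - x[:, j, :]
                h2 = np.maximum(h2, np.einsum("ij,ij->i", d, d))
        self.h_elem = np.sqrt(h2)

    # -- assembly helpers ---------------------------------------------------

    @property
    def _ij(self):
        elems = self.mesh.elements
        nv = elems.shape[1]
        rows = np.repeat(elems, nv, axis=1).ravel()
        cols = np.tile(elems, (1, nv)).ravel()
        return rows, cols

    def _assemble(self, blocks: np.ndarray) -> sp.csr_matrix:
        rows, cols = self._ij
        n = self.mesh.npoints
        return sp.coo_matrix(
            (blocks.reshape(len(blocks), -1).ravel(), (rows, cols)), shape=(n, n)
        ).tocsr()

    def stiffness(self, weight: np.ndarray | float = 1.0) -> sp.csr_matrix:
        """K_ij = sum_K w_K V_K grad(l_i).grad(l_j)."""
        w = np.asarray(weight) * self.volumes
        blocks = np.einsum("e,eid,ejd->eij", w, self.grads, self.grads)
        return self._assemble(blocks)

    def lumped_mass(self) -> np.ndarray:
        """Row-sum lumped mass vector (V/(dim+1) to each vertex)."""
        nv = self.mesh.elements.shape[1]
        m = np.zeros(self.mesh.npoints)
        np.add.at(m, self.mesh.elements.ravel(),
                  np.repeat(self.volumes / nv, nv))
        return m

    def gradient_ops(self) -> List[sp.csr_matrix]:
        """G_c[i, j] = integral l_i d_c l_j (one matrix per direction)."""
        nv = self.mesh.elements.shape[1]
        ops = []
        for c in range(self.mesh.dim):
            # blocks[e, i, j] = V/nv * (grad l_j)_c, constant in i
            blocks = np.broadcast_to(
                (self.volumes[:, None] / nv * self.grads[:, :, c])[:, None, :],
                (len(self.volumes), nv, nv),
            )
            ops.append(self._assemble(np.ascontiguousarray(blocks)))
        return ops

    def convection(self, w_nodes: np.ndarray) -> sp.csr_matrix:
        """C_ij = integral l_i (w . grad l_j) with w linear per element."""
        elems = self.mesh.elements
        nv = elems.shape[1]
        wk = w_nodes[elems]                        # (ne, nv, dim)
        a = np.einsum("ekd,ejd->ekj", wk, self.grads)   # (ne, k, j): w_k . grad l_j
        denom = (nv) * (nv + 1)
        # integral l_i l_k = V (1+delta_ik)/denom
        coef = (np.ones((nv, nv)) + np.eye(nv)) / denom
        blocks = np.einsum("e,ik,ekj->eij", self.volumes, coef, a)
        return self._assemble(blocks)

    def divergence(self, u: np.ndarray, grad_ops=None) -> np.ndarray:
        """Weak divergence vector b_i = integral l_i div(u)."""
        if grad_ops is None:
            grad_ops = self.gradient_ops()
        b = np.zeros(self.mesh.npoints)
        for c, G in enumerate(grad_ops):
            b += G @ u[:, c]
        return b

    def element_gradient(self, field: np.ndarray) -> np.ndarray:
        """Constant per-element gradient of a nodal field.

        Scalar field -> (ne, dim); vector field (n, m) -> (ne, m, dim).
        """
        vals = field[self.mesh.elements]            # (ne, nv[, m])
        if vals.ndim == 2:
            return np.einsum("ei,eid->ed", vals, self.grads)
        return np.einsum("eim,eid->emd", vals, self.grads)

    def element_divergence(self, u: np.ndarray) -> np.ndarray:
        g = self.element_gradient(u)                # (ne, dim, dim)
        return np.trace(g, axis1=1, axis2=2)


def apply_dirichlet(A: sp.csr_matrix, dirichlet: np.ndarray) -> sp.csr_matrix:
    """Replace Dirichlet rows of ``A`` by identity rows."""
    n = A.shape[0]
    keep = np.ones(n)
    keep[dirichlet] = 0.0
    D_free = sp.diags(keep)
    D_dir = sp.diags(1.0 - keep)
    return (D_free @ A + D_dir).tocsr()
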