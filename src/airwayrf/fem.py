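"""Linear (P1) tetrahedral finite-element kernels.

Vectorized assembly of stiffness and lumped-mass operators with
per-element coefficients, facet load vectors, and a Dirichlet solver
that partitions the system into free/constrained blocks.  Direct
sparse factorization is used by default; systems above a configurable
size fall back to conjugate gradients with a diagonal preconditioner.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


def tet_geometry(nodes: np.ndarray, elems: np.ndarray):
    """Volumes (M,) and shape-function gradients (M, 4, 3) of P1 tets."""
    p = nodes[elems]
    J = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]],
                 axis=1)  # rows a, b, c
    vols = np.linalg.det(J) / 6.0
    Jinv = np.linalg.inv(J)
    # grad(lambda_i) for i = 1..3 are the columns of J^{-1}; lambda_0 closes.
    g123 = np.transpose(Jinv, (0, 2, 1))
    g0 = -g123.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g123], axis=1)
    return vols, grads


def stiffness(
    nodes: np.ndarray,
    elems: np.ndarray,
    coeff: np.ndarray,
    vols: np.ndarray | None = None,
    grads: np.ndarray | None = None,
) -> sp.csr_matrix:
    """Assemble K_ij = sum_e coeff_e * V_e * grad(phi_i) . grad(phi_j)."""
    if vols is None or grads is None:
        vols, grads = tet_geometry(nodes, elems)
    Ke = (coeff * vols)[:, None, None] * np.einsum(
        "mid,mjd->mij", grads, grads
    )
    rows = np.broadcast_to(elems[:, :, None], Ke.shape)
    cols = np.broadcast_to(elems[:, None, :], Ke.shape)
    n = nodes.shape[0]
    return sp.coo_matrix(
        (Ke.ravel(), (rows.ravel(), cols.ravel())), shape=(n, n)
    ).tocsr()


def lumped_mass(
    n_nodes: int, elems: np.ndarray, coeff: np.ndarray, vols: np.ndarray
) -> np.ndarray:
    """Row-sum (lumped) mass vector: coeff_e * V_e / 4 to each vertex."""
    m = np.zeros(n_nodes)
    np.add.at(m, elems, ((coeff * vols) / 4.0)[:, None])
    return m


def element_load(
    n_nodes: int, elems: np.ndarray, vols: np.ndarray, q: np.ndarray
) -> np.ndarray:
    """Nodal load vector of a piecewise-constant volumetric source q_e."""
    f = np.zeros(n_nodes)
    np.add.at(f, elems, ((q * vols) / 4.0)[:, None])
    return f


def facet_load(
    n_nodes: int, facets: np.ndarray, areas: np.ndarray, flux: np.ndarray
) -> np.ndarray:
    """Nodal load vector of a piecewise-constant surface flux (W/m^2)."""
    f = np.zeros(n_nodes)
    np.add.at(f, facets, ((flux * areas) / 3.0)[:, None])
    return f


class SolverError(RuntimeError):
    """Linear system could not be solved (singular or non-convergent)."""


class DirichletSolver:
    """Solve A u = b with fixed values on a set of nodes.

    Partitions A into free/constrained blocks; exposes the reaction
    residual r = A u - b at the constrained nodes, which is the
    consistent (superconvergent) boundary flux of the discrete
    solution.
    """

    def __init__(
        self,
        A: sp.spmatrix,
        fixed: np.ndarray,
        n: int,
        iterative_threshold: int = 200_000,
        tol: float = 1e-8,
    ):
        self.A = A.tocsr()
        self.n = n
        self.fixed = np.asarray(fixed, dtype=np.int64)
        free = np.ones(n, dtype=bool)
        free[self.fixed] = False
        self.free = np.flatnonzero(free)
        self._Aff = self.A[self.free][:, self.free].tocsc()
        self._Afc = self.A[self.free][:, self.fixed].tocsr()
        self._tol = tol
        self._iterative = len(self.free) > iterative_threshold
        self._lu = None
        if not self._iterative:
            try:
                self._lu = spla.splu(self._Aff)
            except RuntimeError as exc:  # pragma: no cover - diagnostics
                raise SolverError(
                    f"singular system ({exc}); check that the conducting "
                    "path between the Dirichlet boundaries is connected"
                ) from exc

    def solve(self, b: np.ndarray, fixed_values: np.ndarray) -> np.ndarray:
        u = np.zeros(self.n)
        u[self.fixed] = fixed_values
        rhs = b[self.free] - self._Afc @ u[self.fixed]
        if self._lu is not None:
            uf = self._lu.solve(rhs)
        else:
            M = sp.diags(1.0 / self._Aff.diagonal())
            uf, info = spla.cg(self._Aff, rhs, rtol=self._tol, M=M,
                               maxiter=10 * len(rhs))
            if info != 0:
                raise SolverError(f"CG failed to converge (info={info})")
        if not np.all(np.isfinite(uf)):
            raise SolverError("non-finite solution (singular system?)")
        u[self.free] = uf
        return u

    def reactions(self, u: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Residual A u - b at the constrained nodes (consistent flux)."""
        return (self.A @ u - b)[self.fixed]
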