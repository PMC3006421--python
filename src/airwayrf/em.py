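"""Quasi-static electrical solve and generator-level telemetry quantities.

At 480 kHz soft tissue is essentially resistive, so the RF problem
reduces to the steady conduction equation -div(sigma(T) grad V) = 0 at
each instant.  The drive voltage is applied on the electrode
cross-section at the axial symmetry plane, the 30-degree midplane
between adjacent electrodes is grounded, and all remaining exterior
surfaces carry zero normal current.

Sector quantities are mapped to generator (device) level through a
:class:`SymmetryConvention`: the sector is 1/24 of the device by
symmetry (12 circumferential x 2 axial), adjacent electrodes are
driven antisymmetrically so the terminal voltage is twice the sector
drive, and the generator sources current through half the electrodes,
giving I_device = 2 * n_electrodes * I_sector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fem
from .geometry import Boundary, Mesh


@dataclass(frozen=True)
class SymmetryConvention:
    """Sector -> device scaling factors, frozen by the symmetry audits."""

    n_electrodes: int = 6

    @property
    def voltage(self) -> int:
        return 2

    @property
    def current(self) -> int:
        return 2 * self.n_electrodes

    @property
    def power(self) -> int:
        return self.voltage * self.current


@dataclass
class PotentialField:
    """Solved nodal electric potential and its boundary-condition snapshot."""

    V: np.ndarray
    V_applied: float
    drive_nodes: np.ndarray
    ground_nodes: np.ndarray
    _solver: fem.DirichletSolver | None = field(default=None, repr=False)
    _rhs: np.ndarray | None = field(default=None, repr=False)


def solve_potential(
    mesh: Mesh,
    sigma_elem: np.ndarray,
    V_applied: float,
    dirichlet: list[tuple[np.ndarray, float]] | None = None,
    iterative_threshold: int = 200_000,
    tol: float = 1e-8,
) -> PotentialField:
    """Weak solution of -div(sigma grad V) = 0 on the tagged mesh.

    dirichlet optionally overrides the default boundary sets with an
    explicit list of (node indices, value) pairs (used by the symmetry
    audits, where the drive is applied to whole electrode bodies).
    """
    if V_applied < 0:
        raise ValueError("V_applied must be non-negative")
    if np.any(sigma_elem <= 0):
        raise ValueError("sigma must be positive on every element")

    if dirichlet is None:
        drive = mesh.nodes_on(Boundary.ELECTRODE_DRIVE_FACE)
        ground = mesh.nodes_on(Boundary.GROUND_PLANE)
        if drive.size == 0 or ground.size == 0:
            raise fem.SolverError("mesh lacks drive or ground facets")
        dirichlet = [(drive, V_applied), (ground, 0.0)]
    else:
        drive = dirichlet[0][0]
        ground = dirichlet[-1][0]

    n = mesh.num_nodes
    if V_applied == 0.0 and all(v == 0.0 for _, v in dirichlet):
        return PotentialField(np.zeros(n), 0.0, drive, ground)

    K = fem.stiffness(mesh.nodes, mesh.elems, sigma_elem)
    fixed = np.concatenate([idx for idx, _ in dirichlet])
    values = np.concatenate(
        [np.full(len(idx), val) for idx, val in dirichlet]
    )
    solver = fem.DirichletSolver(K, fixed, n, iterative_threshold, tol)
    V = solver.solve(np.zeros(n), values)
    return PotentialField(V, float(V_applied), drive, ground,
                          _solver=solver, _rhs=np.zeros(n))


def joule_power_density(
    mesh: Mesh, field: PotentialField, sigma_elem: np.ndarray
) -> np.ndarray:
    """Per-element RF power density q = sigma |grad V|^2 (W/m^3, >= 0)."""
    _, grads = fem.tet_geometry(mesh.nodes, mesh.elems)
    E = np.einsum("mid,mi->md", grads, field.V[mesh.elems])
    return sigma_elem * np.einsum("md,md->m", E, E)


def sector_current(mesh: Mesh, field: PotentialField) -> float:
    """Current entering the model through the driven electrode face, A.

    Computed as the consistent reaction of the discrete system at the
    drive nodes (volume-weighted flux), which converges faster than
    differentiating the potential across boundary facets.
    """
    if field._solver is None:
        return 0.0
    r = field._solver.reactions(field.V, field._rhs)
    drive_set = set(field.drive_nodes.tolist())
    on_drive = np.array([i in drive_set for i in field._solver.fixed])
    return float(r[on_drive].sum())


def electrode_current_and_impedance(
    mesh: Mesh,
    field: PotentialField,
    convention: SymmetryConvention = SymmetryConvention(),
) -> tuple[float, float]:
    """Device-level current (A) and impedance (ohm).

    Raises ValueError at zero applied voltage, where the impedance is
    undefined.
    """
    if field.V_applied == 0.0:
        raise ValueError("impedance undefined at zero applied voltage")
    I_s = sector_current(mesh, field)
    I_dev = convention.current * I_s
    V_dev = convention.voltage * field.V_applied
    return I_dev, V_dev / I_dev
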