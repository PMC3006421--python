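"""Symmetry-reduced airway/electrode/parenchyma geometry and meshing.

The device is a six-electrode bipolar catheter expanded against the
wall of a cylindrical airway embedded in parenchyma.  Even spacing of
the electrodes gives 12-fold circumferential symmetry (each 30-degree
sector contains half an electrode at one face and the grounded
midplane between adjacent electrodes at the other), and mirror
symmetry about the electrode's axial midpoint halves the model again,
so the computational domain is a 30-degree, half-length sector.

Coordinates are cylindrical: the airway axis is z, the electrode is
centered at theta = 0, z = 0, and the sector spans theta in
[0, 30 deg], z in [0, half_length].

Meshing is structured: graded tensor grids in (r, theta, z) whose
breakpoints conform exactly to every material interface, with each
hexahedral cell split into six tetrahedra (Freudenthal subdivision,
conforming across cells).  The electrode cross-section is modeled as
an annular-sector box — the published device uses a D-profile wire of
the same width, but the profile detail is below the scale resolved
here and the box conforms exactly to the grid.  The lumen is truncated
at a small core radius instead of being meshed to the axis (lumen air
is electrically and thermally near-inert; the truncation face is
adiabatic and insulated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import IntEnum

import numpy as np


class GeometryError(ValueError):
    """Invalid device geometry or meshing failure."""


class Subdomain(IntEnum):
    ELECTRODE = 1
    AIRWAY_WALL = 2
    PARENCHYMA = 3
    LUMEN_AIR = 4


class Boundary(IntEnum):
    ELECTRODE_DRIVE_FACE = 1      # electrode cross-section on the z=0 plane
    GROUND_PLANE = 2              # theta = sector_angle symmetry plane (0 V)
    SYMMETRY_ELECTRODE_PLANE = 3  # theta = 0 plane through the electrode
    SYMMETRY_AXIAL_PLANE = 4      # z = 0 plane (excluding the drive face)
    OUTER_SURFACE = 5             # outer radius and far axial end (37 C, insulated)
    LUMINAL_SURFACE = 6           # air / airway-wall interface (evaporating)
    ELECTRODE_TISSUE_INTERFACE = 7
    AXIS_PLANE = 8                # lumen truncation face near the axis
    WALL_PARENCHYMA_INTERFACE = 9


#: Subdomain -> material name in the property table.
SUBDOMAIN_MATERIAL = {
    Subdomain.ELECTRODE: "stainless_steel_304",
    Subdomain.AIRWAY_WALL: "trachea",
    Subdomain.PARENCHYMA: "parenchyma",
    Subdomain.LUMEN_AIR: "air",
}

#: Mesh refinement level -> per-direction cell-count multiplier.
REFINEMENT_SCALE = {
    "tiny": 0.6,
    "coarse": 1.0,
    "medium": 1.4,
    "fine": 2.0,
    "paper": 3.0,
}


@dataclass(frozen=True)
class DeviceGeometry:
    """Physical dimensions of the airway, electrode, and model sector.

    All lengths in meters.  Derived quantities (wall thickness, sector
    angle, electrode radii) are properties so that the invariants
    wall = wall_thickness_fraction * lumen_diameter and
    sector_angle = 2 pi / (2 n_electrodes) hold by construction.
    """

    lumen_diameter: float = 4e-3
    wall_thickness_fraction: float = 0.10
    electrode_length: float = 10e-3
    electrode_width: float = 0.5e-3
    electrode_height: float = 0.25e-3
    embed_depth: float = 0.1e-3
    n_electrodes: int = 6
    outer_radius: float = 10e-3
    half_length: float = 10e-3
    core_radius: float = 0.4e-3

    @property
    def lumen_radius(self) -> float:
        return 0.5 * self.lumen_diameter

    @property
    def wall_thickness(self) -> float:
        return self.wall_thickness_fraction * self.lumen_diameter

    @property
    def wall_outer_radius(self) -> float:
        return self.lumen_radius + self.wall_thickness

    @property
    def sector_angle(self) -> float:
        return 2.0 * math.pi / (2 * self.n_electrodes)

    @property
    def electrode_back_radius(self) -> float:
        """Radius of the electrode's luminal (back) surface."""
        return self.lumen_radius - (self.electrode_height - self.embed_depth)

    @property
    def electrode_tip_radius(self) -> float:
        """Radius of the electrode's embedded tip inside the wall."""
        return self.lumen_radius + self.embed_depth

    @property
    def electrode_half_angle(self) -> float:
        return 0.5 * self.electrode_width / self.lumen_radius

    @property
    def electrode_half_length(self) -> float:
        return 0.5 * self.electrode_length

    def validate(self) -> None:
        if self.lumen_diameter <= 0:
            raise GeometryError("lumen_diameter must be positive")
        if not 0 < self.wall_thickness_fraction < 1:
            raise GeometryError("wall_thickness_fraction must lie in (0, 1)")
        if self.n_electrodes < 1:
            raise GeometryError("n_electrodes must be at least 1")
        if not 0 < self.embed_depth < self.wall_thickness:
            raise GeometryError(
                "embed_depth must lie strictly between 0 and the wall "
                f"thickness ({self.wall_thickness:g} m): the electrode must "
                "indent but not pierce the wall"
            )
        if self.electrode_height <= self.embed_depth:
            raise GeometryError("electrode_height must exceed embed_depth")
        if self.electrode_half_length >= self.half_length:
            raise GeometryError("half_length must exceed electrode_length/2")
        if self.outer_radius <= self.wall_outer_radius:
            raise GeometryError("outer_radius must exceed the wall outer radius")
        if self.electrode_half_angle >= self.sector_angle:
            raise GeometryError("electrode wider than the symmetry sector")
        if not 0 < self.core_radius < self.electrode_back_radius:
            raise GeometryError(
                "core_radius must lie strictly between 0 and the electrode "
                "back radius"
            )

    def scaled(self, s: float) -> "DeviceGeometry":
        """All lengths scaled by a factor s (similarity transform)."""
        return replace(
            self,
            lumen_diameter=s * self.lumen_diameter,
            electrode_length=s * self.electrode_length,
            electrode_width=s * self.electrode_width,
            electrode_height=s * self.electrode_height,
            embed_depth=s * self.embed_depth,
            outer_radius=s * self.outer_radius,
            half_length=s * self.half_length,
            core_radius=s * self.core_radius,
        )


@dataclass(frozen=True)
class SectorGeometry:
    """Validated solid-model description of the computational sector."""

    params: DeviceGeometry

    @property
    def sector_angle(self) -> float:
        return self.params.sector_angle

    def subdomain_volume(self, sub: Subdomain) -> float:
        """Analytic volume of a tagged region within the sector."""
        g = self.params
        th = g.sector_angle
        th_el = g.electrode_half_angle

        def annulus(r0, r1, angle, length):
            return 0.5 * angle * (r1 * r1 - r0 * r0) * length

        v_el = annulus(g.electrode_back_radius, g.electrode_tip_radius,
                       th_el, g.electrode_half_length)
        if sub is Subdomain.ELECTRODE:
            return v_el
        if sub is Subdomain.LUMEN_AIR:
            full = annulus(g.core_radius, g.lumen_radius, th, g.half_length)
            in_lumen = annulus(g.electrode_back_radius, g.lumen_radius,
                               th_el, g.electrode_half_length)
            return full - in_lumen
        if sub is Subdomain.AIRWAY_WALL:
            full = annulus(g.lumen_radius, g.wall_outer_radius, th, g.half_length)
            in_wall = annulus(g.lumen_radius, g.electrode_tip_radius,
                              th_el, g.electrode_half_length)
            return full - in_wall
        if sub is Subdomain.PARENCHYMA:
            return annulus(g.wall_outer_radius, g.outer_radius, th, g.half_length)
        raise GeometryError(f"unknown subdomain {sub!r}")

    def total_volume(self) -> float:
        return sum(self.subdomain_volume(s) for s in Subdomain)


def build_sector_geometry(params: DeviceGeometry) -> SectorGeometry:
    """Validate the device parameters and return the sector description."""
    params.validate()
    return SectorGeometry(params)


@dataclass
class Mesh:
    """Linear tetrahedral mesh with subdomain and boundary tags.

    nodes     : (N, 3) Cartesian coordinates, m
    cyl       : (N, 3) cylindrical coordinates (r, theta, z) of the nodes
    elems     : (M, 4) node indices, positively oriented
    elem_tag  : (M,) Subdomain value per element
    facets    : (F, 3) node indices of tagged facets (exterior boundary
                plus tagged internal interfaces)
    facet_tag : (F,) Boundary value per facet
    facet_elem: (F,) owner element index (tissue side for interfaces)
    """

    nodes: np.ndarray
    cyl: np.ndarray
    elems: np.ndarray
    elem_tag: np.ndarray
    facets: np.ndarray
    facet_tag: np.ndarray
    facet_elem: np.ndarray
    geometry: SectorGeometry | None = None

    @property
    def num_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def num_elements(self) -> int:
        return self.elems.shape[0]

    def element_volumes(self) -> np.ndarray:
        p = self.nodes[self.elems]
        a, b, c = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def facet_areas(self, which: np.ndarray | None = None) -> np.ndarray:
        f = self.facets if which is None else self.facets[which]
        p = self.nodes[f]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )

    def facets_with(self, tag: Boundary) -> np.ndarray:
        return np.flatnonzero(self.facet_tag == int(tag))

    def nodes_on(self, *tags: Boundary) -> np.ndarray:
        mask = np.isin(self.facet_tag, [int(t) for t in tags])
        return np.unique(self.facets[mask])

    def nodes_in(self, *subs: Subdomain) -> np.ndarray:
        mask = np.isin(self.elem_tag, [int(s) for s in subs])
        return np.unique(self.elems[mask])

    def element_quality(self) -> np.ndarray:
        """Shape quality per element: 6*sqrt(2)*V / l_max^3 (regular tet = 1)."""
        p = self.nodes[self.elems]
        vols = self.element_volumes()
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        lmax = np.max(
            [np.linalg.norm(p[:, i] - p[:, j], axis=1) for i, j in pairs], axis=0
        )
        return 6.0 * math.sqrt(2.0) * vols / lmax**3

    def subdomain_volume(self, sub: Subdomain) -> float:
        return float(self.element_volumes()[self.elem_tag == int(sub)].sum())


# --- structured grid machinery -------------------------------------------

def _graded(a: float, b: float, n: int, bias: float) -> np.ndarray:
    """n-cell partition of [a, b]; consecutive cell sizes grow by `bias`."""
    n = max(int(n), 1)
    w = bias ** np.arange(n)
    cum = np.concatenate(([0.0], np.cumsum(w)))
    return a + (b - a) * cum / cum[-1]


def _graded_from(a: float, b: float, h0: float, ratio: float) -> np.ndarray:
    """Partition of [a, b] growing geometrically from first-cell size h0.

    The cell count follows from h0 and the growth ratio, so near-`a`
    resolution stays fixed when the segment length (domain margin)
    changes.
    """
    length = b - a
    n = max(1, math.ceil(math.log1p(length * (ratio - 1.0) / h0)
                         / math.log(ratio)))
    return _graded(a, b, n, ratio)


def _concat_segments(segments) -> np.ndarray:
    """Join per-segment point arrays, dropping duplicated endpoints."""
    pts = [segments[0]]
    for seg in segments[1:]:
        pts.append(seg[1:])
    return np.concatenate(pts)


# Freudenthal subdivision of the unit cube (vertex bits: x + 2y + 4z).
_TETS = np.array(
    [[0, 1, 3, 7], [0, 1, 5, 7], [0, 2, 3, 7],
     [0, 2, 6, 7], [0, 4, 5, 7], [0, 4, 6, 7]]
)
# Quad faces of the cell -> two triangles (consistent with _TETS) and the
# local tet owning each triangle.
_FACE_TRIS = {
    "x0": [((0, 2, 6), 3), ((0, 6, 4), 5)],
    "x1": [((1, 3, 7), 0), ((1, 7, 5), 1)],
    "y0": [((0, 1, 5), 1), ((0, 5, 4), 4)],
    "y1": [((2, 3, 7), 2), ((2, 7, 6), 3)],
    "z0": [((0, 1, 3), 0), ((0, 3, 2), 2)],
    "z1": [((4, 5, 7), 4), ((4, 7, 6), 5)],
}

# Interface (subdomain-pair) -> tag and owner subdomain for the facet.
_INTERFACE_TAGS = {
    frozenset({Subdomain.LUMEN_AIR, Subdomain.AIRWAY_WALL}):
        (Boundary.LUMINAL_SURFACE, Subdomain.AIRWAY_WALL),
    frozenset({Subdomain.ELECTRODE, Subdomain.AIRWAY_WALL}):
        (Boundary.ELECTRODE_TISSUE_INTERFACE, Subdomain.AIRWAY_WALL),
    frozenset({Subdomain.AIRWAY_WALL, Subdomain.PARENCHYMA}):
        (Boundary.WALL_PARENCHYMA_INTERFACE, Subdomain.AIRWAY_WALL),
}


def _radial_points(g: DeviceGeometry, s: float) -> np.ndarray:
    """Graded radial breakpoints conforming to every material radius.

    Fine at the electrode/tissue band, coarsening toward the axis and
    the outer boundary (element size non-decreasing with distance from
    the electrode-tissue interface).
    """
    nc = lambda base: max(2, round(base * s))
    return _concat_segments([
        _graded(g.core_radius, g.electrode_back_radius, nc(4), 0.55),
        _graded(g.electrode_back_radius, g.lumen_radius, nc(2), 1.0),
        _graded(g.lumen_radius, g.electrode_tip_radius, nc(2), 1.0),
        _graded(g.electrode_tip_radius, g.wall_outer_radius, nc(3), 1.25),
        # Parenchyma margin: fixed first-cell size (resolves the thin
        # evaporative boundary layer identically at any outer radius).
        _graded_from(g.wall_outer_radius, g.outer_radius, 0.1e-3 / s, 1.5),
    ])


def _theta_points_sector(g: DeviceGeometry, s: float) -> np.ndarray:
    nc = lambda base: max(2, round(base * s))
    return _concat_segments([
        _graded(0.0, g.electrode_half_angle, nc(3), 1.0),
        _graded(g.electrode_half_angle, g.sector_angle, nc(6), 1.45),
    ])


def _z_points(g: DeviceGeometry, s: float) -> np.ndarray:
    nc = lambda base: max(2, round(base * s))
    return _concat_segments([
        _graded(0.0, g.electrode_half_length, nc(6), 1.0),
        _graded_from(g.electrode_half_length, g.half_length, 0.5e-3 / s, 1.5),
    ])


def _electrode_cell(g: DeviceGeometry, rc, tc, zc, centers) -> np.ndarray:
    """Boolean mask of cells whose centroid lies inside an electrode box."""
    radial = (rc > g.electrode_back_radius) & (rc < g.electrode_tip_radius)
    axial = np.abs(zc) < g.electrode_half_length
    angular = np.zeros_like(tc, dtype=bool)
    for c in centers:
        angular |= np.abs(tc - c) < g.electrode_half_angle
    return radial & angular & axial


def _classify(g: DeviceGeometry, rc, tc, zc, centers) -> np.ndarray:
    tag = np.empty(rc.shape, dtype=np.int32)
    tag[:] = int(Subdomain.PARENCHYMA)
    tag[rc < g.wall_outer_radius] = int(Subdomain.AIRWAY_WALL)
    tag[rc < g.lumen_radius] = int(Subdomain.LUMEN_AIR)
    tag[_electrode_cell(g, rc, tc, zc, centers)] = int(Subdomain.ELECTRODE)
    return tag


def _build_structured(
    g: DeviceGeometry,
    rs: np.ndarray,
    ts: np.ndarray,
    zs: np.ndarray,
    electrode_centers: tuple[float, ...],
    theta_face_tags: tuple[Boundary, Boundary],
    zmin_is_symmetry: bool,
    geometry: SectorGeometry | None,
) -> Mesh:
    nr, nt, nz = len(rs) - 1, len(ts) - 1, len(zs) - 1
    R, TH, Z = np.meshgrid(rs, ts, zs, indexing="ij")
    nodes = np.stack(
        [R * np.cos(TH), R * np.sin(TH), Z], axis=-1
    ).reshape(-1, 3)
    cyl = np.stack([R, TH, Z], axis=-1).reshape(-1, 3)

    def nid(i, j, k):
        return (i * (nt + 1) + j) * (nz + 1) + k

    # Cell centroids (in cylindrical coordinates) and subdomain tags.
    rc = 0.5 * (rs[:-1] + rs[1:])
    tc = 0.5 * (ts[:-1] + ts[1:])
    zc = 0.5 * (zs[:-1] + zs[1:])
    RC, TC, ZC = np.meshgrid(rc, tc, zc, indexing="ij")
    cell_tag = _classify(g, RC, TC, ZC, electrode_centers)

    # Cell corner node ids in Freudenthal bit order (x=r, y=theta, z=z).
    I, J, K = np.meshgrid(
        np.arange(nr), np.arange(nt), np.arange(nz), indexing="ij"
    )
    corners = np.stack(
        [nid(I + (b & 1), J + ((b >> 1) & 1), K + ((b >> 2) & 1))
         for b in range(8)],
        axis=-1,
    ).reshape(-1, 8)
    cells_flat = cell_tag.reshape(-1)

    elems = corners[:, _TETS].reshape(-1, 4)
    elem_tag = np.repeat(cells_flat, 6)

    # Enforce positive orientation.
    p = nodes[elems]
    vol6 = np.einsum(
        "ij,ij->i", p[:, 1] - p[:, 0], np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0])
    )
    flip = vol6 < 0
    elems[flip, 2], elems[flip, 3] = elems[flip, 3], elems[flip, 2].copy()

    def cell_index(i, j, k):
        return (i * nt + j) * nz + k

    facets, ftags, fowner = [], [], []

    def emit(ci, cj, ck, face: str, tag: Boundary):
        cell = cell_index(ci, cj, ck)
        cc = corners[cell]
        for tri, local_tet in _FACE_TRIS[face]:
            facets.append(cc[list(tri)])
            ftags.append(int(tag))
            fowner.append(cell * 6 + local_tet)

    tag_j0, tag_j1 = theta_face_tags
    for i in range(nr):
        for j in range(nt):
            for k in range(nz):
                tag_c = cells_flat[cell_index(i, j, k)]
                # Exterior faces.
                if i == 0:
                    emit(i, j, k, "x0", Boundary.AXIS_PLANE)
                if i == nr - 1:
                    emit(i, j, k, "x1", Boundary.OUTER_SURFACE)
                if j == 0:
                    emit(i, j, k, "y0", tag_j0)
                if j == nt - 1:
                    emit(i, j, k, "y1", tag_j1)
                if k == 0:
                    if zmin_is_symmetry:
                        tag = (Boundary.ELECTRODE_DRIVE_FACE
                               if tag_c == int(Subdomain.ELECTRODE)
                               else Boundary.SYMMETRY_AXIAL_PLANE)
                    else:
                        tag = Boundary.OUTER_SURFACE
                    emit(i, j, k, "z0", tag)
                if k == nz - 1:
                    emit(i, j, k, "z1", Boundary.OUTER_SURFACE)
                # Interior material interfaces (owner = tissue side).
                for di, dj, dk, face_lo, face_hi in (
                    (1, 0, 0, "x1", "x0"),
                    (0, 1, 0, "y1", "y0"),
                    (0, 0, 1, "z1", "z0"),
                ):
                    ni_, nj_, nk_ = i + di, j + dj, k + dk
                    if ni_ >= nr or nj_ >= nt or nk_ >= nz:
                        continue
                    tag_n = cells_flat[cell_index(ni_, nj_, nk_)]
                    if tag_n == tag_c:
                        continue
                    key = frozenset({Subdomain(tag_c), Subdomain(tag_n)})
                    if key not in _INTERFACE_TAGS:
                        continue
                    btag, owner_sub = _INTERFACE_TAGS[key]
                    if tag_c == int(owner_sub):
                        emit(i, j, k, face_lo, btag)
                    else:
                        emit(ni_, nj_, nk_, face_hi, btag)

    mesh = Mesh(
        nodes=nodes,
        cyl=cyl,
        elems=elems,
        elem_tag=elem_tag.astype(np.int32),
        facets=np.asarray(facets, dtype=np.int64),
        facet_tag=np.asarray(ftags, dtype=np.int32),
        facet_elem=np.asarray(fowner, dtype=np.int64),
        geometry=geometry,
    )
    _check_mesh(mesh)
    return mesh


def _check_mesh(mesh: Mesh, quality_floor: float = 1e-6) -> None:
    vols = mesh.element_volumes()
    if np.any(vols <= 0):
        bad = int(np.argmin(vols))
        centroid = mesh.nodes[mesh.elems[bad]].mean(axis=0)
        raise GeometryError(
            f"inverted/degenerate element {bad} at centroid {centroid}"
        )
    q = mesh.element_quality()
    if q.min() < quality_floor:
        bad = int(np.argmin(q))
        centroid = mesh.nodes[mesh.elems[bad]].mean(axis=0)
        raise GeometryError(
            f"element quality {q.min():.2e} below floor {quality_floor:g} "
            f"at centroid {centroid}"
        )


def generate_mesh(geometry: SectorGeometry, refinement: str = "coarse") -> Mesh:
    """Graded tetrahedral mesh of the 30-degree sector, fully tagged.

    refinement selects the per-direction cell-count multiplier
    (REFINEMENT_SCALE); the grid is finest at the electrode-tissue
    interface and coarsens monotonically away from it.
    """
    if refinement not in REFINEMENT_SCALE:
        raise GeometryError(
            f"unknown refinement {refinement!r}; choose from "
            f"{sorted(REFINEMENT_SCALE)}"
        )
    s = REFINEMENT_SCALE[refinement]
    g = geometry.params
    return _build_structured(
        g,
        _radial_points(g, s),
        _theta_points_sector(g, s),
        _z_points(g, s),
        electrode_centers=(0.0,),
        theta_face_tags=(Boundary.SYMMETRY_ELECTRODE_PLANE, Boundary.GROUND_PLANE),
        zmin_is_symmetry=True,
        geometry=geometry,
    )


def tag_regions(mesh: Mesh, geometry: SectorGeometry) -> Mesh:
    """Re-derive all subdomain and boundary tags from the geometry.

    The structured generator tags while building; this re-tags from
    coordinates (e.g. after external modification) and verifies that
    every exterior facet carries exactly one tag.
    """
    g = geometry.params
    cent = mesh.cyl[mesh.elems].mean(axis=1)
    mesh.elem_tag = _classify(
        g, cent[:, 0], cent[:, 1], cent[:, 2], (0.0,)
    ).astype(np.int32)

    fc = mesh.cyl[mesh.facets].mean(axis=1)
    tol = 1e-9
    tags = np.full(len(mesh.facets), -1, dtype=np.int32)
    owner_tag = mesh.elem_tag[mesh.facet_elem]
    r, th, z = fc[:, 0], fc[:, 1], fc[:, 2]
    tags[np.abs(r - g.core_radius) < tol] = int(Boundary.AXIS_PLANE)
    tags[np.abs(r - g.outer_radius) < tol] = int(Boundary.OUTER_SURFACE)
    tags[np.abs(z - g.half_length) < tol] = int(Boundary.OUTER_SURFACE)
    tags[np.abs(th) < tol] = int(Boundary.SYMMETRY_ELECTRODE_PLANE)
    tags[np.abs(th - g.sector_angle) < tol] = int(Boundary.GROUND_PLANE)
    on_z0 = np.abs(z) < 1e-12
    tags[on_z0 & (owner_tag != int(Subdomain.ELECTRODE))] = int(
        Boundary.SYMMETRY_AXIAL_PLANE
    )
    tags[on_z0 & (owner_tag == int(Subdomain.ELECTRODE))] = int(
        Boundary.ELECTRODE_DRIVE_FACE
    )
    interior = tags < 0
    # Interior interfaces keep their constructed tag.
    tags[interior] = mesh.facet_tag[interior]
    if np.any(tags < 0):
        bad = int(np.flatnonzero(tags < 0)[0])
        raise GeometryError(
            f"untaggable facet at centroid (r, theta, z) = {tuple(fc[bad])}"
        )
    mesh.facet_tag = tags
    return mesh


# --- auxiliary meshes for verification ------------------------------------

def build_mirror_audit_mesh(params: DeviceGeometry,
                            refinement: str = "tiny") -> Mesh:
    """Double-width audit model: full electrode centered in a 60-deg span.

    Both angular faces are grounded midplanes, so the model contains a
    whole electrode width; its current must be twice the half-electrode
    sector current (audits the circumferential mirror factor).
    """
    params.validate()
    s = REFINEMENT_SCALE[refinement]
    g = params
    nc = lambda base: max(2, round(base * s))
    a = g.sector_angle
    th = _concat_segments([
        _graded(0.0, a - g.electrode_half_angle, nc(6), 1 / 1.45),
        _graded(a - g.electrode_half_angle, a + g.electrode_half_angle,
                nc(6), 1.0),
        _graded(a + g.electrode_half_angle, 2 * a, nc(6), 1.45),
    ])
    return _build_structured(
        g, _radial_points(g, s), th, _z_points(g, s),
        electrode_centers=(a,),
        theta_face_tags=(Boundary.GROUND_PLANE, Boundary.GROUND_PLANE),
        zmin_is_symmetry=True,
        geometry=None,
    )


def build_bipolar_audit_mesh(params: DeviceGeometry,
                             refinement: str = "tiny") -> Mesh:
    """Antisymmetric-pair audit model: two half electrodes 60 deg apart.

    Half electrodes sit at both angular faces (tagged as symmetry
    planes); driving them at +V and -V must reproduce the sector
    solution with a 0 V midplane at 30 deg (audits the bipolar-drive
    voltage convention).  Electrode node sets are distinguished by
    their theta coordinate.
    """
    params.validate()
    s = REFINEMENT_SCALE[refinement]
    g = params
    nc = lambda base: max(2, round(base * s))
    a = g.sector_angle
    th = _concat_segments([
        _graded(0.0, g.electrode_half_angle, nc(3), 1.0),
        _graded(g.electrode_half_angle, a, nc(6), 1.45),
        _graded(a, 2 * a - g.electrode_half_angle, nc(6), 1 / 1.45),
        _graded(2 * a - g.electrode_half_angle, 2 * a, nc(3), 1.0),
    ])
    return _build_structured(
        g, _radial_points(g, s), th, _z_points(g, s),
        electrode_centers=(0.0, 2 * a),
        theta_face_tags=(Boundary.SYMMETRY_ELECTRODE_PLANE,
                         Boundary.SYMMETRY_ELECTRODE_PLANE),
        zmin_is_symmetry=True,
        geometry=None,
    )


def build_box_mesh(
    lx: float, ly: float, lz: float,
    nx: int, ny: int, nz: int,
    subdomain: Subdomain = Subdomain.AIRWAY_WALL,
) -> Mesh:
    """Rectangular slab with Dirichlet tags on the two x faces.

    x = 0  -> ELECTRODE_DRIVE_FACE, x = lx -> GROUND_PLANE, all other
    faces insulated/adiabatic (SYMMETRY_AXIAL_PLANE).  Used by the
    closed-form verification suite.
    """
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    return _tensor_cartesian(xs, ys, zs, subdomain,
                             x0=Boundary.ELECTRODE_DRIVE_FACE,
                             x1=Boundary.GROUND_PLANE,
                             other=Boundary.SYMMETRY_AXIAL_PLANE)


def build_annulus_mesh(
    r_inner: float, r_outer: float, length: float, angle: float,
    nr: int, ntheta: int, nz: int,
    subdomain: Subdomain = Subdomain.AIRWAY_WALL,
) -> Mesh:
    """Cylindrical annulus sector with Dirichlet tags on the radial faces.

    r = r_inner -> ELECTRODE_DRIVE_FACE, r = r_outer -> GROUND_PLANE
    (doubling as OUTER_SURFACE semantics in thermal tests); angular and
    axial faces insulated.  The sector of opening `angle` and length
    `length` has closed-form resistance ln(b/a) / (angle * sigma * length).
    """
    rs = np.linspace(r_inner, r_outer, nr + 1)
    ts = np.linspace(0.0, angle, ntheta + 1)
    zs = np.linspace(0.0, length, nz + 1)
    R, TH, Z = np.meshgrid(rs, ts, zs, indexing="ij")
    xs3 = np.stack([R * np.cos(TH), R * np.sin(TH), Z], axis=-1).reshape(-1, 3)
    cyl = np.stack([R, TH, Z], axis=-1).reshape(-1, 3)
    return _assemble_tensor(
        xs3, cyl, nr, ntheta, nz, subdomain,
        x0=Boundary.ELECTRODE_DRIVE_FACE, x1=Boundary.GROUND_PLANE,
        other=Boundary.SYMMETRY_AXIAL_PLANE,
    )


def _tensor_cartesian(xs, ys, zs, subdomain, x0, x1, other) -> Mesh:
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    return _assemble_tensor(
        nodes, nodes.copy(), len(xs) - 1, len(ys) - 1, len(zs) - 1,
        subdomain, x0=x0, x1=x1, other=other,
    )


def _assemble_tensor(nodes, cyl, nx, ny, nz, subdomain, x0, x1, other) -> Mesh:
    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    corners = np.stack(
        [nid(I + (b & 1), J + ((b >> 1) & 1), K + ((b >> 2) & 1))
         for b in range(8)], axis=-1,
    ).reshape(-1, 8)
    elems = corners[:, _TETS].reshape(-1, 4)
    p = nodes[elems]
    vol6 = np.einsum("ij,ij->i", p[:, 1] - p[:, 0],
                     np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]))
    flip = vol6 < 0
    elems[flip, 2], elems[flip, 3] = elems[flip, 3], elems[flip, 2].copy()

    facets, ftags, fowner = [], [], []

    def cell_index(i, j, k):
        return (i * ny + j) * nz + k

    def emit(ci, cj, ck, face, tag):
        cell = cell_index(ci, cj, ck)
        cc = corners[cell]
        for tri, local_tet in _FACE_TRIS[face]:
            facets.append(cc[list(tri)])
            ftags.append(int(tag))
            fowner.append(cell * 6 + local_tet)

    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if i == 0:
                    emit(i, j, k, "x0", x0)
                if i == nx - 1:
                    emit(i, j, k, "x1", x1)
                if j == 0:
                    emit(i, j, k, "y0", other)
                if j == ny - 1:
                    emit(i, j, k, "y1", other)
                if k == 0:
                    emit(i, j, k, "z0", other)
                if k == nz - 1:
                    emit(i, j, k, "z1", other)

    mesh = Mesh(
        nodes=nodes,
        cyl=cyl,
        elems=elems,
        elem_tag=np.full(len(elems), int(subdomain), dtype=np.int32),
        facets=np.asarray(facets, dtype=np.int64),
        facet_tag=np.asarray(ftags, dtype=np.int32),
        facet_elem=np.asarray(fowner, dtype=np.int64),
        geometry=None,
    )
    _check_mesh(mesh)
    return mesh
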