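"""Sector geometry, meshing, tagging, and their invariants."""

import math

import numpy as np
import pytest

from airwayrf.geometry import (
    Boundary,
    DeviceGeometry,
    GeometryError,
    Subdomain,
    build_sector_geometry,
    generate_mesh,
    tag_regions,
)

EXTERIOR_TAGS = {
    Boundary.ELECTRODE_DRIVE_FACE, Boundary.GROUND_PLANE,
    Boundary.SYMMETRY_ELECTRODE_PLANE, Boundary.SYMMETRY_AXIAL_PLANE,
    Boundary.OUTER_SURFACE, Boundary.AXIS_PLANE,
}


class TestDeviceGeometry:
    def test_default_radii(self):
        g = DeviceGeometry()
        assert g.lumen_radius == pytest.approx(2.0e-3)
        assert g.wall_thickness == pytest.approx(0.4e-3)
        assert g.wall_outer_radius == pytest.approx(2.4e-3)

    def test_sector_angle_six_electrodes(self):
        assert DeviceGeometry().sector_angle == pytest.approx(math.radians(30))
        assert DeviceGeometry(n_electrodes=4).sector_angle == pytest.approx(
            math.radians(45))

    def test_similarity_scaling(self):
        g = DeviceGeometry().scaled(2.0)
        assert g.lumen_radius == pytest.approx(4.0e-3)
        assert g.wall_outer_radius == pytest.approx(4.8e-3)
        assert g.sector_angle == DeviceGeometry().sector_angle

    @pytest.mark.parametrize("bad", [
        dict(embed_depth=0.5e-3),          # would pierce the 0.4 mm wall
        dict(electrode_length=25e-3),      # longer than the model
        dict(outer_radius=2.0e-3),         # inside the wall
        dict(electrode_width=2.5e-3),      # wider than the sector
        dict(wall_thickness_fraction=-0.1),
    ])
    def test_invalid_geometry_rejected(self, bad):
        with pytest.raises(GeometryError):
            build_sector_geometry(DeviceGeometry(**bad))

    def test_analytic_volumes_scale_cubically(self):
        base = build_sector_geometry(DeviceGeometry())
        scaled = build_sector_geometry(DeviceGeometry().scaled(2.0))
        for sub in Subdomain:
            assert scaled.subdomain_volume(sub) == pytest.approx(
                8.0 * base.subdomain_volume(sub), rel=1e-12)


class TestMesh:
    def test_coarse_element_count_in_desk_range(self):
        mesh = generate_mesh(build_sector_geometry(DeviceGeometry()), "coarse")
        assert 5_000 <= mesh.num_elements <= 40_000

    def test_refinement_strictly_increases_count(self):
        geo = build_sector_geometry(DeviceGeometry())
        counts = [generate_mesh(geo, lvl).num_elements
                  for lvl in ("tiny", "coarse", "medium")]
        assert counts[0] < counts[1] < counts[2]

    def test_no_inverted_elements(self, sector_mesh):
        assert np.all(sector_mesh.element_volumes() > 0)

    def test_subdomain_volumes_partition_total(self, sector_mesh):
        total = sector_mesh.element_volumes().sum()
        parts = sum(sector_mesh.subdomain_volume(s) for s in Subdomain)
        assert parts == pytest.approx(total, rel=1e-10)

    def test_mesh_volumes_match_analytic_within_chord_error(self, sector_mesh):
        geo = sector_mesh.geometry
        for sub in Subdomain:
            assert sector_mesh.subdomain_volume(sub) == pytest.approx(
                geo.subdomain_volume(sub), rel=0.01)

    def test_mesh_similarity_scaling(self):
        base = generate_mesh(build_sector_geometry(DeviceGeometry()), "tiny")
        scaled = generate_mesh(
            build_sector_geometry(DeviceGeometry().scaled(2.0)), "tiny")
        assert scaled.element_volumes().sum() == pytest.approx(
            8.0 * base.element_volumes().sum(), rel=1e-9)

    def test_radial_grading_monotone_away_from_electrode(self, sector_mesh):
        g = sector_mesh.geometry.params
        rs = np.unique(np.round(sector_mesh.cyl[:, 0], 12))
        dr = np.diff(rs)
        outside = rs[:-1] >= g.wall_outer_radius
        assert np.all(np.diff(dr[outside]) > -1e-12)
        inside = rs[1:] <= g.electrode_back_radius
        assert np.all(np.diff(dr[inside]) < 1e-12)

    def test_unknown_refinement(self):
        with pytest.raises(GeometryError):
            generate_mesh(build_sector_geometry(DeviceGeometry()), "extreme")


class TestTags:
    def test_exterior_facets_fully_and_uniquely_tagged(self, sector_mesh):
        # Exterior faces are those appearing in exactly one tetrahedron.
        faces = {}
        for tet in sector_mesh.elems:
            for tri in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
                key = tuple(sorted(tet[list(tri)]))
                faces[key] = faces.get(key, 0) + 1
        exterior = {k for k, n in faces.items() if n == 1}
        tagged = {}
        for f, tag in zip(sector_mesh.facets, sector_mesh.facet_tag):
            if Boundary(tag) in EXTERIOR_TAGS:
                key = tuple(sorted(f))
                assert key not in tagged, "facet tagged twice"
                tagged[key] = tag
        assert set(tagged) == exterior

    def test_tagged_exterior_area_partitions_surface(self, sector_mesh):
        ext = np.isin(sector_mesh.facet_tag, [int(t) for t in EXTERIOR_TAGS])
        by_tag = sum(
            sector_mesh.facet_areas(sector_mesh.facets_with(t)).sum()
            for t in EXTERIOR_TAGS)
        assert by_tag == pytest.approx(
            sector_mesh.facet_areas(np.flatnonzero(ext)).sum(), rel=1e-12)

    def test_ground_plane_at_thirty_degrees(self, sector_mesh):
        nodes = sector_mesh.nodes_on(Boundary.GROUND_PLANE)
        theta = sector_mesh.cyl[nodes, 1]
        assert np.allclose(theta, math.radians(30))

    def test_outer_surface_on_outer_boundaries(self, sector_mesh):
        g = sector_mesh.geometry.params
        nodes = sector_mesh.nodes_on(Boundary.OUTER_SURFACE)
        r, z = sector_mesh.cyl[nodes, 0], sector_mesh.cyl[nodes, 2]
        assert np.all((np.abs(r - g.outer_radius) < 1e-12)
                      | (np.abs(z - g.half_length) < 1e-12))

    def test_drive_face_is_electrode_cross_section(self, sector_mesh):
        g = sector_mesh.geometry.params
        nodes = sector_mesh.nodes_on(Boundary.ELECTRODE_DRIVE_FACE)
        r, z = sector_mesh.cyl[nodes, 0], sector_mesh.cyl[nodes, 2]
        assert np.all(np.abs(z) < 1e-12)
        assert np.all(r >= g.electrode_back_radius - 1e-12)
        assert np.all(r <= g.electrode_tip_radius + 1e-12)

    def test_retagging_reproduces_constructed_tags(self, sector_mesh):
        import copy

        mesh = copy.deepcopy(sector_mesh)
        original = mesh.facet_tag.copy()
        tag_regions(mesh, mesh.geometry)
        assert np.array_equal(mesh.facet_tag, original)
        assert np.array_equal(mesh.elem_tag, sector_mesh.elem_tag)
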