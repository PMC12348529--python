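"""Cog-thread geometry: cuts, watertightness, sections, volume meshing."""

import math

import numpy as np
import pytest

from cogsim.threads import (
    COMMERCIAL_THREAD,
    COMPUTATIONAL_THREAD,
    LinearTetVolume,
    SurfaceMesh,
    ThreadSpec,
    build_filament,
    cut_barbs,
    min_cross_section_area,
    tetrahedralize,
)

R_MM = 0.3
FULL_AREA = math.pi * R_MM**2


def circular_segment_area(depth_mm: float) -> float:
    h = R_MM - depth_mm
    return R_MM**2 * math.acos(h / R_MM) - h * math.sqrt(2 * R_MM * depth_mm - depth_mm**2)


class TestThreadSpec:
    def test_presets_match_published_dimensions(self):
        assert COMMERCIAL_THREAD.length == 160.0
        assert COMMERCIAL_THREAD.diameter == 630.0
        assert COMPUTATIONAL_THREAD.length == 80.0
        assert COMPUTATIONAL_THREAD.diameter == 600.0
        for spec in (COMMERCIAL_THREAD, COMPUTATIONAL_THREAD):
            assert spec.cut_depth == 200.0
            assert spec.axial_spacing == 1600.0
            assert spec.n_directions == 4

    def test_cut_site_count_matches_spacing_arithmetic(self):
        # 80 mm / 1.6 mm spacing -> 50 sites per direction at zero phase
        assert COMPUTATIONAL_THREAD.n_cut_sites_per_direction == 50

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(cut_depth=300.0),          # cuts to the axis: severs the core
            dict(cut_depth=350.0),
            dict(barb_angle=0.0),
            dict(barb_angle=95.0),
            dict(length=1.0),               # shorter than the axial spacing
            dict(n_directions=0),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ThreadSpec(**kwargs)


class TestBuildFilament:
    def test_cylinder_volume_within_polygonal_tolerance(self):
        surf = build_filament(80.0, 600.0, 64)
        surf.check()
        assert surf.volume() == pytest.approx(FULL_AREA * 80.0, rel=0.01)

    def test_octagonal_prism_volume_exact(self):
        surf = build_filament(1.0, 1000.0, 8)
        # octagon inscribed in radius 0.5: area = 4 * r^2 * sin(pi/4) / ... = (8/2) r^2 sin(2pi/8)
        area = 4.0 * 0.5**2 * math.sin(math.pi / 4.0)
        assert surf.volume() == pytest.approx(area * 1.0, rel=1e-12)

    def test_degenerate_dimensions_rejected(self):
        with pytest.raises(ValueError):
            build_filament(0.0, 600.0)
        with pytest.raises(ValueError):
            build_filament(10.0, 600.0, circumferential_segments=4)


@pytest.fixture(scope="module")
def short_cut():
    spec = ThreadSpec(length=6.0)
    surf = cut_barbs(build_filament(6.0, 600.0, 64), spec)
    return spec, surf


class TestCutBarbs:

    def test_cut_surface_watertight(self, short_cut):
        _, surf = short_cut
        surf.check()
        assert surf.is_watertight()

    def test_cut_volume_strictly_below_uncut(self, short_cut):
        _, surf = short_cut
        assert surf.volume() < build_filament(6.0, 600.0, 64).volume()

    def test_volume_monotone_in_cut_depth(self):
        vols = []
        for depth in (100.0, 150.0, 200.0, 250.0):
            spec = ThreadSpec(length=6.0, cut_depth=depth)
            vols.append(cut_barbs(build_filament(6.0, 600.0, 48), spec).volume())
        assert all(a > b for a, b in zip(vols, vols[1:]))

    def test_right_angle_barb_is_mirror_symmetric(self):
        # at 90 deg both cut faces are normal to the axis: reflecting the
        # mesh about the cut-site plane maps the solid onto itself
        spec = ThreadSpec(length=6.0, barb_angle=90.0, axial_phase=1000.0)
        surf = cut_barbs(build_filament(6.0, 600.0, 32), spec)
        y0 = 1.0 + spec.leading_length_mm  # deepest station of the first cut
        prof = surf.profile
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        for dy in (0.01, 0.03):
            r_up = prof.radius_at(theta, y0 + dy)
            r_dn = prof.radius_at(theta, y0 - dy)
            assert np.allclose(r_up, r_dn, atol=1e-12)

    def test_rotational_symmetry_of_cut_pattern(self, short_cut):
        spec, surf = short_cut
        prof = surf.profile
        theta = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        step = 2 * np.pi / spec.n_directions
        r = prof.radius_at(theta, 1.7)
        r_rot = prof.radius_at(theta + step, 1.7)
        assert np.allclose(r, r_rot, atol=1e-12)


class TestMinCrossSection:
    def test_uncut_filament_recovers_circle_area(self):
        surf = build_filament(5.0, 600.0, 64)
        area, _ = min_cross_section_area(surf, axis_samples=50)
        assert area == pytest.approx(FULL_AREA, rel=0.01)

    def test_single_cut_matches_circular_segment_oracle(self):
        spec = ThreadSpec(length=5.0, n_directions=1)
        surf = cut_barbs(build_filament(5.0, 600.0, 64), spec)
        area, loc = min_cross_section_area(surf, axis_samples=120)
        expected = FULL_AREA - circular_segment_area(0.2)
        assert area == pytest.approx(expected, rel=0.01)

    def test_four_cuts_give_inscribed_square(self):
        # four simultaneous 200 um cuts at 90 deg leave a 0.2 x 0.2 mm core
        spec = ThreadSpec(length=5.0, n_directions=4)
        surf = cut_barbs(build_filament(5.0, 600.0, 96), spec)
        area, _ = min_cross_section_area(surf, axis_samples=120)
        assert area == pytest.approx(0.04, rel=0.01)

    def test_invariant_under_rigid_transformation(self):
        spec = ThreadSpec(length=5.0, n_directions=1)
        surf = cut_barbs(build_filament(5.0, 600.0, 48), spec)
        a0, _ = min_cross_section_area(surf, axis_samples=60)
        # rotate by an arbitrary rotation and translate
        axis = np.array([1.0, 2.0, 3.0])
        axis = axis / np.linalg.norm(axis)
        ang = 0.8
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + math.sin(ang) * K + (1 - math.cos(ang)) * K @ K
        moved = SurfaceMesh(surf.vertices @ R.T + [5.0, -2.0, 1.0], surf.triangles)
        a1, _ = min_cross_section_area(moved, axis_samples=60)
        assert a1 == pytest.approx(a0, rel=1e-3)

    def test_non_watertight_input_rejected(self):
        surf = build_filament(5.0, 600.0, 16)
        broken = SurfaceMesh(surf.vertices, surf.triangles[:-1])
        with pytest.raises(ValueError):
            min_cross_section_area(broken)


class TestTetrahedralize:
    def test_cylinder_volume_within_two_percent(self):
        surf = build_filament(5.0, 600.0, 32)
        mesh = tetrahedralize(surf, n_theta=24, n_rings=2, axial_edge=1.0)
        mesh.validate()
        assert mesh.volume() == pytest.approx(FULL_AREA * 5.0, rel=0.02)

    def test_grip_sets_present(self):
        mesh = tetrahedralize(build_filament(5.0, 600.0, 16), n_theta=12, axial_edge=1.0)
        assert len(mesh.node_sets["grip_bottom"]) > 0
        assert len(mesh.node_sets["grip_top"]) > 0
        assert len(mesh.facet_sets["grip_top"]) > 0

    def test_linear_order_returns_four_node_tets(self):
        out = tetrahedralize(
            build_filament(2.0, 600.0, 16), order="linear", n_theta=12, axial_edge=1.0
        )
        assert isinstance(out, LinearTetVolume)
        assert out.tets.shape[1] == 4

    def test_profile_free_surface_rejected(self):
        surf = build_filament(2.0, 600.0, 16)
        anonymous = SurfaceMesh(surf.vertices, surf.triangles)  # no profile
        with pytest.raises(ValueError, match="profile"):
            tetrahedralize(anonymous)

    def test_cut_thread_mesh_volume_matches_surface(self):
        spec = ThreadSpec(length=5.0)
        surf = cut_barbs(build_filament(5.0, 600.0, 48), spec)
        mesh = tetrahedralize(surf, n_theta=24, n_rings=2, axial_edge=0.5)
        mesh.validate()
        assert mesh.volume() == pytest.approx(surf.volume(), rel=0.03)
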