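"""Channel polyhedron, median structure, cylinder and cell-grid geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from porewater.geometry import (
    OUTSIDE,
    CellIndex,
    ChannelCylinder,
    DegenerateGeometryError,
    assign_cell,
    assign_cells,
    build_cylinder,
    build_polyhedron,
    find_median_frame,
    point_in_polyhedron,
    polyhedron_from_points,
)
from porewater.synthetic import SyntheticChannelSpec, generate_scaffold, simulate_waters

from conftest import make_frames
from oracles import point_in_hull_by_tetrahedra, volume_by_tetrahedra

UNIT_CUBE = np.array(
    [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0], [1, 0, 1], [0, 1, 1], [1, 1, 1]],
    dtype=float,
)


class TestPolyhedron:
    def test_unit_cube_volume(self):
        poly = polyhedron_from_points(UNIT_CUBE)
        assert poly.volume == pytest.approx(0.001, rel=1e-12)

    def test_tetrahedron_volume(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        poly = polyhedron_from_points(pts)
        assert poly.volume == pytest.approx((1 / 6) / 1000, rel=1e-12)

    def test_random_volume_against_monte_carlo(self, rng):
        pts = rng.uniform(0, 10, size=(15, 3))
        poly = polyhedron_from_points(pts)
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        samples = rng.uniform(lo, hi, size=(10**6, 3))
        box = np.prod(hi - lo) / 1000.0
        est = poly.contains(samples).mean() * box
        assert est == pytest.approx(poly.volume, rel=0.01)

    def test_volume_matches_tetra_decomposition(self, rng):
        for _ in range(5):
            pts = rng.uniform(-5, 5, size=(rng.integers(4, 20), 3))
            poly = polyhedron_from_points(pts)
            assert poly.volume == pytest.approx(volume_by_tetrahedra(poly), rel=1e-9)

    def test_interior_point_leaves_volume_unchanged(self, rng):
        pts = rng.uniform(0, 10, size=(12, 3))
        poly = polyhedron_from_points(pts)
        interior = pts.mean(axis=0)
        poly2 = polyhedron_from_points(np.vstack([pts, interior]))
        assert poly2.volume == pytest.approx(poly.volume, rel=1e-12)

    def test_too_few_points_names_corners(self):
        with pytest.raises(DegenerateGeometryError, match="R1"):
            polyhedron_from_points(np.eye(3), labels=["R1", "R2", "R3"])

    def test_coplanar_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [2, 3, 0]], dtype=float)
        with pytest.raises(DegenerateGeometryError):
            polyhedron_from_points(pts)

    def test_from_residue_centres_of_mass(self):
        # two-atom residues whose COM (equal masses) is the midpoint
        coords = np.array([[[0, 0, -1], [0, 0, 1], [2, 0, -1], [2, 0, 1],
                            [0, 2, -1], [0, 2, 1], [0, 0, 1], [0, 0, 3]]], dtype=float)
        frames = make_frames(
            coords,
            names=["C"] * 8,
            resids=[1, 1, 2, 2, 3, 3, 4, 4],
            resnames=["XXX"] * 8,
        )
        poly = build_polyhedron(frames, 0, [1, 2, 3, 4])
        # COMs: (0,0,0),(2,0,0),(0,2,0),(0,0,2) → tetrahedron volume 8/6 Å3
        assert poly.volume == pytest.approx((8 / 6) / 1000, rel=1e-12)


class TestPointInPolyhedron:
    def test_cube_centre_inside_boundary_and_outside(self):
        poly = polyhedron_from_points(UNIT_CUBE)
        assert point_in_polyhedron([0.5, 0.5, 0.5], poly)
        assert point_in_polyhedron([0.0, 0.5, 0.5], poly)  # boundary counts
        assert not point_in_polyhedron([2.0, 0.0, 0.0], poly)

    def test_matches_tetra_decomposition_oracle(self, rng):
        pts = rng.uniform(0, 10, size=(12, 3))
        poly = polyhedron_from_points(pts)
        probes = rng.uniform(-1, 11, size=(1000, 3))
        mine = poly.contains(probes, tol=1e-7)
        oracle = np.array([point_in_hull_by_tetrahedra(p, poly, tol=1e-7) for p in probes])
        assert (mine == oracle).all()


class TestMedianFrame:
    def test_frame_equal_to_mean_wins(self):
        base = np.zeros((1, 2, 3))
        coords = np.concatenate([base + 1, base - 1, base + 0.0, base + 2, base - 2])
        frames = make_frames(coords)
        # mean structure is 0; frame 2 matches it exactly
        assert find_median_frame(frames) == 2

    def test_tie_breaks_to_lowest_index(self):
        base = np.zeros((1, 2, 3))
        frames = make_frames(np.concatenate([base + 1, base - 1]))
        assert find_median_frame(frames) == 0

    def test_agrees_with_exhaustive_scan(self, rng):
        coords = rng.normal(size=(50, 7, 3))
        frames = make_frames(coords)
        mean = coords.mean(axis=0)
        rmsd = np.sqrt(((coords - mean) ** 2).sum(axis=(1, 2)) / 7)
        assert find_median_frame(frames) == int(np.argmin(rmsd))

    def test_window_is_respected_and_empty_window_errors(self, rng):
        coords = rng.normal(size=(20, 3, 3))
        frames = make_frames(coords)
        idx = find_median_frame(frames, window=(5, 15))
        assert 5 <= idx < 15
        with pytest.raises(ValueError):
            find_median_frame(frames, window=(4, 4))

    def test_invariant_under_rigid_translation(self, rng):
        coords = rng.normal(size=(30, 5, 3))
        frames = make_frames(coords)
        shifted = make_frames(coords + np.array([10.0, -3.0, 7.0]))
        assert find_median_frame(frames) == find_median_frame(shifted)


class TestCylinder:
    def test_axis_elongation_and_cap(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 2] = 27.27
        frames = make_frames(coords, names=["CA", "CA"], resids=[1, 2])
        cyl = build_cylinder(frames, 0, [1], [2])
        assert np.linalg.norm(cyl.axis_top - cyl.axis_base) == pytest.approx(30.0, abs=0.01)
        assert cyl.n_slices == 15

    def test_long_axis_capped_to_slice_coverage(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 2] = 50.0
        frames = make_frames(coords, names=["CA", "CA"], resids=[1, 2])
        cyl = build_cylinder(frames, 0, [1], [2])
        # sliced height never exceeds 15 × 2 Å, centred on the axis midpoint
        assert cyl.half_height == pytest.approx(15.0)
        assert np.allclose(cyl.centre, [0, 0, 25.0])

    def test_zero_length_axis_errors(self):
        coords = np.zeros((1, 2, 3))
        frames = make_frames(coords, names=["CA", "CA"], resids=[1, 2])
        with pytest.raises(ValueError, match="zero-length"):
            build_cylinder(frames, 0, [1], [2])

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="ring bound"):
            ChannelCylinder([0, 0, -15], [0, 0, 15], ring_bounds=(1.0, 3.5, 5.0))
        with pytest.raises(ValueError, match="divide"):
            ChannelCylinder([0, 0, -15], [0, 0, 15], segment_width=25.0)
        with pytest.raises(ValueError, match="coverage"):
            ChannelCylinder([0, 0, 0], [0, 0, 10], n_slices=15, slice_thickness=2.0)

    def test_scaffold_heights_match_dot_product_oracle(self):
        spec = SyntheticChannelSpec(n_waters=0, marker_heights=(-2.0, 5.0), n_frames=1)
        frames = generate_scaffold(spec)
        cyl = build_cylinder(frames, 0, spec.bottom_ids, spec.top_ids)
        for rid, h in zip(spec.marker_ids, spec.marker_heights):
            pos = frames.residue_com(rid, 0)
            expected = np.dot(pos - cyl.centre, cyl.axis_unit)
            assert cyl.heights(pos) == pytest.approx(expected, abs=1e-12)
            assert cyl.heights(pos) == pytest.approx(h, abs=1e-9)


class TestAssignCell:
    @pytest.fixture
    def cyl(self):
        return ChannelCylinder(axis_base=[0, 0, -15], axis_top=[0, 0, 15])

    def test_on_axis_point(self, cyl):
        assert assign_cell([0, 0, 0.5], cyl) == CellIndex(8, 1, 1)

    def test_ring_upper_edge_inclusive(self, cyl):
        # r = 4.0 lies in (3.5, 5.0] → ring 3; height −14 → slice 1
        assert assign_cell([4.0, 0.0, -14.0], cyl) == CellIndex(1, 3, 1)
        assert assign_cell([3.5, 0.0, -14.0], cyl) == CellIndex(1, 2, 1)

    def test_outside_radius_and_axially(self, cyl):
        assert assign_cell([10.0, 0, 0], cyl) == OUTSIDE
        assert assign_cell([0, 0, 15.5], cyl) == OUTSIDE

    def test_slice_boundaries_half_open_topmost_closed(self, cyl):
        assert assign_cell([0, 0, -13.0], cyl).slice == 2
        assert assign_cell([0, 0, 15.0], cyl).slice == 15

    def test_segment_of_azimuth(self, cyl):
        # axis along z → in-plane basis is (x, y); 45° falls in segment 2
        c = assign_cell([1.0, 1.0, 0.0], cyl)
        assert c.segment == 2

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.floats(-12, 12),
        st.floats(0, 11),
        st.floats(0, 360),
    )
    def test_partition_every_in_cylinder_point_has_one_cell(self, h, r, az):
        cyl = ChannelCylinder(axis_base=[0, 0, -15], axis_top=[0, 0, 15])
        p = [r * np.cos(np.radians(az)), r * np.sin(np.radians(az)), h]
        cell = assign_cell(p, cyl)
        if r <= 9.5:
            assert isinstance(cell, CellIndex)
            assert 1 <= cell.slice <= 15
            assert 1 <= cell.ring <= 4
            assert 1 <= cell.segment <= 12
        else:
            assert cell == OUTSIDE

    def test_cell_counts_sum_to_in_cylinder_total(self, rng):
        cyl = ChannelCylinder(axis_base=[0, 0, -15], axis_top=[0, 0, 15])
        pts = rng.uniform(-16, 16, size=(2000, 3))
        s, ring, seg, inside = assign_cells(pts, cyl)
        counts = np.zeros((15, 4, 12))
        np.add.at(counts, (s[inside] - 1, ring[inside] - 1, seg[inside] - 1), 1)
        assert counts.sum() == inside.sum()


def test_polyhedron_contained_in_cylinder():
    """Scaffold-channel containment: polyhedron waters are cylinder waters."""
    spec = SyntheticChannelSpec(n_waters=25, n_frames=50, seed=7)
    frames = simulate_waters(spec)
    cyl = build_cylinder(frames, 0, spec.bottom_ids, spec.top_ids)
    for t in range(0, frames.n_frames, 10):
        poly = build_polyhedron(frames, t, spec.corner_ids)
        pts = frames.water_oxygens(t)
        in_poly = poly.contains(pts)
        _, _, _, in_cyl = assign_cells(pts, cyl)
        assert (in_poly <= in_cyl).all()
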