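"""Void classification, periodic labeling, bubble statistics, and tracking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from voidscan import (
    AtomFrame,
    BoxVectors,
    DensityGrid,
    DetectionConfig,
    GridSpec,
    VoidMask,
    analyze_frame,
    analyze_trajectory,
    classify_voids,
    label_components,
    match_bubbles_across_frames,
    summarize_bubbles,
)
from voidscan import fixtures as fx

from oracles import erosion_void_oracle, label_oracle


def unit_spec(shape):
    return GridSpec(
        counts=tuple(shape),
        cell_lengths=(1.0, 1.0, 1.0),
        box_lengths=tuple(float(s) for s in shape),
    )


def density_grid(values):
    values = np.asarray(values, dtype=float)
    return DensityGrid(spec=unit_spec(values.shape), density=values, neighbor_cells=4)


class TestClassifyVoids:
    def test_empty_box_is_all_void(self):
        mask = classify_voids(density_grid(np.zeros((5, 5, 5))), 0.25)
        assert mask.mask.all()

    def test_uniform_water_has_no_voids(self):
        mask = classify_voids(density_grid(np.full((5, 5, 5), 1000.0)), 0.25)
        assert not mask.mask.any()

    def test_pocket_counted_exactly_and_cutoff_is_strict(self):
        values = np.full((10, 10, 10), 1000.0)
        values.ravel()[:50] = 0.0
        values[9, 9, 9] = 0.25  # exactly at cutoff -> not void
        mask = classify_voids(density_grid(values), 0.25)
        assert int(mask.mask.sum()) == 50


class TestLabelComponents:
    def test_wrap_adjacency_across_x_boundary(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[0, 0, 0] = mask[7, 0, 0] = True
        vm = VoidMask(unit_spec((8, 8, 8)), mask)
        _, n_periodic = label_components(vm, 26, periodic=True)
        _, n_open = label_components(vm, 26, periodic=False)
        assert (n_periodic, n_open) == (1, 2)

    def test_all_false_mask_has_zero_components(self):
        vm = VoidMask(unit_spec((4, 4, 4)), np.zeros((4, 4, 4), bool))
        labels, n = label_components(vm)
        assert n == 0 and not labels.any()

    def test_corner_sphere_eight_octants_merge_periodically(self):
        shape = (20, 20, 20)
        idx = np.indices(shape)
        centers = idx + 0.5
        delta = np.minimum(centers, 20.0 - centers)  # min-image dist to corner
        mask = (delta ** 2).sum(axis=0) < 36.0
        vm = VoidMask(unit_spec(shape), mask)
        _, n_periodic = label_components(vm, 26, periodic=True)
        _, n_open = label_components(vm, 26, periodic=False)
        assert n_periodic == 1
        assert n_open == 8

    def test_volume_additivity_labels_cover_mask(self, rng):
        mask = rng.uniform(size=(12, 12, 12)) < 0.3
        vm = VoidMask(unit_spec((12, 12, 12)), mask)
        labels, n = label_components(vm, 26, True)
        assert int((labels > 0).sum()) == int(mask.sum())
        assert set(np.unique(labels)) == set(range(n + 1)) or n == 0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        shape=st.tuples(*[st.integers(2, 8) for _ in range(3)]),
        p=st.floats(0.1, 0.7),
        connectivity=st.sampled_from([6, 26]),
        periodic=st.booleans(),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_matches_union_find_oracle(self, shape, p, connectivity, periodic, seed):
        mask = np.random.default_rng(seed).uniform(size=shape) < p
        vm = VoidMask(unit_spec(shape), mask)
        labels, n = label_components(vm, connectivity, periodic)
        exp_labels, exp_n = label_oracle(mask, connectivity, periodic)
        assert n == exp_n
        assert np.array_equal(labels, exp_labels)


class TestSummarizeBubbles:
    def test_min_volume_filter_is_strict(self):
        spec = unit_spec((20, 20, 20))
        labels = np.zeros((20, 20, 20), dtype=int)
        labels[2:6, 2:7, 2:7] = 1  # 4*5*5 = 100 voxels = 0.1 nm^3 exactly
        assert summarize_bubbles(labels, spec, 0.1) == []
        labels[6, 2, 2] = 1  # 101 voxels
        bubbles = summarize_bubbles(labels, spec, 0.1)
        assert len(bubbles) == 1
        assert bubbles[0].voxel_count == 101
        assert bubbles[0].volume == pytest.approx(0.101)

    def test_empty_labels_give_empty_list(self):
        assert summarize_bubbles(np.zeros((5, 5, 5), int), unit_spec((5, 5, 5)), 0.1) == []

    def test_cube_moments(self):
        spec = unit_spec((20, 20, 20))
        labels = np.zeros((20, 20, 20), dtype=int)
        labels[5:10, 5:10, 5:10] = 1  # 5^3 cube
        (b,) = summarize_bubbles(labels, spec, 0.1)
        assert b.volume == pytest.approx(0.125)
        # per-axis variance of {-2..2} is 2 -> rg = sqrt(6)
        assert b.radius_of_gyration == pytest.approx(np.sqrt(6.0), rel=1e-9)
        assert b.principal_extents[0] == pytest.approx(b.principal_extents[2])
        assert b.centroid == pytest.approx((7.5, 7.5, 7.5))

    def test_boundary_straddling_bubble_gets_interior_centroid(self):
        spec = unit_spec((20, 20, 20))
        labels = np.zeros((20, 20, 20), dtype=int)
        labels[:3, 5:10, 5:10] = 1
        labels[17:, 5:10, 5:10] = 1  # 6 planes wrapped across x boundary
        (b,) = summarize_bubbles(labels, spec, 0.1)
        # physical block spans x in [17, 23) -> centroid at x = 0 (mod 20)
        assert min(b.centroid[0], 20.0 - b.centroid[0]) == pytest.approx(0.0, abs=1e-9)
        assert b.centroid[1] == pytest.approx(7.5)
        # moments computed on the unwrapped block, not the split halves
        assert b.radius_of_gyration == pytest.approx(
            np.sqrt(35 / 12 + 2 + 2), rel=1e-9
        )


class TestAnalyzeFrame:
    def test_uniform_water_lattice_is_negative(self, water30):
        rep = analyze_frame(water30)
        assert not rep.bubble_present
        assert rep.bubbles == []
        assert rep.total_void_volume == 0.0

    def test_empty_cube_is_one_whole_box_bubble(self):
        box = BoxVectors((50, 0, 0), (0, 50, 0), (0, 0, 50))
        frame = AtomFrame(np.zeros((0, 3)), np.zeros(0), box)
        rep = analyze_frame(frame)
        assert rep.n_bubbles == 1
        assert rep.bubbles[0].volume == pytest.approx(125.0)
        assert rep.bubbles[0].voxel_count == 50 ** 3

    def test_carved_sphere_matches_erosion_oracle(self):
        frame = fx.carve_sphere(fx.water_lattice((40, 40, 40)), (20, 20, 20), 10.0)
        rep = analyze_frame(frame, keep_fields=True)
        assert rep.n_bubbles == 1
        from voidscan import make_grid, voxelize, wrap_to_brick

        grid = voxelize(wrap_to_brick(frame), make_grid(frame.box, 1.0))
        expected = erosion_void_oracle(grid.cell_mass, 4)
        assert np.array_equal(rep.labels > 0, expected)
        assert rep.bubbles[0].voxel_count == int(expected.sum())

    def test_monotone_carving(self):
        base = fx.water_lattice((40, 40, 40))
        volumes = []
        for radius in (6.0, 8.0, 10.0, 12.0):
            rep = analyze_frame(fx.carve_sphere(base, (20, 20, 20), radius))
            volumes.append(rep.total_void_volume)
        assert volumes == sorted(volumes)

    def test_every_reported_bubble_exceeds_min_volume(self):
        frame = fx.carve_sphere(fx.water_lattice((40, 40, 40)), (5, 35, 20), 9.0)
        config = DetectionConfig(min_bubble_volume=0.1)
        rep = analyze_frame(frame, config)
        for b in rep.bubbles:
            assert b.volume > config.min_bubble_volume


class TestTrajectoryAndTracking:
    def test_shrinking_bubble_monotone_to_zero(self):
        frames = fx.shrinking_bubble_trajectory(10, 12.0, (40, 40, 40), seed=7)
        reports = analyze_trajectory(frames, keep_fields=True)
        volumes = [r.total_void_volume for r in reports]
        assert all(a >= b for a, b in zip(volumes, volumes[1:]))
        assert not reports[-1].bubble_present
        assert volumes[-1] == 0.0
        assert reports[0].bubbles[0].voxel_count > 0
        tracks = match_bubbles_across_frames(reports)
        assert len(tracks) == 1
        frames_in_track = [f for f, _ in tracks[0]]
        assert frames_in_track == sorted(frames_in_track)

    def test_single_frame_matches_analyze_frame(self, water30):
        reports = analyze_trajectory([water30])
        assert len(reports) == 1
        assert reports[0].bubble_present == analyze_frame(water30).bubble_present

    def test_empty_sequence(self):
        assert analyze_trajectory([]) == []

    def test_identical_masks_match_to_self(self):
        frame = fx.carve_sphere(fx.water_lattice((40, 40, 40)), (20, 20, 20), 9.0)
        reports = analyze_trajectory([frame, frame], keep_fields=True)
        tracks = match_bubbles_across_frames(reports)
        assert len(tracks) == 1 and len(tracks[0]) == 2

    def test_vanishing_bubble_ends_track(self):
        carved = fx.carve_sphere(fx.water_lattice((40, 40, 40)), (20, 20, 20), 9.0)
        intact = fx.water_lattice((40, 40, 40))
        reports = analyze_trajectory([carved, intact, intact], keep_fields=True)
        tracks = match_bubbles_across_frames(reports)
        assert len(tracks) == 1
        assert [f for f, _ in tracks[0]] == [0]

    def test_merging_bubbles_continue_larger_overlap_track(self):
        base = fx.water_lattice((50, 50, 50))
        two = fx.carve_sphere(
            fx.carve_sphere(base, (15, 25, 25), 8.0), (35, 25, 25), 6.0
        )
        merged = fx.carve_sphere(base, (20, 25, 25), 14.0)
        reports = analyze_trajectory([two, merged], keep_fields=True)
        assert reports[0].n_bubbles == 2
        assert reports[1].n_bubbles == 1
        tracks = match_bubbles_across_frames(reports)
        assert len(tracks) == 2
        continued = [t for t in tracks if len(t) == 2]
        ended = [t for t in tracks if len(t) == 1]
        assert len(continued) == 1 and len(ended) == 1
        # the larger-overlap predecessor (the bigger carved sphere) continues
        big_label = reports[0].bubbles[0].label
        assert continued[0][0] == (0, big_label)

    def test_tracking_requires_kept_fields(self, water30):
        reports = analyze_trajectory([water30])
        with pytest.raises(ValueError, match="keep_fields"):
            match_bubbles_across_frames(reports)


class TestTranslationInvariance:
    def test_wrap_shift_changes_volume_at_most_by_surface(self, rng):
        from oracles import surface_voxel_count

        frame = fx.carve_sphere(fx.water_lattice((40, 40, 40)), (20, 20, 20), 10.0)
        ref = analyze_frame(frame, keep_fields=True)
        ref_count = ref.bubbles[0].voxel_count
        surface = surface_voxel_count(ref.labels > 0)
        for _ in range(3):
            shift = rng.uniform(-40, 40, size=3)
            moved = AtomFrame(
                frame.coordinates + shift, frame.masses, frame.box
            )
            rep = analyze_frame(moved)
            assert rep.n_bubbles == 1
            assert abs(rep.bubbles[0].voxel_count - ref_count) <= surface
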