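"""Nucleus detection, greedy radius-N linking, gradient maps, registration."""

from itertools import permutations

import numpy as np
import pytest

import nichemetry as nm
from nichemetry.phantom import ImagingConfig, MotionSpec, place_cells, simulate_timelapse
from nichemetry.tracking import (
    Track,
    TrackingConfig,
    apply_shift,
    detect_nuclei,
    estimate_shift,
    kernel_to_um,
    link_tracks,
    render_gradient_map,
    summarize_motility,
    z_partition,
)

UM = 1.66


class TestZPartition:
    def test_default_split_covers_stack(self, rng):
        stack = rng.uniform(size=(12, 8, 8))
        zp = z_partition(stack)
        assert zp.bottom_slices == 7 and zp.top_slices == 5
        assert np.array_equal(zp.bottom, stack[:7].max(axis=0))
        assert np.array_equal(zp.top, stack[7:].max(axis=0))

    def test_mean_projection(self, rng):
        stack = rng.uniform(size=(12, 4, 4))
        zp = z_partition(stack, projection="mean")
        assert np.allclose(zp.bottom, stack[:7].mean(axis=0))

    def test_invalid_split_rejected(self, rng):
        with pytest.raises(ValueError):
            z_partition(rng.uniform(size=(12, 4, 4)), bottom_slices=12)
        with pytest.raises(ValueError):
            z_partition(rng.uniform(size=(4, 4)))


class TestDetect:
    def test_blank_and_constant_images(self):
        assert detect_nuclei(np.zeros((32, 32))).shape == (0, 2)
        assert detect_nuclei(np.full((32, 32), 7.0)).shape == (0, 2)

    def _projection_with_cells(self, model, cells):
        imaging = ImagingConfig(fov=(210.0, 520.0))
        from nichemetry.phantom import render_nuclei_stack

        stack = render_nuclei_stack(model, cells, imaging, rng=None)
        return z_partition(stack).bottom

    def test_single_nucleus_centroid_within_one_pixel(self, default_model):
        from nichemetry.phantom import SyntheticCell

        cell = SyntheticCell(x=100.0, y=30.0, z=8.0)
        proj = self._projection_with_cells(default_model, [cell])
        dets = detect_nuclei(proj)
        assert len(dets) == 1
        assert np.hypot(dets[0, 0] - 100.0 / UM, dets[0, 1] - 30.0 / UM) < 1.0

    def test_two_nuclei_resolved(self, default_model):
        from nichemetry.phantom import SyntheticCell

        cells = [
            SyntheticCell(x=80.0, y=30.0, z=8.0),
            SyntheticCell(x=80.0 + 30 * UM, y=30.0, z=8.0),
        ]
        proj = self._projection_with_cells(default_model, cells)
        dets = detect_nuclei(proj)
        assert len(dets) == 2
        for c in cells:
            d = np.hypot(dets[:, 0] - c.x / UM, dets[:, 1] - c.y / UM).min()
            assert d < 1.0


def _as_detections(paths: list[list[tuple[float, float] | None]]) -> list[np.ndarray]:
    """paths[i][t] is cell i's position at time t (None = absent)."""
    T = len(paths[0])
    return [
        np.array([p[t] for p in paths if p[t] is not None], dtype=float).reshape(-1, 2)
        for t in range(T)
    ]


class TestLinking:
    def test_stationary_cell_single_track_zero_distance(self):
        dets = _as_detections([[(5.0, 5.0)] * 6])
        tracks = link_tracks(dets, TrackingConfig())
        assert len(tracks) == 1
        assert tracks[0].total_distance_px == 0.0
        assert tracks[0].n_points == 6

    def test_constant_step_total_distance(self):
        # 3 px per frame for 6 frames: 15 px = 24.9 µm at 1.66 µm/px
        dets = _as_detections([[(10.0 + 3 * t, 20.0) for t in range(6)]])
        (track,) = link_tracks(dets, TrackingConfig())
        assert track.total_distance_px == pytest.approx(15.0)
        assert track.total_distance_um == pytest.approx(24.9)

    def test_jump_beyond_N_terminates_and_short_tracks_drop(self):
        # jump of N+1 between t=2 and t=3 splits the trajectory into a
        # 3-point head and a 3-point remnant; both fall below 5 points
        path = [(10.0, 10.0), (12.0, 10.0), (14.0, 10.0),
                (35.0, 10.0), (37.0, 10.0), (39.0, 10.0)]
        tracks = link_tracks(_as_detections([path]), TrackingConfig(N=10))
        assert tracks == []

    def test_second_pass_recovers_late_appearance(self):
        late = [None, (50.0, 50.0), (52.0, 50.0), (54.0, 50.0), (56.0, 50.0), (58.0, 50.0)]
        always = [(5.0, 5.0)] * 6
        tracks = link_tracks(_as_detections([always, late]), TrackingConfig())
        assert len(tracks) == 2
        by_pass = {t.pass_index for t in tracks}
        assert by_pass == {1, 2}
        second = next(t for t in tracks if t.pass_index == 2)
        assert second.t0 == 1 and second.n_points == 5

    def test_five_point_track_kept_four_point_dropped(self):
        five = [(0.0, 0.0), (1.0, 0.0), (2.0, 0.0), (3.0, 0.0), (4.0, 0.0), None]
        four = [(40.0, 40.0), (41.0, 40.0), (42.0, 40.0), (43.0, 40.0), None, None]
        tracks = link_tracks(_as_detections([five, four]), TrackingConfig())
        assert len(tracks) == 1
        assert tracks[0].n_points == 5

    def test_detections_claimed_exclusively(self, rng):
        dets = [rng.uniform(0, 100, size=(12, 2)) for _ in range(6)]
        tracks = link_tracks(dets, TrackingConfig(min_track_points=2))
        for t in range(6):
            used = [
                tuple(np.round([x, y], 9))
                for tr in tracks
                for tt, x, y in tr.positions
                if tt == t
            ]
            assert len(used) == len(set(used))
        for tr in tracks:
            assert (tr.step_lengths_px <= 10.0 + 1e-9).all()

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError):
            link_tracks([np.zeros((1, 2))], TrackingConfig())


def _brute_force_total(dets: list[np.ndarray], N: float) -> float:
    """Minimum summed step length over all timepoint-wise full matchings.

    Valid only when every cell persists and matchings are complete (equal
    counts per frame); used on well-separated configurations where the
    optimum is unique.
    """
    n = len(dets[0])
    best = {tuple(range(n)): 0.0}  # assignment of track i -> detection index
    for t in range(1, len(dets)):
        new_best: dict[tuple, float] = {}
        for assign, cost in best.items():
            prev = dets[t - 1][list(assign)]
            for perm in permutations(range(n)):
                cur = dets[t][list(perm)]
                steps = np.hypot(*(cur - prev).T)
                if (steps > N).any():
                    continue
                c = cost + steps.sum()
                if c < new_best.get(perm, np.inf):
                    new_best[perm] = c
        best = new_best
    return min(best.values())


class TestGreedyVsExhaustive:
    def test_well_separated_cells_match_optimal_assignment(self, rng):
        # cells further than 2N apart at all times: greedy = global optimum
        N = 10.0
        starts = np.array([[20.0, 20.0], [80.0, 20.0], [20.0, 80.0], [90.0, 90.0]])
        paths = [starts.copy()]
        for _ in range(5):
            paths.append(paths[-1] + rng.uniform(-4, 4, size=starts.shape))
        dets = [p.copy() for p in paths]
        # shuffle detection order per frame so linking has to work for it
        for t in range(1, 6):
            dets[t] = dets[t][rng.permutation(len(starts))]
        tracks = link_tracks(dets, TrackingConfig(N=N))
        assert len(tracks) == len(starts)
        greedy_total = sum(t.total_distance_px for t in tracks)
        assert greedy_total == pytest.approx(_brute_force_total(dets, N), abs=1e-9)


class TestKernelConversion:
    @pytest.mark.parametrize(
        "N,px,expected", [(10, 1.66, 16.6), (1, 1.0, 1.0), (2, 1.66, 3.32)]
    )
    def test_kernel_to_um(self, N, px, expected):
        assert kernel_to_um(N, px) == pytest.approx(expected)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            kernel_to_um(0, 1.66)


def _track_at(positions, pixel_size=1.66, pass_index=1):
    return Track(id=0, positions=positions, pass_index=pass_index, pixel_size=pixel_size)


class TestGradientMap:
    def test_no_tracks_zero_field(self):
        gm = render_gradient_map([], (32, 32))
        assert gm.field.max() == 0.0

    def test_single_track_peak_is_clipped_distance(self):
        tr = _track_at([(t, 10.0 + 3 * t, 10.0) for t in range(6)])
        gm = render_gradient_map([tr], (64, 64), display_max=30.0)
        assert gm.field.max() == pytest.approx(min(tr.total_distance_um, 30.0))
        tr_fast = _track_at([(t, 10.0 + 9 * t, 10.0) for t in range(6)])
        gm2 = render_gradient_map([tr_fast], (64, 64), display_max=30.0)
        assert gm2.field.max() == pytest.approx(30.0)

    def test_overlapping_tracks_combine_by_max(self):
        slow = _track_at([(t, 20.0, 20.0 + t) for t in range(6)])
        fast = _track_at([(t, 20.0 + 4 * t, 20.0) for t in range(6)])
        gm = render_gradient_map([slow, fast], (64, 64), display_max=30.0)
        assert gm.field.max() == pytest.approx(
            min(fast.total_distance_um, 30.0)
        )
        assert gm.field[20, 20] >= slow.total_distance_um - 1e-9

    def test_field_zero_far_from_tracks(self):
        tr = _track_at([(0, 5.0, 5.0), (1, 5.0, 5.0)] + [(t, 5.0, 5.0) for t in range(2, 6)])
        gm = render_gradient_map([tr], (64, 64), kernel_sigma_px=3.0)
        assert gm.field[60, 60] == 0.0


class TestRegistration:
    def test_injected_shift_recovered_and_undone(self, default_model):
        mask = nm.rasterize(default_model, 1.66, fov=(210.0, 520.0))
        ref = mask.wall_coverage.astype(float)
        shifted = np.roll(ref, (4, -3), axis=(0, 1))
        dy, dx = estimate_shift(shifted, ref)
        assert (dy, dx) == (4, -3)
        restored = apply_shift(shifted, (-dy, -dx))
        inner = (slice(10, -10), slice(10, -10))
        assert np.allclose(restored[inner], ref[inner])


class TestSummarize:
    def test_stationary_niche_tracks(self, default_model, unit1_mask):
        # a pixel on the niche band of the first wall set
        tr = _track_at([(t, 30.0, 2.0) for t in range(6)])
        tr.partition = "bottom"
        out = summarize_motility([tr], default_model, unit1_mask)
        row = out.iloc[0]
        assert row.region == 20.0
        assert row.mean_total_um == 0.0
        assert row.niche_fraction == 1.0

    def test_track_outside_sets_is_control(self, default_model, unit1_mask):
        # y = 62 µm sits in the inter-set gap
        tr = _track_at([(t, 30.0, 62.0 / 1.66) for t in range(6)])
        out = summarize_motility([tr], default_model, unit1_mask)
        assert out.iloc[0].region == "control"

    def test_empty_tracks_give_empty_table(self, default_model, unit1_mask):
        out = summarize_motility([], default_model, unit1_mask)
        assert len(out) == 0

    def test_region_dependent_motility_ordering(self, default_model, unit1_imaging, unit1_mask):
        # generate slow cells between 20 µm walls and fast ones between 55 µm
        # walls; the recovered mean distances must preserve that ordering
        rng = np.random.default_rng(31)
        cells = place_cells(default_model, 50, 0.0, rng=rng)
        motion = MotionSpec(step_scale={20.0: 1.0, 25.0: 3.0, 35.0: 3.0, 55.0: 8.0})
        res = simulate_timelapse(default_model, cells, motion, unit1_imaging, rng=rng)
        tracks = []
        for part in ("bottom", "top"):
            dets = []
            for s in res.stacks:
                zp = z_partition(s)
                dets.append(detect_nuclei(zp.bottom if part == "bottom" else zp.top))
            for tr in link_tracks(dets, TrackingConfig()):
                tr.partition = part
                tracks.append(tr)
        out = summarize_motility(tracks, default_model, unit1_mask)
        pooled = out.groupby("region").apply(
            lambda g: (g.mean_total_um * g.n_tracks).sum() / g.n_tracks.sum(),
            include_groups=False,
        )
        assert pooled[20.0] < pooled[55.0]
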