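"""Synthetic phantom: cell placement, rendering, and time-lapse motion."""

import numpy as np
import pytest

import nichemetry as nm
from nichemetry.phantom import (
    ImagingConfig,
    MotionSpec,
    PlacementError,
    SyntheticCell,
    _in_material,
    place_cells,
    render_nuclei_stack,
    render_stack,
    simulate_timelapse,
)


def _distance_to_wall(model, y):
    return min(abs(y - w.y) for w in model.walls)


class TestPlacement:
    def test_same_seed_identical(self, default_model):
        a = place_cells(default_model, 40, 0.3, rng=np.random.default_rng(5))
        b = place_cells(default_model, 40, 0.3, rng=np.random.default_rng(5))
        assert a == b

    def test_full_bias_puts_all_centers_in_niche_zones(self, default_model):
        cells = place_cells(default_model, 60, 1.0, rng=np.random.default_rng(1))
        d = default_model.params.niche_depth
        for c in cells:
            assert _distance_to_wall(default_model, c.y) <= d
            assert c.contact

    def test_unbiased_occupancy_matches_binomial_oracle(self, default_model):
        # center-based occupancy: uniform centers in [t/2, sep - t/2] land
        # within the niche band with probability 2*(d - t/2)/(sep - t),
        # which is the isotropic ratio up to the line-thickness margin
        p = default_model.params
        cells = place_cells(default_model, 400, 0.0, rng=np.random.default_rng(2))
        per_class: dict[float, list[bool]] = {}
        for c in cells:
            ch = next(x for x in default_model.chambers if x.contains(c.x, c.y))
            per_class.setdefault(ch.wall_separation, []).append(
                _distance_to_wall(default_model, c.y) <= p.niche_depth
            )
        for sep, flags in per_class.items():
            v = np.array(flags)
            p_exact = 2 * (p.niche_depth - p.line_thickness / 2) / (sep - p.line_thickness)
            sigma = np.sqrt(p_exact * (1 - p_exact) / len(v))
            assert abs(v.mean() - p_exact) <= 3 * sigma
            assert abs(p_exact - nm.isotropic_niche_ratio(sep)) < 0.06

    def test_centers_avoid_material_and_respect_separation(self, default_model):
        cells = place_cells(default_model, 100, 0.5, rng=np.random.default_rng(3))
        xs = np.array([c.x for c in cells])
        ys = np.array([c.y for c in cells])
        assert not _in_material(default_model, xs, ys).any()
        pts = np.array([[c.x, c.y, c.z] for c in cells])
        d2 = ((pts[:, None] - pts[None]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        assert d2.min() >= 8.0**2 - 1e-9

    def test_overfull_region_raises(self, mini_model):
        with pytest.raises(PlacementError):
            place_cells(mini_model, 400, 0.0, rng=np.random.default_rng(0), max_tries=100)

    def test_bad_bias_rejected(self, mini_model):
        with pytest.raises(ValueError):
            place_cells(mini_model, 1, 1.5, rng=np.random.default_rng(0))


class TestRendering:
    @pytest.fixture()
    def small_imaging(self):
        return ImagingConfig(fov=(210.0, 60.0))

    def test_rendering_is_linear_in_sources(self, default_model, endmembers_405, small_imaging):
        rng = np.random.default_rng(4)
        cells = place_cells(default_model, 12, 0.0, rng=rng)
        a, b = cells[:6], cells[6:]
        s_ab, _ = render_stack(default_model, a + b, endmembers_405, small_imaging, rng=None)
        s_a, _ = render_stack(default_model, a, endmembers_405, small_imaging, rng=None)
        s_b, _ = render_stack(default_model, b, endmembers_405, small_imaging, rng=None)
        s_0, _ = render_stack(default_model, [], endmembers_405, small_imaging, rng=None)
        assert np.allclose(
            s_ab.data + s_0.data, s_a.data + s_b.data, rtol=1e-5, atol=1e-3
        )

    def test_empty_scene_is_scaffold_plus_background(self, default_model, endmembers_405, small_imaging):
        stack, truth = render_stack(default_model, [], endmembers_405, small_imaging, rng=None)
        assert truth["nuclei"].max() == 0 and truth["cytoplasm"].max() == 0
        # off-wall voxel spectrum is exactly the background endmember shape
        mask = nm.rasterize(default_model, small_imaging.pixel_size, fov=small_imaging.fov)
        free = np.argwhere((mask.wall_coverage == 0))
        j, i = free[len(free) // 2]
        spec = stack.data[0, :, j, i]
        expected = truth["background"][0, j, i] * endmembers_405["background"].weights
        assert np.allclose(spec, expected, rtol=1e-5)

    def test_single_cell_support(self, default_model, endmembers_405, small_imaging):
        cell = SyntheticCell(x=100.0, y=30.0, z=12.0)
        stack, truth = render_stack(default_model, [cell], endmembers_405, small_imaging, rng=None)
        nuc = truth["nuclei"]
        assert nuc.sum() > 0
        # no nuclei signal farther than the cell radius from the center
        zc, yc, xc = np.nonzero(nuc)
        ys = (yc + 0.5) * small_imaging.pixel_size
        xs = (xc + 0.5) * small_imaging.pixel_size
        r = np.hypot(xs - cell.x, ys - cell.y)
        assert r.max() <= cell.nucleus_diameter / 2 + small_imaging.pixel_size

    def test_deposited_mass_matches_sphere_volume(self, default_model, endmembers_405, small_imaging):
        cell = SyntheticCell(x=100.0, y=30.0, z=12.0)
        _, truth = render_stack(default_model, [cell], endmembers_405, small_imaging, rng=None)
        voxel = small_imaging.pixel_size**2 * small_imaging.z_step
        vol = truth["nuclei"].sum() / nm.DEFAULT_BRIGHTNESS["nuclei"] * voxel
        sphere = 4 / 3 * np.pi * (cell.nucleus_diameter / 2) ** 3
        # center-sampled in XY, exact slab integration in Z
        assert vol == pytest.approx(sphere, rel=0.08)

    def test_same_seed_bit_identical(self, default_model, endmembers_405, small_imaging):
        cells = place_cells(default_model, 5, 0.0, rng=np.random.default_rng(6))
        s1, _ = render_stack(default_model, cells, endmembers_405, small_imaging, rng=7)
        s2, _ = render_stack(default_model, cells, endmembers_405, small_imaging, rng=7)
        assert np.array_equal(s1.data, s2.data)

    def test_quench_scales_scaffold(self, default_model, endmembers_405, small_imaging):
        _, t0 = render_stack(default_model, [], endmembers_405, small_imaging,
                             quench_time=0.0, rng=None)
        _, t150 = render_stack(default_model, [], endmembers_405, small_imaging,
                               quench_time=150.0, rng=None)
        ratio = t150["scaffold"].sum() / t0["scaffold"].sum()
        assert ratio == pytest.approx(0.22, rel=1e-6)

    def test_wrong_spectral_grid_rejected(self, default_model, small_imaging):
        ems488 = nm.default_endmembers(nm.LAMBDA_488)
        with pytest.raises(ValueError, match="channel"):
            render_stack(default_model, [], ems488, small_imaging)

    def test_missing_endmember_rejected(self, default_model, endmembers_405, small_imaging):
        incomplete = {k: v for k, v in endmembers_405.items() if k != "nuclei"}
        with pytest.raises(ValueError, match="endmember set"):
            render_stack(default_model, [], incomplete, small_imaging)


class TestMotion:
    def test_zero_step_means_zero_distance(self, default_model, unit1_imaging):
        cells = place_cells(default_model, 10, 0.0, rng=np.random.default_rng(8))
        res = simulate_timelapse(
            default_model, cells, MotionSpec(step_scale=0.0), unit1_imaging,
            rng=np.random.default_rng(8), render=False,
        )
        assert (res.total_distances() == 0).all()

    def test_free_walk_mean_displacement_equals_step_scale(self, default_model, unit1_imaging):
        # fixed step length + uniform direction: per-interval displacement is
        # exactly the step scale when nothing blocks
        cells = place_cells(default_model, 40, 0.0, rng=np.random.default_rng(9))
        s = 3.0
        res = simulate_timelapse(
            default_model, cells, MotionSpec(step_scale=s, wall_blocking=False),
            unit1_imaging, rng=np.random.default_rng(9), render=False,
        )
        tr = res.tracks.sort_values(["cell", "t"])
        steps = []
        for _, g in tr.groupby("cell"):
            steps.extend(np.hypot(np.diff(g.x_um), np.diff(g.y_um)))
        steps = np.array(steps)
        inside = steps > 0  # boundary-clamped attempts may stall
        assert steps[inside].mean() == pytest.approx(s, rel=1e-9)
        assert inside.mean() > 0.95

    def test_confinement_truncates_net_displacement(self, default_model, unit1_imaging):
        # rejected steps are redrawn, so the path length stays at 5 steps;
        # confinement shows in the net start-to-end displacement, which the
        # chamber walls cap well below the free-walk value
        rng = np.random.default_rng(10)
        cells = [c for c in place_cells(default_model, 80, 0.0, rng=rng)
                 if next(ch for ch in default_model.chambers if ch.contains(c.x, c.y)).wall_separation == 20.0]
        assert len(cells) >= 5

        def net(res):
            out = []
            for _, g in res.tracks.sort_values("t").groupby("cell"):
                out.append(np.hypot(g.x_um.iloc[-1] - g.x_um.iloc[0],
                                    g.y_um.iloc[-1] - g.y_um.iloc[0]))
            return np.mean(out)

        spec_free = MotionSpec(step_scale=12.0, wall_blocking=False)
        spec_conf = MotionSpec(step_scale=12.0, wall_blocking=True)
        free = simulate_timelapse(default_model, cells, spec_free, unit1_imaging,
                                  rng=np.random.default_rng(11), render=False)
        conf = simulate_timelapse(default_model, cells, spec_conf, unit1_imaging,
                                  rng=np.random.default_rng(11), render=False)
        assert net(conf) < 0.8 * net(free)

    def test_positions_never_on_material(self, default_model, unit1_imaging):
        cells = place_cells(default_model, 30, 0.5, rng=np.random.default_rng(12))
        res = simulate_timelapse(default_model, cells, MotionSpec(step_scale=8.0),
                                 unit1_imaging, rng=np.random.default_rng(12), render=False)
        hit = _in_material(default_model, res.tracks.x_um.to_numpy(),
                           res.tracks.y_um.to_numpy())
        assert not hit.any()

    def test_region_dependent_step_scale(self, default_model):
        spec = MotionSpec(step_scale={20.0: 1.0, 55.0: 6.0, "control": 0.0})
        assert spec.scale_at(default_model, 10.0) == 1.0       # inside set 0
        assert spec.scale_at(default_model, 500.0) == 6.0      # inside set 3
        assert spec.scale_at(default_model, 62.0) == 0.0       # inter-set gap

    def test_rendered_timelapse_shapes(self, default_model, unit1_imaging):
        cells = place_cells(default_model, 5, 0.0, rng=np.random.default_rng(13))
        res = simulate_timelapse(default_model, cells, MotionSpec(), unit1_imaging,
                                 rng=np.random.default_rng(13))
        assert len(res.stacks) == 6
        for s in res.stacks:
            assert s.shape == (12, 313, 127)
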