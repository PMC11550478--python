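"""PIV displacement recovery, validity handling and radial aggregation."""

import dataclasses

import numpy as np
import pytest

from lumenflow import (
    VelocityField,
    arrow_map,
    generate_scene,
    heatmap_accumulate,
    mean_radial_series,
    piv_pair,
    preset,
    radial_project,
    true_velocity_field,
)

PX, DT = 0.1, 36.0


def textured_frame(rng, shape=(128, 128)):
    """Smooth random texture rich enough for every window to lock on."""
    from scipy.ndimage import gaussian_filter

    return gaussian_filter(rng.random(shape), 1.5) * 1000.0


def make_field(rng, shape=(5, 5), invalid=()):
    gx, gy = np.meshgrid(np.arange(shape[1]) * 16 + 15.5, np.arange(shape[0]) * 16 + 15.5)
    u = rng.normal(0, 2, shape)
    v = rng.normal(0, 2, shape)
    valid = np.ones(shape, bool)
    for ij in invalid:
        valid[ij] = False
    u = np.where(valid, u, np.nan)
    v = np.where(valid, v, np.nan)
    return VelocityField(
        x=gx, y=gy, u=u, v=v, valid=valid,
        peak_ratio=np.where(valid, 2.0, np.nan), window_px=32, overlap_px=16,
    )


class TestPivPair:
    def test_identity_pair_reports_zero(self, rng):
        a = textured_frame(rng)
        f = piv_pair(a, a, subpixel="none")
        assert f.n_valid == f.u.size
        assert np.all(f.u[f.valid] == 0) and np.all(f.v[f.valid] == 0)

    def test_integer_shift_exact_on_interior_windows(self, rng):
        a = textured_frame(rng)
        b = np.roll(a, shift=(-2, 3), axis=(0, 1))  # content moves +3 x, -2 y
        f = piv_pair(a, b, subpixel="none")
        inner_valid = f.valid[1:-1, 1:-1]
        assert inner_valid.all()
        assert np.all(f.u[1:-1, 1:-1][inner_valid] == 3)
        assert np.all(f.v[1:-1, 1:-1][inner_valid] == -2)

    @pytest.mark.parametrize("shift_px", [0.1, 0.3, 0.5])
    def test_subpixel_shift_recovered_within_tenth_pixel(self, shift_px):
        p = dataclasses.replace(
            preset("translation_test"),
            flow_params={"velocity_um_s": (shift_px * PX / DT, 0.0)},
            seed=21,
        )
        stack, _ = generate_scene(p)
        f = piv_pair(stack.frame(0, 0), stack.frame(1, 0), subpixel="gauss3")
        err = f.u[f.valid] - shift_px
        assert np.sqrt(np.mean(err**2)) <= 0.1

    def test_pure_noise_mostly_invalidated(self):
        rng = np.random.default_rng(99)
        a = rng.normal(100, 10, (160, 160))
        b = rng.normal(100, 10, (160, 160))
        f = piv_pair(a, b)
        assert 1 - f.n_valid / f.u.size >= 0.8

    def test_flat_window_invalid_not_fabricated(self, rng):
        a = textured_frame(rng)
        a[:40, :40] = 5.0
        f = piv_pair(a, a)
        assert not f.valid[0, 0]
        assert np.isnan(f.u[0, 0]) and np.isnan(f.v[0, 0])

    def test_intensity_floor_invalidates_dim_windows(self, rng):
        a = textured_frame(rng)
        f = piv_pair(a, a, min_mean_intensity=a.mean() * 10)
        assert f.n_valid == 0

    def test_input_contract_errors(self, rng):
        a = textured_frame(rng)
        with pytest.raises(ValueError, match="share shape"):
            piv_pair(a, a[:64])
        with pytest.raises(ValueError, match="larger than image"):
            piv_pair(a[:16, :16], a[:16, :16], window_px=32)
        with pytest.raises(ValueError, match="overlap"):
            piv_pair(a, a, window_px=32, overlap_px=32)
        with pytest.raises(ValueError, match="subpixel"):
            piv_pair(a, a, subpixel="spline")


class TestRadialProject:
    def test_outward_flow_is_pure_radial(self):
        p = dataclasses.replace(
            preset("wildtype_ring"), flow_mode="outward",
            flow_params={"speed_um_s": 0.005},
        )
        field = true_velocity_field(p)
        rmap = radial_project(field, p.ring_center_px, PX, DT)
        keep = rmap.valid
        np.testing.assert_allclose(rmap.radial[keep], 0.005, atol=1e-12)
        np.testing.assert_allclose(rmap.tangential[keep], 0.0, atol=1e-12)

    def test_rigid_rotation_has_zero_radial(self):
        p = preset("rotation_test")
        omega = p.flow_params["omega_rad_s"]
        field = true_velocity_field(p)
        rmap = radial_project(field, p.ring_center_px, PX, DT)
        keep = rmap.valid
        assert np.nanmax(np.abs(rmap.radial[keep])) < 1e-12
        # |tangential| = omega * r
        r_um = np.hypot(field.x - 79.5, field.y - 79.5) * PX
        np.testing.assert_allclose(
            np.abs(rmap.tangential[keep]), omega * r_um[keep], rtol=1e-9
        )

    def test_uniform_translation_cancels_on_symmetric_grid(self):
        p = dataclasses.replace(
            preset("translation_test"),
            flow_params={"velocity_um_s": (0.004, -0.002)},
        )
        field = true_velocity_field(p)
        rmap = radial_project(field, (79.5, 79.5), PX, DT)
        assert abs(np.nanmean(rmap.radial)) < 1e-12

    def test_decomposition_reconstructs_speed(self, rng):
        f = make_field(rng, invalid=((2, 2),))
        rmap = radial_project(f, (47.5, 47.5), PX, DT)
        speed2 = (f.u**2 + f.v**2) * (PX / DT) ** 2
        keep = rmap.valid
        np.testing.assert_allclose(
            rmap.radial[keep] ** 2 + rmap.tangential[keep] ** 2,
            speed2[keep], rtol=1e-9,
        )

    def test_center_window_excluded(self, rng):
        f = make_field(rng)
        rmap = radial_project(f, (47.5, 47.5), PX, DT)  # grid point hits center
        assert not rmap.valid[2, 2]
        assert np.isnan(rmap.radial[2, 2])


class TestAggregation:
    def test_identical_outward_fields_accumulate_linearly(self):
        p = dataclasses.replace(
            preset("wildtype_ring"), flow_mode="outward",
            flow_params={"speed_um_s": 0.05 / DT * 1.0},  # 0.05 µm per pair
        )
        fields = [
            dataclasses.replace(true_velocity_field(p, t_s=i * DT))
            for i in range(10)
        ]
        acc = heatmap_accumulate(fields, p.ring_center_px, PX)
        keep = np.hypot(fields[0].x - 79.5, fields[0].y - 79.5) > 1e-9
        np.testing.assert_allclose(acc.total_um[keep], 0.5, atol=1e-9)
        np.testing.assert_allclose(acc.mean_um[keep], 0.05, atol=1e-10)

    def test_alternating_fields_cancel(self, rng):
        f = make_field(rng)
        g = dataclasses.replace(f, u=-f.u, v=-f.v)
        acc = heatmap_accumulate([f, g, f, g], (0.0, 0.0), PX)
        np.testing.assert_allclose(acc.total_um, 0.0, atol=1e-12)

    def test_span_concatenation_equals_sum(self, rng):
        fields = [make_field(rng) for _ in range(6)]
        center = (10.0, 20.0)
        whole = heatmap_accumulate(fields, center, PX)
        first = heatmap_accumulate(fields[:3], center, PX)
        second = heatmap_accumulate(fields[3:], center, PX)
        np.testing.assert_allclose(whole.total_um, first.total_um + second.total_um)
        np.testing.assert_array_equal(
            whole.valid_count, first.valid_count + second.valid_count
        )

    def test_invalid_windows_never_contaminate(self, rng):
        fields = [make_field(rng, invalid=((0, 0), (1, 3))) for _ in range(4)]
        acc = heatmap_accumulate(fields, (5.0, 5.0), PX)
        assert np.isfinite(acc.total_um).all()
        assert acc.valid_count[0, 0] == 0 and np.isnan(acc.mean_um[0, 0])
        ser = mean_radial_series(fields, (5.0, 5.0), PX, DT, interval_s=DT)
        finite = ser["mean_radial_um_s"].dropna()
        assert np.isfinite(finite).all()

    def test_mismatched_grids_rejected(self, rng):
        f = make_field(rng, shape=(5, 5))
        g = make_field(rng, shape=(4, 4))
        with pytest.raises(ValueError, match="grid"):
            heatmap_accumulate([f, g], (0.0, 0.0), PX)
        with pytest.raises(ValueError, match="empty"):
            heatmap_accumulate([], (0.0, 0.0), PX)


class TestMeanRadialSeries:
    def test_constant_outward_flow_gives_flat_series(self):
        p = dataclasses.replace(
            preset("wildtype_ring"), flow_mode="outward",
            flow_params={"speed_um_s": 0.006},
        )
        fields = [true_velocity_field(p, t_s=i * DT) for i in range(10)]
        for i, f in enumerate(fields):
            f.time_s = i * DT
        ser = mean_radial_series(fields, p.ring_center_px, PX, DT, interval_s=120.0)
        np.testing.assert_allclose(ser["mean_radial_um_s"], 0.006, atol=1e-12)
        assert len(ser) == 3

    def test_ring_expansion_sign_convention_positive(self, wildtype_scene):
        stack, truth = wildtype_scene
        floor = 0.25 * float(stack.data[:, 0].mean())
        fields = [
            piv_pair(stack.frame(t, 0), stack.frame(t + 1, 0),
                     time_s=t * DT, min_mean_intensity=floor)
            for t in range(stack.n_frames - 1)
        ]
        ys, xs = np.nonzero(truth.masks["apical"].pixels)
        ser = mean_radial_series(fields, (xs.mean(), ys.mean()), PX, DT)
        assert (ser["mean_radial_um_s"].dropna() > 0).all()

    def test_interval_must_cover_frame_spacing(self, rng):
        f = make_field(rng)
        with pytest.raises(ValueError, match="interval"):
            mean_radial_series([f], (0.0, 0.0), PX, DT, interval_s=DT / 2)


class TestArrowMap:
    def test_zero_field_zero_length_arrows(self, rng):
        f = make_field(rng)
        f.u[:] = np.where(f.valid, 0.0, np.nan)
        f.v[:] = np.where(f.valid, 0.0, np.nan)
        arrows = arrow_map(f, (0.0, 0.0), PX, DT)
        assert (arrows["draw_dx_px"] == 0).all() and (arrows["draw_dy_px"] == 0).all()

    def test_display_scale_doubles_drawn_not_data(self, rng):
        f = make_field(rng)
        a1 = arrow_map(f, (0.0, 0.0), PX, DT, display_scale=1.0)
        a2 = arrow_map(f, (0.0, 0.0), PX, DT, display_scale=2.0)
        np.testing.assert_allclose(a2["draw_dx_px"], 2 * a1["draw_dx_px"])
        np.testing.assert_allclose(a2["u_px"], a1["u_px"])

    def test_arrow_colors_agree_with_radial_projection(self, rng):
        f = make_field(rng)
        center = (5.0, 7.0)
        arrows = arrow_map(f, center, PX, DT)
        rmap = radial_project(f, center, PX, DT)
        np.testing.assert_allclose(
            arrows["radial_um_s"].to_numpy(), rmap.radial[rmap.valid]
        )
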