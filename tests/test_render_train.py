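"""Rendering equation, hemisphere discretization, loss and training."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import echofield as ef
from echofield.field import FieldConfig, init_field
from echofield.render_train import (
    RenderContext, TrainConfig, _backward_slices, _forward_slices,
    hemisphere_samples, render_slice, render_spectrogram, slice_loss, train,
)
from echofield.spectro import CompressionConfig, SpectroConfig, compress, \
    make_observation, uncompress


class TestHemisphereSamples:
    def test_default_count_and_geometry(self):
        pose = ef.pose_sphere(1, 0.3, (0, 0, 0), seed=2)[0]
        hs = hemisphere_samples(pose, 0.25)
        assert hs.points_world.shape == (600, 3)
        d = np.linalg.norm(hs.points_world - pose.position, axis=1)
        assert np.allclose(d, 0.25, atol=1e-9)
        # forward half-space only
        assert np.all(hs.directions @ pose.forward > 0)

    def test_weights_sum_to_hemisphere_solid_angle(self):
        pose = ef.Pose(np.zeros(3), np.zeros(3))
        hs = hemisphere_samples(pose, 0.1, n=123)
        assert hs.weights.sum() == pytest.approx(2 * math.pi, rel=1e-12)

    def test_near_uniform_spacing(self):
        # brute-force nearest-neighbor angles vs uniform-packing ideal
        pose = ef.Pose(np.zeros(3), np.zeros(3))
        hs = hemisphere_samples(pose, 1.0, n=200)
        u = hs.directions
        cos = np.clip(u @ u.T, -1, 1)
        np.fill_diagonal(cos, -1)
        nn = np.arccos(cos.max(axis=1))
        ideal = math.sqrt(2 * math.pi / 200)
        assert np.all(nn > 0.3 * ideal)
        assert nn.mean() == pytest.approx(ideal, rel=0.3)

    def test_invalid_arguments(self):
        pose = ef.Pose(np.zeros(3), np.zeros(3))
        with pytest.raises(ValueError):
            hemisphere_samples(pose, -0.1)
        with pytest.raises(ValueError):
            hemisphere_samples(pose, 0.1, n=2)


BOUNDS = np.array([[-0.05] * 3, [0.05] * 3])


def _zero_field():
    params = init_field(FieldConfig(hidden_widths=(8,), skip_at=(), seed=0), BOUNDS)
    params.weights[-1][:] = 0.0
    params.biases[-1][:] = 0.0
    return params


class TestRenderSlice:
    def test_zero_field_renders_compressed_zero(self, call, ertf):
        sl = render_slice(_zero_field(), ef.Pose(np.zeros(3), np.zeros(3)),
                          0.3, ertf, call, n_hemisphere=32)
        assert sl.spectrum.shape == (94,)
        assert np.allclose(sl.spectrum, 0.0)

    def test_delay_factor_inert_under_magnitude(self, call, ertf):
        # the unimodular delay depends on v_s; changing it must not move the
        # rendered magnitudes
        params = init_field(FieldConfig(hidden_widths=(16,), skip_at=(), seed=4), BOUNDS)
        params.weights[-1] *= 50.0
        pose = ef.Pose(np.zeros(3), np.zeros(3))
        a = render_slice(params, pose, 0.3, ertf, call, n_hemisphere=64, v_s=343.0)
        b = render_slice(params, pose, 0.3, ertf, call, n_hemisphere=64, v_s=500.0)
        assert np.allclose(a.spectrum, b.spectrum, atol=1e-12)

    def test_values_in_unit_interval(self, call, ertf):
        params = init_field(FieldConfig(hidden_widths=(16,), skip_at=(), seed=1), BOUNDS)
        params.weights[-1] *= 1e4  # drive saturation
        sl = render_slice(params, ef.Pose(np.zeros(3), np.zeros(3)), 0.2,
                          ertf, call, n_hemisphere=32)
        assert np.all(sl.spectrum >= 0.0) and np.all(sl.spectrum <= 1.0)

    def test_prerender_magnitude_is_homogeneous_in_field(self, call, ertf):
        # rendering is linear in the field before the magnitude/compression
        cc = CompressionConfig()
        pose = ef.Pose(np.zeros(3), np.zeros(3))

        def flat(alpha):
            return lambda p, d: alpha * np.ones((p.shape[0], 47), dtype=complex)

        a = render_slice(flat(1.0), pose, 0.3, ertf, call, cc, ref=1e3,
                         n_hemisphere=64)
        b = render_slice(flat(2.5), pose, 0.3, ertf, call, cc, ref=1e3,
                         n_hemisphere=64)
        lin_a = uncompress(a.spectrum, cc, 1e3)
        lin_b = uncompress(b.spectrum, cc, 1e3)
        assert np.allclose(lin_b, 2.5 * lin_a, rtol=1e-6)

    def test_delta_field_matches_simulated_observation(self, call_flat, ertf):
        """Renderer vs simulator oracle: a field that is a delta at a lone
        scatterer, rendered at the scatterer's range, reproduces the
        simulated + preprocessed observation column."""
        err = delta_field_relative_error(call_flat, ertf)
        assert err < 0.05


def delta_field_relative_error(call, ertf, n_hemi=600):
    """Shared renderer-vs-simulator comparison (also used for acceptance)."""
    sim = ef.SimConfig(max_range=0.42)
    pose = ef.Pose(np.zeros(3), np.zeros(3))
    hs = hemisphere_samples(pose, 0.3, n_hemi)
    k = int(np.argmax(hs.directions_body[:, 0]))
    target = hs.points_world[k]
    scene = ef.Scene([ef.Scatterer(target, gain=1.0)],
                     bounds=np.stack([target - 0.01, target + 0.01]))
    echo = ef.simulate_echo(scene, pose, call, ertf, sim)
    obs = make_observation(echo, call, SpectroConfig(), v_s=sim.v_s,
                           max_range=sim.max_range)
    col = int(np.argmax(obs.values.sum(axis=0)))

    def delta_field(pos, dirs):
        hit = np.linalg.norm(pos - target, axis=1) < 0.005
        return hit[:, None] * np.ones((1, 47), dtype=complex)

    cc = CompressionConfig()
    sl = render_slice(delta_field, pose, float(obs.ranges[col]), ertf, call,
                      cc, ref=1.0, v_s=sim.v_s, n_hemisphere=n_hemi)
    # matched normalization: compress both against their own peak magnitude
    lin_a = uncompress(sl.spectrum, cc, 1.0)
    a = compress(lin_a, cc, float(lin_a.max()))
    lin_b = uncompress(obs.values[:, col], cc, obs.meta["compression"]["ref"])
    b = compress(lin_b, cc, float(lin_b.max()))
    return float(np.linalg.norm(a - b) / np.linalg.norm(b))


class TestRenderSpectrogram:
    def test_zero_field_and_shape(self, call, ertf):
        ranges = np.linspace(0.1, 0.4, 25)
        spec = render_spectrogram(_zero_field(), ef.Pose(np.zeros(3), np.zeros(3)),
                                  ranges, ertf, call, n_hemisphere=16)
        assert spec.values.shape == (94, 25)
        assert np.all(spec.values == 0)

    def test_columns_equal_individual_slices(self, call, ertf):
        params = init_field(FieldConfig(hidden_widths=(16,), skip_at=(), seed=2), BOUNDS)
        params.weights[-1] *= 100.0
        pose = ef.pose_sphere(1, 0.3, (0, 0, 0), seed=1)[0]
        ranges = np.array([0.2, 0.3, 0.35])
        spec = render_spectrogram(params, pose, ranges, ertf, call,
                                  n_hemisphere=32)
        for j, r in enumerate(ranges):
            sl = render_slice(params, pose, r, ertf, call, n_hemisphere=32)
            assert np.allclose(spec.values[:, j], sl.spectrum, atol=1e-12)


class TestSliceLoss:
    def test_zero_for_identical(self):
        v = np.linspace(0, 1, 94)
        assert slice_loss(v, v) == 0.0

    def test_arithmetic_example(self):
        assert slice_loss([0.2, 0.4], [0.0, 0.4]) == pytest.approx(0.02)

    @given(st.lists(st.floats(0, 1), min_size=4, max_size=4),
           st.lists(st.floats(0, 1), min_size=4, max_size=4))
    def test_symmetric_and_nonnegative(self, a, b):
        assert slice_loss(a, b) == pytest.approx(slice_loss(b, a))
        assert slice_loss(a, b) >= 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            slice_loss([0.1], [0.1, 0.2])


class TestGradientThroughRenderer:
    def test_autograd_matches_finite_differences(self, call, ertf):
        """End-to-end gradient of slice_loss(render_slice) w.r.t. field
        parameters vs central finite differences on a 2-layer toy field."""
        rng = np.random.default_rng(7)
        params = init_field(FieldConfig(hidden_widths=(16, 16), skip_at=(), seed=3), BOUNDS)
        params.weights[-1] += rng.normal(0, 0.05, params.weights[-1].shape)
        ctx = RenderContext(call, ertf, n_hemisphere=16,
                            compression=CompressionConfig(), ref=1.0)
        pose = ef.pose_sphere(1, 0.3, (0, 0, 0), seed=5)[0]
        rots = pose.rotation[None].repeat(2, 0)
        poss = pose.position[None].repeat(2, 0)
        ranges = np.array([0.27, 0.32])
        target = rng.uniform(0.2, 0.8, (2, 94))

        def loss_of(p):
            s = _forward_slices(p, ctx, rots, poss, ranges)
            return float(np.mean((s - target) ** 2))

        s, fwd = _forward_slices(params, ctx, rots, poss, ranges, want_cache=True)
        gw, gb = _backward_slices(params, ctx, fwd, 2.0 / s.size * (s - target))
        h = 1e-4
        checked = 0
        for li in range(3):
            w = params.weights[li]
            for ij in [(0, 0), (w.shape[0] // 2, w.shape[1] // 2),
                       (w.shape[0] - 1, w.shape[1] - 1)]:
                orig = w[ij]
                w[ij] = orig + h
                lp = loss_of(params)
                w[ij] = orig - h
                lm = loss_of(params)
                w[ij] = orig
                fd = (lp - lm) / (2 * h)
                if abs(fd) > 1e-8:
                    assert gw[li][ij] == pytest.approx(fd, rel=1e-4)
                    checked += 1
        assert checked >= 5


class TestTraining:
    def test_loss_decreases_on_desk_scene(self, trained_sphere):
        lc = trained_sphere["params"].meta["loss_curve"]
        assert len(lc) == 20
        assert lc[-1] < 0.5 * lc[0]

    def test_heldout_prediction_correlates(self, trained_sphere):
        ens = trained_sphere["ensemble"]
        params = trained_sphere["params"]
        for pose, obs in zip(trained_sphere["held_poses"],
                             trained_sphere["held"].spectrograms):
            pred = render_spectrogram(
                params, pose, obs.ranges, ef.PistonErtf(), ens.call,
                ens.compression_config(), ens.ref, ens.v_s, 128,
                times=obs.times)
            r = np.corrcoef(pred.values.ravel(), obs.values.ravel())[0, 1]
            assert r >= 0.8

    def test_seeded_training_is_deterministic(self, call, ertf):
        scene = ef.Scene([ef.Scatterer((0.0, 0, 0))],
                         bounds=np.array([[-0.02] * 3, [0.02] * 3]))
        poses = ef.pose_sphere(2, 0.25, (0, 0, 0), seed=3)
        from echofield.cli import simulate_ensemble
        ens = simulate_ensemble(scene, poses, call, ertf,
                                ef.SimConfig(max_range=0.3),
                                SpectroConfig(overlap=0.75))
        fc = FieldConfig(hidden_widths=(16,), skip_at=(), seed=1)
        tc = TrainConfig(batch_size=32, epochs=2, seed=9, n_hemisphere=16)
        a = train(ens, fc, tc, scene_bounds=BOUNDS)
        b = train(ens, fc, tc, scene_bounds=BOUNDS)
        assert a.meta["loss_curve"] == b.meta["loss_curve"]

    def test_sample_count_is_poses_times_columns(self, trained_sphere):
        ens = trained_sphere["ensemble"]
        assert ens.n_slices == 24 * ens.spectrograms[0].n_t

    def test_paper_scale_sample_count(self):
        # 400 poses x ~500 columns ~= 2e5 slices with the full-scale defaults
        n_cols = int(0.6 / (343.0 * 3 / 400e3 / 2))
        assert 1.5e5 <= 400 * n_cols <= 2.5e5
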