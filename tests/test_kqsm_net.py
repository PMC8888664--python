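"""Network input assembly, architecture, losses, patching, training."""

import numpy as np
import pytest

from kqsm import (
    FieldMap,
    KSpaceVolume,
    NetworkConfig,
    TrainingConfig,
    ValidationError,
    VoxelGrid,
    build_network,
    extract_patches,
    fft_volume,
    forward_field,
    infer,
    ifft_volume,
    load_checkpoint,
    loss_l1,
    loss_mse,
    lr_schedule,
    make_dipole_kernel,
    nonill_mask,
    prepare_input,
    save_checkpoint,
    simulate_multi_orientation,
    smooth_random_phantom,
    stitch_patches,
    total_loss,
    tkd_reconstruct,
    train,
)

DESK_NET = NetworkConfig(feature_width=8, thr=0.2)


class TestPrepareInput:
    def test_zero_field(self, grid_small, b0_z):
        f = FieldMap(np.zeros(grid_small.shape), grid_small, b0_z)
        stack = prepare_input(f, thr=0.2)
        assert stack.channels.shape == (3,) + grid_small.shape
        np.testing.assert_array_equal(stack.channels[1:], 0.0)
        ker = make_dipole_kernel(grid_small, b0_z)
        np.testing.assert_allclose(stack.channels[0], ker.values, atol=1e-6)
        assert stack.scale == 1.0

    def test_scale_round_trip(self, grid32, b0_z, smooth_chi32):
        ker = make_dipole_kernel(grid32, b0_z)
        field = forward_field(smooth_chi32, ker)
        stack = prepare_input(field, thr=0.2)
        restored = stack.channels[1:].astype(np.float64) * stack.scale
        tkd = tkd_reconstruct(field, ker, 0.2)
        np.testing.assert_allclose(
            restored[0], tkd.kspace.real_part,
            atol=1e-10 * np.abs(tkd.kspace.real_part).max() + 1e-3)

    def test_cross_module_consistency(self, grid32, b0_z, smooth_chi32):
        """Un-normalized TKD channels inverse-transform to the TKD map."""
        ker = make_dipole_kernel(grid32, b0_z)
        field = forward_field(smooth_chi32, ker)
        stack = prepare_input(field, thr=0.2)
        spec = (stack.channels[1].astype(np.float64)
                + 1j * stack.channels[2].astype(np.float64)) * stack.scale
        back = ifft_volume(KSpaceVolume.from_complex(spec, grid32)).real
        tkd = tkd_reconstruct(field, ker, 0.2)
        # float32 channels bound the agreement
        assert np.abs(back - tkd.susceptibility.values).max() < 1e-4


class TestArchitecture:
    def test_shape_preserving(self):
        state = build_network(DESK_NET, seed=0)
        x = np.random.default_rng(0).standard_normal((3, 8, 8, 8)).astype(np.float32)
        y = state.net.forward(x)
        assert y.shape == (2, 8, 8, 8)

    def test_eval_determinism(self):
        state = build_network(DESK_NET, seed=0)
        state.net.set_train(False)
        x = np.random.default_rng(1).standard_normal((3, 8, 8, 8)).astype(np.float32)
        np.testing.assert_array_equal(state.net.forward(x), state.net.forward(x))

    def test_residual_skip_wired(self):
        """Disabling one residual add changes the output."""
        state = build_network(DESK_NET, seed=0)
        # make the residual branches non-trivial
        rng = np.random.default_rng(3)
        for rb in state.net.resblocks:
            rb.branch.layers[3].init_random(rng, gain=0.5)
        x = np.random.default_rng(2).standard_normal((3, 8, 8, 8)).astype(np.float32)
        base = state.net.forward(x)
        state.net.resblocks[4].skip_enabled = False
        ablated = state.net.forward(x)
        state.net.resblocks[4].skip_enabled = True
        assert not np.allclose(base, ablated)

    def test_identity_preserving_init(self, grid32, b0_z, smooth_chi32):
        """Freshly built network reproduces its TKD input channels."""
        ker = make_dipole_kernel(grid32, b0_z)
        field = forward_field(smooth_chi32, ker)
        stack = prepare_input(field, thr=0.2)
        state = build_network(NetworkConfig(feature_width=8, thr=0.2, init_gain=0.0))
        out = state.net.forward(stack.channels)
        np.testing.assert_allclose(out, stack.channels[1:], atol=1e-4)

    def test_parameter_count_scales_with_width(self):
        small = build_network(NetworkConfig(feature_width=4), seed=0)
        large = build_network(NetworkConfig(feature_width=8), seed=0)
        assert large.n_params > small.n_params > 0


class TestLosses:
    def test_mse_basics(self, grid_small):
        z = np.zeros((2,) + grid_small.shape)
        pred = z.copy()
        pred[0, 0, 0, 0], pred[1, 0, 0, 0] = 3.0, 4.0  # 3 + 4i at one k-point
        n = np.prod(grid_small.shape)
        assert loss_mse(pred, z) == pytest.approx(25.0 / n)
        assert loss_mse(z, z) == 0.0
        assert loss_mse(2 * pred, z) == pytest.approx(4 * 25.0 / n)

    def test_l1_modulus_and_masking(self, grid_small):
        z = np.zeros((2,) + grid_small.shape)
        pred = z.copy()
        pred[0, 0, 0, 0], pred[1, 0, 0, 0] = 3.0, 4.0
        mask = np.zeros(grid_small.shape, bool)
        assert loss_l1(pred, z, mask) == 0.0  # empty mask
        mask[0, 0, 0] = True
        mask[1, 1, 1] = True
        assert loss_l1(pred, z, mask) == pytest.approx(5.0 / 2)
        # pred = tkd on the mask, arbitrary elsewhere -> 0
        pred2 = np.random.default_rng(0).standard_normal(pred.shape)
        pred2[:, mask] = z[:, mask]
        assert loss_l1(pred2, z, mask) == 0.0

    def test_total_loss_weights(self, grid_small, rng):
        pred = rng.standard_normal((2,) + grid_small.shape)
        label = rng.standard_normal((2,) + grid_small.shape)
        tkd = rng.standard_normal((2,) + grid_small.shape)
        mask = rng.random(grid_small.shape) > 0.5
        assert total_loss(pred, label, tkd, mask, 1, 0) == pytest.approx(
            loss_mse(pred, label))
        assert total_loss(pred, label, tkd, mask, 0, 1) == pytest.approx(
            loss_l1(pred, tkd, mask))

    def test_total_loss_two_point_hand_check(self):
        """4^3 volume, two nonzero k-points, verified by hand arithmetic."""
        shape = (4, 4, 4)
        pred = np.zeros((2,) + shape)
        label = np.zeros((2,) + shape)
        tkd = np.zeros((2,) + shape)
        pred[0, 0, 0, 0] = 1.0          # error 1 + 0i vs label
        pred[1, 1, 1, 1] = 2.0          # error 0 + 2i vs label
        tkd[0, 0, 0, 0] = 4.0           # consistency diff -3 + 0i
        mask = np.zeros(shape, bool)
        mask[0, 0, 0] = True
        n = 64
        expected = (1.0 + 4.0) / n + 1.0 * 3.0 / 1
        assert total_loss(pred, label, tkd, mask, 1.0, 1.0) == pytest.approx(expected)


class TestPatching:
    def test_single_patch_when_volume_fits(self):
        vol = np.zeros((64, 64, 64))
        patches = extract_patches(vol, 64, 0.5)
        assert len(patches) == 1
        assert patches[0][0] == (0, 0, 0)

    def test_96_cube_gives_8_patches(self):
        vol = np.arange(96**3, dtype=float).reshape(96, 96, 96)
        patches = extract_patches(vol, 64, 0.5)
        assert len(patches) == 8
        offsets = {off for off, _ in patches}
        assert offsets == {(i, j, k) for i in (0, 32) for j in (0, 32) for k in (0, 32)}

    def test_coverage_and_stitch_round_trip(self):
        vol = np.random.default_rng(0).standard_normal((40, 48, 36))
        patches = extract_patches(vol, 24, 0.5)
        count = np.zeros(vol.shape)
        for (i, j, k), p in patches:
            count[i:i + 24, j:j + 24, k:k + 24] += 1
        assert count.min() >= 1
        # stitching constant-consistent patches reproduces the volume
        back = stitch_patches(patches, vol.shape)
        np.testing.assert_allclose(back, vol, atol=1e-12)

    def test_patch_too_large_rejected(self):
        with pytest.raises(ValidationError):
            extract_patches(np.zeros((16, 16, 16)), 32)


@pytest.fixture(scope="module")
def tiny_trained():
    """One 16^3 phantom, width-4 net, 30 epochs — a smoke-scale run."""
    grid = VoxelGrid((16, 16, 16))
    chi = smooth_random_phantom(grid, seed=3, amplitude=0.1)
    from kqsm import rotation_to_b0

    field = simulate_multi_orientation(chi, [rotation_to_b0(0)], 0.0)[0]
    net_cfg = NetworkConfig(feature_width=4, thr=0.2)
    train_cfg = TrainingConfig(epochs=30, lr0=1e-3, seed=0, patch_size=16)
    state = train([(field, chi)], net_cfg, train_cfg)
    return state, field, chi


class TestTraining:
    def test_lr_schedule_steps(self):
        cfg = TrainingConfig(epochs=60)
        assert lr_schedule(0, cfg) == pytest.approx(1e-4)
        assert lr_schedule(24, cfg) == pytest.approx(1e-4)
        assert lr_schedule(25, cfg) == pytest.approx(9e-5)
        assert lr_schedule(50, cfg) == pytest.approx(8.1e-5)

    def test_loss_decreases(self, tiny_trained):
        state, _, _ = tiny_trained
        assert state.loss_log[-1] < state.loss_log[0]
        assert len(state.loss_log) == 30

    def test_training_determinism(self, tiny_trained):
        grid = VoxelGrid((16, 16, 16))
        chi = smooth_random_phantom(grid, seed=3, amplitude=0.1)
        from kqsm import rotation_to_b0

        field = simulate_multi_orientation(chi, [rotation_to_b0(0)], 0.0)[0]
        cfg = TrainingConfig(epochs=3, lr0=1e-3, seed=5, patch_size=16)
        a = train([(field, chi)], NetworkConfig(feature_width=4), cfg)
        b = train([(field, chi)], NetworkConfig(feature_width=4), cfg)
        assert a.loss_log == b.loss_log

    def test_consistency_weight_pins_output_to_tkd(self):
        """With a dominant consistency weight the trained output stays
        near the TKD input on the non-ill-posed region."""
        grid = VoxelGrid((16, 16, 16))
        chi = smooth_random_phantom(grid, seed=9, amplitude=0.1)
        from kqsm import rotation_to_b0

        field = simulate_multi_orientation(chi, [rotation_to_b0(0)], 0.0)[0]
        cfg = TrainingConfig(epochs=20, lr0=1e-3, seed=0, patch_size=16,
                             w_mse=1.0, w_l1=50.0)
        state = train([(field, chi)], NetworkConfig(feature_width=4), cfg)
        stack = prepare_input(field, thr=0.2)
        state.net.set_train(False)
        pred = state.net.forward(stack.channels).astype(np.float64)
        mask = nonill_mask(stack.kernel, 0.2).values
        diff = np.sqrt(((pred - stack.channels[1:3].astype(np.float64)) ** 2).sum(0))
        assert diff[mask].mean() < 0.02 * np.abs(stack.channels[1:3]).max()

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValidationError):
            train([], DESK_NET, TrainingConfig(epochs=1))


class TestInference:
    def test_sign_magnitude_rule(self):
        c = np.array([2.0 + 0.0j, -2.0 + 0.1j, 0.0 + 1.0j])
        out = np.abs(c) * np.sign(c.real)
        assert out[0] == pytest.approx(2.0)
        assert out[1] == pytest.approx(-np.abs(-2.0 + 0.1j))
        assert out[2] == 0.0  # Re = 0 tie rule

    def test_infer_deterministic_and_checkpoint_round_trip(self, tmp_path,
                                                           grid_small, b0_z):
        chi = smooth_random_phantom(grid_small, seed=11, amplitude=0.1)
        field = simulate_multi_orientation(chi, [b0_z], 0.0)[0]
        state = build_network(DESK_NET, seed=2)
        a = infer(field, state=state)
        b = infer(field, state=state)
        np.testing.assert_array_equal(a.values, b.values)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(state, path)
        loaded = load_checkpoint(path)
        c = infer(field, state=loaded)
        np.testing.assert_allclose(a.values, c.values, atol=1e-12)

    def test_patched_inference_matches_full(self, grid_small, b0_z):
        """Patch-stitched inference approximates the whole-volume pass."""
        chi = smooth_random_phantom(grid_small, seed=13, amplitude=0.1)
        field = simulate_multi_orientation(chi, [b0_z], 0.0)[0]
        state = build_network(DESK_NET, seed=2)
        full = infer(field, state=state)
        patched = infer(field, state=state, patch_size=12)
        # interiors agree; boundary voxels differ by padding context
        diff = np.abs(full.values - patched.values)
        assert np.median(diff) < 0.05 * np.abs(full.values).max()

    def test_infer_requires_state(self, grid_small, b0_z):
        field = FieldMap(np.zeros(grid_small.shape), grid_small, b0_z)
        with pytest.raises(ValidationError):
            infer(field, state=None)
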