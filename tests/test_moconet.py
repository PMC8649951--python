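import numpy as np
import pytest

from t1moco import dvf as D
from t1moco import moconet as M
from t1moco.errors import ConfigurationError, ContractError


@pytest.fixture(scope="module")
def small_model():
    return M.build_network(M.NetworkConfig(n_scales=4, base_channels=4), seed=0)


class TestNetworkConfig:
    def test_defaults_valid(self):
        cfg = M.NetworkConfig()
        assert cfg.n_scales == 4
        assert cfg.divisor == 16

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_scales=1), dict(kernel_size=5), dict(in_frames=6), dict(base_channels=0)],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            M.NetworkConfig(**kwargs)


class TestBuildNetwork:
    def test_scale_pyramid_shapes(self, small_model):
        rng = np.random.default_rng(0)
        x = rng.random((7, 64, 64)).astype(np.float32)
        sets = small_model.forward(x)
        shapes = [s.shape for s in sets]
        assert shapes == [(8, 8), (16, 16), (32, 32), (64, 64)]

    def test_same_seed_identical_checksums(self):
        a = M.build_network(M.NetworkConfig(base_channels=4), seed=3)
        b = M.build_network(M.NetworkConfig(base_channels=4), seed=3)
        c = M.build_network(M.NetworkConfig(base_channels=4), seed=4)
        assert a.parameter_checksum() == b.parameter_checksum()
        assert a.parameter_checksum() != c.parameter_checksum()

    def test_indivisible_size_rejected(self, small_model):
        with pytest.raises(ContractError):
            small_model.forward(np.zeros((7, 60, 64), dtype=np.float32))

    def test_untrained_model_predicts_identity_deformation(self, small_model):
        # zero-initialised heads -> the untrained corrector is a no-op
        rng = np.random.default_rng(1)
        x = rng.random((7, 32, 32)).astype(np.float32)
        pred = M.predict_dvfs(small_model, x)
        assert np.abs(pred.as_array()).max() == 0.0


class TestPredictDvfs:
    def test_output_shape_and_finiteness(self, small_model):
        rng = np.random.default_rng(2)
        x = rng.random((7, 48, 48)).astype(np.float32)
        pred = M.predict_dvfs(small_model, x)
        assert pred.shape == (48, 48)
        assert np.all(np.isfinite(pred.as_array()))

    def test_inference_deterministic(self, small_model):
        rng = np.random.default_rng(3)
        x = rng.random((7, 32, 32)).astype(np.float32)
        a = M.predict_dvfs(small_model, x).as_array()
        b = M.predict_dvfs(small_model, x).as_array()
        np.testing.assert_array_equal(a, b)

    def test_nonfinite_input_rejected(self, small_model):
        x = np.zeros((7, 32, 32), dtype=np.float32)
        x[0, 0, 0] = np.nan
        with pytest.raises(ContractError):
            M.predict_dvfs(small_model, x)


class TestMultiscaleLoss:
    def test_zero_at_resampled_truth(self):
        rng = np.random.default_rng(4)
        gt = rng.normal(0, 2, (7, 16, 16, 2))
        preds = []
        for s in (2, 1, 0):
            f = 2**s
            t = M.resample_gt_to_scale(M.dvfset_to_tensor(gt), f)
            preds.append(t.reshape(7, 2, 16 // f, 16 // f).transpose(0, 2, 3, 1))
        assert M.multiscale_loss(preds, gt) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_single_scale_example(self):
        # single scale, single 1x1 frame: prediction (1, 2), target (0, 0)
        pred = np.array([1.0, 2.0]).reshape(1, 1, 1, 2)
        gt = np.zeros((1, 1, 1, 2))
        assert M.multiscale_loss([pred], gt) == pytest.approx((1.0 + 4.0) / 2.0)
        assert M.multiscale_loss([pred], gt) == pytest.approx(2.5)

    def test_nonnegative_and_increases_under_perturbation(self):
        rng = np.random.default_rng(5)
        gt = rng.normal(0, 1, (7, 8, 8, 2))
        perfect = [
            M.resample_gt_to_scale(M.dvfset_to_tensor(gt), f)
            .reshape(7, 2, 8 // f, 8 // f).transpose(0, 2, 3, 1)
            for f in (2, 1)
        ]
        assert M.multiscale_loss(perfect, gt) == pytest.approx(0.0, abs=1e-12)
        for scale in range(2):
            for _ in range(5):
                perturbed = [p.copy() for p in perfect]
                idx = tuple(rng.integers(d) for d in perturbed[scale].shape)
                perturbed[scale][idx] += rng.uniform(0.1, 1.0)
                assert M.multiscale_loss(perturbed, gt) > 0.0

    def test_scale_count_mismatch_rejected(self):
        gt = np.zeros((7, 8, 8, 2))
        bad = [np.zeros((7, 3, 3, 2))]
        with pytest.raises(ContractError):
            M.multiscale_loss(bad, gt)

    def test_batched_training_loss_agrees_with_public_loss(self):
        model = M.build_network(M.NetworkConfig(n_scales=3, base_channels=4), seed=9)
        rng = np.random.default_rng(6)
        for p in model.parameters():
            p.value = (0.1 * rng.standard_normal(p.value.shape)).astype(np.float32)
        x = rng.random((7, 16, 16)).astype(np.float32)
        gt = rng.normal(0, 1, (7, 16, 16, 2))
        sets = model.forward(x)
        public = M.multiscale_loss(sets, gt)
        preds = model.forward_batch(x[None], train=False)
        batched, _ = M.multiscale_loss_grads(preds, M.dvfset_to_tensor(gt)[None])
        assert batched == pytest.approx(public, rel=1e-5)


class TestPredictDvfsLearns:
    def test_translation_only_task_recovers_inverse_fields(self):
        """Train on translation-only deformations (+-2 px) and check the
        mean endpoint error of predicted vs true inverse fields on held-out
        stacks. Scaled down (32x32, 60 samples) to stay inside the test
        budget; the < 1 px gate is a repo acceptance threshold."""
        from conftest import make_clean_stacks
        from t1moco import dvf as D
        from t1moco import nn, training

        def translation_pair(stack, rng):
            shifts = rng.uniform(-2.0, 2.0, (7, 2))
            shifts -= shifts.mean(axis=0)
            H, W = stack.frame_shape
            fields = np.broadcast_to(shifts[:, None, None, :], (7, H, W, 2))
            deformed = np.stack(
                [D.warp(frame, f) for frame, f in zip(stack.images, fields)]
            )
            x = training.quantile_normalize(deformed).astype(np.float32)
            gt = M.dvfset_to_tensor(-fields)
            return x, gt

        rng = np.random.default_rng(42)
        stacks = make_clean_stacks(60, base_seed=21, shape=(32, 32), blur_sigma_px=0.0)
        model = M.build_network(M.NetworkConfig(base_channels=4), seed=5)
        opt = nn.Adam(model.parameters(), lr=1e-3)
        for _ in range(25):
            order = rng.permutation(len(stacks))
            for start in range(0, len(order), 4):
                batch = [translation_pair(stacks[i], rng) for i in order[start:start + 4]]
                x = np.stack([b[0] for b in batch])
                gt = np.stack([b[1] for b in batch])
                preds = model.forward_batch(x, train=True)
                _, grads = M.multiscale_loss_grads(preds, gt)
                opt.zero_grad()
                model.backward_batch(grads)
                opt.step()

        held_out = make_clean_stacks(20, base_seed=77, shape=(32, 32), blur_sigma_px=0.0)
        rng_eval = np.random.default_rng(7)
        epes = []
        for stack in held_out:
            x, gt = translation_pair(stack, rng_eval)
            pred = M.predict_dvfs(model, x).as_array()
            truth = gt.reshape(7, 2, 32, 32).transpose(0, 2, 3, 1)
            epes.append(float(np.sqrt(((pred - truth) ** 2).sum(axis=-1)).mean()))
        assert float(np.mean(epes)) < 1.0


class TestTrainingDynamics:
    def test_single_batch_loss_decreases_over_50_steps(self):
        from t1moco import nn

        model = M.build_network(M.NetworkConfig(n_scales=3, base_channels=4), seed=11)
        rng = np.random.default_rng(12)
        x = rng.random((2, 7, 32, 32)).astype(np.float32)
        gt = (0.5 * rng.standard_normal((2, 14, 32, 32))).astype(np.float32)
        opt = nn.Adam(model.parameters(), lr=1e-3)
        first = None
        for step in range(50):
            preds = model.forward_batch(x, train=True)
            loss, grads = M.multiscale_loss_grads(preds, gt)
            if first is None:
                first = loss
            opt.zero_grad()
            model.backward_batch(grads)
            opt.step()
        assert loss < first


class TestCheckpoint:
    def test_roundtrip(self, small_model, tmp_path):
        path = tmp_path / "model.npz"
        M.save_checkpoint(path, small_model, extra={"note": "test"})
        loaded = M.load_checkpoint(path)
        assert loaded.config == small_model.config
        rng = np.random.default_rng(13)
        x = rng.random((7, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(
            M.predict_dvfs(loaded, x).as_array(), M.predict_dvfs(small_model, x).as_array()
        )

    def test_garbage_file_rejected(self, tmp_path):
        path = tmp_path / "junk.npz"
        np.savez(path, a=np.zeros(3))
        with pytest.raises(ContractError):
            M.load_checkpoint(path)
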