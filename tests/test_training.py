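"""Pair sampling, paired augmentation, WGAN-GP losses, training loop."""

import numpy as np
import pytest
from scipy.stats import chisquare

from growsim.conditioning import ConditionSet
from growsim.nn import tensor as T
from growsim.training import (
    AugmentParams,
    TrainConfig,
    augment_pair,
    blend,
    gradient_penalty,
    sample_pair,
    train,
    wgan_losses,
)

from conftest import tiny_specs


class TestPairSampling:
    def test_length_two_sequence_always_pairs_with_other(self, tiny_dataset):
        # build an index whose sequence we truncate virtually: use any
        # sequence and check the partner is never the input itself
        rng = np.random.default_rng(0)
        idx = int(tiny_dataset.indices_by_split("train")[0])
        for _ in range(10):
            pair = sample_pair(tiny_dataset, idx, rng)
            assert pair.ref_idx != idx
            assert pair.input_idx == idx

    def test_reference_uniform_over_sequence(self, tiny_dataset):
        # a sequence has 8 images; over many draws each of the 7
        # candidates should appear with frequency ~1/7
        rng = np.random.default_rng(1)
        idx = int(tiny_dataset.indices_by_split("train")[0])
        draws = [sample_pair(tiny_dataset, idx, rng).ref_idx for _ in range(10_000)]
        values, counts = np.unique(draws, return_counts=True)
        assert len(values) == 7
        assert chisquare(counts).pvalue > 1e-3

    def test_treatment_constant_within_pair(self, tiny_dataset):
        rng = np.random.default_rng(2)
        for idx in tiny_dataset.indices_by_split("train")[:20]:
            pair = sample_pair(tiny_dataset, int(idx), rng)
            rec_in = tiny_dataset.records[pair.input_idx]
            rec_ref = tiny_dataset.records[pair.ref_idx]
            assert rec_in.treatment_id == rec_ref.treatment_id
            assert rec_in.sequence_id == rec_ref.sequence_id


class TestAugmentation:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.a = rng.random((16, 16, 3)).astype(np.float32)
        self.b = rng.random((16, 16, 3)).astype(np.float32)

    def test_identity_draw_is_noop(self):
        rng = np.random.default_rng(0)
        out_a, out_b = augment_pair(self.a, self.b, rng, AugmentParams.identity())
        np.testing.assert_array_equal(out_a, self.a)
        np.testing.assert_array_equal(out_b, self.b)

    def test_shared_transform_preserves_correspondence(self):
        # encode spatial position in both images; after any draw the two
        # outputs must still match pixel-for-pixel
        marker = np.zeros((16, 16, 3), dtype=np.float32)
        marker[2:5, 3:7] = 1.0
        params = AugmentParams(p_flip=1.0, p_rot90=1.0, translate_frac=0.0, p_shadow=0.0)
        rng = np.random.default_rng(3)
        out_a, out_b = augment_pair(marker, marker.copy(), rng, params)
        np.testing.assert_array_equal(out_a, out_b)
        assert out_a.sum() == marker.sum()

    def test_shadowout_alpha_extremes(self):
        params = AugmentParams(
            p_flip=0.0,
            p_rot90=0.0,
            translate_frac=0.0,
            p_shadow=1.0,
            shadow_alpha=(1.0, 1.0),
        )
        rng = np.random.default_rng(0)
        out_a, _ = augment_pair(self.a, self.b, rng, params)
        np.testing.assert_allclose(out_a, self.a)  # alpha=1: no-op

        params0 = AugmentParams(
            p_flip=0.0,
            p_rot90=0.0,
            translate_frac=0.0,
            p_shadow=1.0,
            shadow_alpha=(0.0, 0.0),
            shadow_frac=(0.5, 0.5),
        )
        out_a, _ = augment_pair(self.a, self.b, np.random.default_rng(0), params0)
        assert (out_a == 0).sum() >= 8 * 8 * 3  # alpha=0: CutOut rectangle

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            augment_pair(self.a, self.b[:8], np.random.default_rng(0))


class TestBlend:
    def test_endpoints_and_midpoint(self):
        x_ref = np.zeros((2, 3, 4, 4), dtype=np.float32)
        x_gen = np.ones((2, 3, 4, 4), dtype=np.float32)
        np.testing.assert_allclose(blend(x_ref, x_gen, [1.0, 1.0]), x_ref)
        np.testing.assert_allclose(blend(x_ref, x_gen, [0.0, 0.0]), x_gen)
        np.testing.assert_allclose(
            blend(x_ref, x_gen, [0.5, 0.5]), np.full_like(x_ref, 0.5)
        )

    def test_per_element_epsilon(self):
        x_ref = np.zeros((2, 1, 2, 2), dtype=np.float32)
        x_gen = np.ones((2, 1, 2, 2), dtype=np.float32)
        out = blend(x_ref, x_gen, [0.25, 0.75])
        np.testing.assert_allclose(out[0], 0.75)
        np.testing.assert_allclose(out[1], 0.25)


class TestGradientPenalty:
    """Closed-form checks with linear and constant critics."""

    def setup_method(self):
        rng = np.random.default_rng(0)
        self.x = rng.normal(size=(4, 3, 8, 8))
        u = rng.normal(size=(3, 8, 8))
        self.u = u / np.linalg.norm(u)

    def _linear_critic(self, scale):
        u = T.Tensor(self.u[None] * scale)

        def critic_fn(xh):
            return T.tsum(xh * u, axis=(1, 2, 3))

        return critic_fn

    def test_unit_gradient_norm_gives_zero(self):
        gp = gradient_penalty(self._linear_critic(1.0), self.x, 10.0)
        assert gp.item() == pytest.approx(0.0, abs=1e-10)

    def test_doubled_gradient_gives_lambda(self):
        gp = gradient_penalty(self._linear_critic(2.0), self.x, 10.0)
        assert gp.item() == pytest.approx(10.0 * (2 - 1) ** 2, rel=1e-7)

    def test_constant_critic_gives_lambda(self):
        def const_fn(xh):
            return T.tsum(xh * T.Tensor(np.zeros_like(self.x)), axis=(1, 2, 3))

        gp = gradient_penalty(const_fn, self.x, 7.5)
        # the sqrt's 1e-12 stabilizer bounds the zero-gradient error
        assert gp.item() == pytest.approx(7.5, abs=1e-4)

    def test_penalty_nonnegative_for_random_critic(self, tiny_critic):
        rng = np.random.default_rng(0)
        x = rng.uniform(-1, 1, (2, 3, 32, 32)).astype(np.float32)
        y_in = ConditionSet(t=[1, 2], c=[0, 1], b=[[0.1, 0.1]] * 2)
        y_gen = ConditionSet(t=[5, 6], c=[0, 1], b=[[0.4, 0.2]] * 2, role="target")
        gp = gradient_penalty(
            lambda xh: tiny_critic(xh, T.Tensor(x), y_in, y_gen), x, 10.0
        )
        assert gp.item() >= 0


class TestWganLosses:
    def _stub_batch(self, n=4):
        rng = np.random.default_rng(0)
        x = rng.uniform(-1, 1, (n, 3, 32, 32)).astype(np.float32)
        y_in = ConditionSet(t=rng.integers(0, 50, n))
        y_gen = ConditionSet(t=rng.integers(0, 50, n), role="target")
        return (x, x.copy(), y_in, y_gen)

    class _ConstCritic:
        """Critic stub returning a fixed score per image identity."""

        def __init__(self, ref_score, gen_score, ref_images):
            self.ref_score, self.gen_score = ref_score, gen_score
            self.ref = ref_images

        def __call__(self, x_cand, x_in, y_in, y_gen):
            data = x_cand.data if isinstance(x_cand, T.Tensor) else x_cand
            n = data.shape[0]
            is_ref = np.allclose(data, self.ref)
            score = self.ref_score if is_ref else self.gen_score
            out = np.full(n, float(score), dtype=np.float32)
            if isinstance(x_cand, T.Tensor) and x_cand.requires_grad:
                # keep the graph connected with zero contribution
                return T.tsum(x_cand * T.Tensor(np.zeros_like(data)), axis=(1, 2, 3)) + T.Tensor(out)
            return T.Tensor(out)

    @staticmethod
    def _t_only_generator():
        from growsim.generator import Generator

        spec, _ = tiny_specs(signature=("t",), width=8)
        return Generator(spec, np.random.default_rng(0))

    def test_score_difference_sign_convention(self):
        batch = self._stub_batch()
        critic = self._ConstCritic(ref_score=1.0, gen_score=0.0, ref_images=batch[1])
        rng = np.random.default_rng(0)
        c_loss, g_loss, gp = wgan_losses(
            batch, self._t_only_generator(), critic, lambda_gp=0.0, rng=rng
        )
        assert c_loss.item() == pytest.approx(-1.0, abs=1e-6)
        assert g_loss.item() == pytest.approx(0.0, abs=1e-6)

    def test_constant_critic_leaves_only_penalty(self):
        batch = self._stub_batch()
        critic = self._ConstCritic(ref_score=2.0, gen_score=2.0, ref_images=batch[1])
        c_loss, g_loss, gp = wgan_losses(
            batch, self._t_only_generator(), critic, lambda_gp=10.0,
            rng=np.random.default_rng(0),
        )
        # score difference cancels; only the penalty term remains
        assert c_loss.item() == pytest.approx(gp.item(), abs=1e-5)

    def test_wasserstein_term_shift_invariant(self, tiny_generator, tiny_critic):
        rng = np.random.default_rng(0)
        n = 2
        x = rng.uniform(-1, 1, (n, 3, 32, 32)).astype(np.float32)
        y_in = ConditionSet(t=[1, 2], c=[0, 1], b=[[0.1, 0.1]] * 2)
        y_gen = ConditionSet(t=[5, 6], c=[0, 1], b=[[0.2, 0.3]] * 2, role="target")
        d_ref = tiny_critic(x, x, y_in, y_gen).data
        d_gen = tiny_critic(x * 0.5, x, y_in, y_gen).data
        w1 = d_ref.mean() - d_gen.mean()
        w2 = (d_ref + 3.0).mean() - (d_gen + 3.0).mean()
        assert w1 == pytest.approx(w2, abs=1e-5)


class TestTrainLoop:
    def test_smoke_run_writes_checkpoint_and_log(self, tiny_dataset, tmp_path):
        gen_spec, critic_spec = tiny_specs(signature=("t",), width=8)
        cfg = TrainConfig(epochs=2, batch_size=8, max_val_pairs=4)
        result = train(tiny_dataset, gen_spec, critic_spec, cfg, seed=5, out_dir=tmp_path)
        assert (tmp_path / "best.npz").exists()
        assert (tmp_path / "last.npz").exists()
        assert (tmp_path / "log.jsonl").exists()
        assert len(result.log) == 2
        for entry in result.log:
            assert np.isfinite(entry["critic_loss"])

    def test_identical_seeds_reproduce_epoch1_losses(self, tiny_dataset):
        gen_spec, critic_spec = tiny_specs(signature=("t",), width=8)
        cfg = TrainConfig(epochs=1, batch_size=8, max_val_pairs=2)
        r1 = train(tiny_dataset, gen_spec, critic_spec, cfg, seed=9)
        r2 = train(tiny_dataset, gen_spec, critic_spec, cfg, seed=9)
        assert r1.log[0]["critic_loss"] == r2.log[0]["critic_loss"]
        assert r1.log[0]["generator_loss"] == r2.log[0]["generator_loss"]
        assert r1.log[0]["val_lpips"] == r2.log[0]["val_lpips"]

    def test_best_epoch_is_argmin_of_validation_curve(self, tiny_dataset):
        gen_spec, critic_spec = tiny_specs(signature=("t",), width=8)
        cfg = TrainConfig(epochs=2, batch_size=8, max_val_pairs=2)
        result = train(tiny_dataset, gen_spec, critic_spec, cfg, seed=5)
        assert result.best_epoch_is_argmin()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lambda_gp=-1.0)
        with pytest.raises(ValueError):
            TrainConfig(n_critic=0)
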