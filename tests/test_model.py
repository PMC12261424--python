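"""Encoder: linear embedding, NTK-scaled rotary positions, forward
contracts, LoRA, and the parameter count."""

import numpy as np
import pytest

from probgenome.model import (AdamW, LoraSpec, ModelConfig, ProbEncoder,
                              RopeConfig, apply_rope, count_parameters,
                              dynamic_ntk_alpha, embed_probabilistic,
                              forward_mlm, lora_trainable_count, lora_wrap,
                              ntk_scaled_base)
from probgenome.model.checkpoint import load_checkpoint, save_checkpoint
from probgenome.exceptions import FormatVersionError

TINY = dict(num_layers=2, hidden_size=16, num_heads=2,
            intermediate_size=32, train_context=64)


def _random_batch(rng, b, l):
    x = rng.random((b, 9, l))
    return x / x.sum(axis=1, keepdims=True)


class TestEmbedProbabilistic:
    def test_one_hot_equals_lookup(self):
        rng = np.random.default_rng(0)
        table = rng.normal(size=(9, 8))
        matrix = np.zeros((9, 3))
        matrix[4, 0] = matrix[7, 1] = matrix[0, 2] = 1.0
        out = embed_probabilistic(matrix, table)
        np.testing.assert_array_equal(out, table[[4, 7, 0]])

    def test_mixture_is_weighted_mean(self):
        rng = np.random.default_rng(1)
        table = rng.normal(size=(9, 8))
        matrix = np.zeros((9, 1))
        matrix[5, 0] = matrix[7, 0] = 0.5
        out = embed_probabilistic(matrix, table)
        np.testing.assert_allclose(out[0], (table[5] + table[7]) / 2)

    def test_invalid_columns_rejected(self):
        table = np.zeros((9, 4))
        with pytest.raises(ValueError):
            embed_probabilistic(np.zeros((9, 2)), table)  # zero columns
        with pytest.raises(ValueError):
            embed_probabilistic(np.zeros((4, 2)), table)  # row mismatch


class TestNtkScaling:
    @pytest.mark.parametrize("alpha0", [1.0, 1.5, 2.0, 8.0])
    def test_alpha_is_one_within_train_context(self, alpha0):
        assert dynamic_ntk_alpha(512, 512, alpha0) == 1.0
        assert dynamic_ntk_alpha(100, 512, alpha0) == 1.0

    def test_alpha_examples(self):
        assert dynamic_ntk_alpha(2048, 512, 1.0) == 4.0
        assert dynamic_ntk_alpha(1024, 512, 2.0) == 3.0

    def test_alpha_continuous_and_increasing(self):
        just_above = dynamic_ntk_alpha(513, 512, 2.0)
        assert just_above == pytest.approx(1.0, abs=0.01)
        values = [dynamic_ntk_alpha(l, 512, 2.0)
                  for l in (512, 600, 1024, 4096)]
        assert values == sorted(values)

    def test_scaled_base(self):
        assert ntk_scaled_base(10000.0, 1.0, 64) == 10000.0
        assert ntk_scaled_base(10000.0, 4.0, 64) == pytest.approx(
            10000.0 * 4.0 ** (64 / 62))
        # exponent tends to 1 for large dim
        assert ntk_scaled_base(10000.0, 4.0, 4096) == pytest.approx(
            40000.0, rel=1e-2)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            dynamic_ntk_alpha(0, 512)
        with pytest.raises(ValueError):
            ntk_scaled_base(10000.0, 2.0, 2)
        with pytest.raises(ValueError):
            ntk_scaled_base(10000.0, 2.0, 7)


class TestRope:
    def test_position_zero_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 16))
        out = apply_rope(x, np.array([0]))
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_norm_preserved(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(5, 32))
        out = apply_rope(x, np.arange(5) * 17, theta=10000.0)
        np.testing.assert_allclose(np.linalg.norm(out, axis=-1),
                                   np.linalg.norm(x, axis=-1), atol=1e-9)

    def test_relative_position_property(self):
        """q(t1).k(t2) depends only on t1 - t2, across 100 random pairs."""
        rng = np.random.default_rng(2)
        q = rng.normal(size=32)
        k = rng.normal(size=32)
        for _ in range(100):
            t1, t2 = rng.integers(0, 2000, size=2)
            shift = int(rng.integers(0, 500))
            dot_a = apply_rope(q[None], [t1])[0] @ apply_rope(
                k[None], [t2])[0]
            dot_b = apply_rope(q[None], [t1 + shift])[0] @ apply_rope(
                k[None], [t2 + shift])[0]
            assert dot_a == pytest.approx(dot_b, abs=1e-6)

    def test_odd_dim_rejected(self):
        with pytest.raises(ValueError):
            apply_rope(np.zeros((1, 15)), [0])


class TestForward:
    def test_rows_are_distributions(self):
        model = ProbEncoder(ModelConfig(**TINY), seed=0)
        x = _random_batch(np.random.default_rng(3), 2, 12)
        probs = forward_mlm(model, x)
        assert probs.shape == (2, 12, 9)
        assert np.all(probs > 0)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)

    def test_eval_mode_deterministic(self):
        model = ProbEncoder(ModelConfig(**TINY), seed=0)
        x = _random_batch(np.random.default_rng(4), 2, 10)
        a = forward_mlm(model, x)
        b = forward_mlm(model, x)
        np.testing.assert_array_equal(a, b)

    def test_same_seed_same_model(self):
        cfg = ModelConfig(**TINY)
        x = _random_batch(np.random.default_rng(5), 1, 8)
        a = forward_mlm(ProbEncoder(cfg, seed=9), x)
        b = forward_mlm(ProbEncoder(cfg, seed=9), x)
        np.testing.assert_array_equal(a, b)

    def test_batch_permutation_equivariance(self):
        model = ProbEncoder(ModelConfig(**TINY), seed=0)
        x = _random_batch(np.random.default_rng(6), 4, 10)
        perm = np.array([2, 0, 3, 1])
        out = forward_mlm(model, x)
        out_perm = forward_mlm(model, x[perm])
        np.testing.assert_allclose(out_perm, out[perm], atol=1e-6)

    def test_invalid_columns_rejected(self):
        model = ProbEncoder(ModelConfig(**TINY), seed=0)
        bad = np.zeros((1, 9, 5))
        with pytest.raises(ValueError):
            model.forward(bad)

    def test_hard_cap_enforced(self):
        model = ProbEncoder(ModelConfig(**TINY), seed=0)
        from probgenome.model.encoder import MAX_CONTEXT
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 9, MAX_CONTEXT + 1)))

    def test_padding_mask_isolates_content(self):
        """Adding PAD columns behind a mask must not change the
        unpadded positions' outputs."""
        model = ProbEncoder(ModelConfig(**TINY), seed=0)
        rng = np.random.default_rng(7)
        x = _random_batch(rng, 1, 8)
        padded = np.zeros((1, 9, 12))
        padded[:, :, :8] = x
        padded[:, 0, 8:] = 1.0
        mask = np.zeros((1, 12), dtype=bool)
        mask[:, :8] = True
        a = forward_mlm(model, x)
        b = forward_mlm(model, padded, attn_mask=mask)
        np.testing.assert_allclose(b[:, :8], a, atol=1e-5)


class TestCountParameters:
    def test_small_config_matches_instantiated_model(self):
        cfg = ModelConfig(num_layers=1, hidden_size=8, num_heads=2,
                          intermediate_size=16, train_context=16)
        model = ProbEncoder(cfg, seed=0)
        assert count_parameters(cfg) == model.trainable_parameter_count()

    def test_small_config_matches_hand_enumeration(self):
        d, inner, v = 8, 16, 9
        hand = (
            (v * d + d)                    # input linear
            + 4 * (d * d + d)              # q,k,v,o
            + 2 * (2 * d)                  # block norms
            + (d * inner + inner) + (inner * d + d)  # ffn
            + 2 * d                        # final norm
            + (d * d + d) + 2 * d + (d * v + v)      # head
        )
        cfg = ModelConfig(num_layers=1, hidden_size=d, num_heads=2,
                          intermediate_size=inner, train_context=16)
        assert count_parameters(cfg) == hand

    def test_default_geometry_rounds_to_86_million(self):
        assert round(count_parameters(ModelConfig()) / 1e6) == 86

    def test_doubling_inner_changes_only_ffn_term(self):
        base = ModelConfig(num_layers=3, hidden_size=32, num_heads=2,
                           intermediate_size=64, train_context=16)
        double = ModelConfig(num_layers=3, hidden_size=32, num_heads=2,
                             intermediate_size=128, train_context=16)
        per_layer_delta = (32 * 64 + 64) + (64 * 32)
        assert (count_parameters(double) - count_parameters(base)
                == 3 * per_layer_delta)


class TestLora:
    def test_wrapped_model_forward_identical_at_init(self):
        model = ProbEncoder(ModelConfig(**TINY), seed=0)
        x = _random_batch(np.random.default_rng(8), 2, 10)
        before = forward_mlm(model, x)
        lora_wrap(model, LoraSpec(rank=2), seed=1)
        after = forward_mlm(model, x)
        np.testing.assert_array_equal(before, after)

    def test_trainable_count_formula(self):
        assert lora_trainable_count(768, 768, 8) == 12_288
        model = ProbEncoder(ModelConfig(**TINY), seed=0)
        wrapped = lora_wrap(model, LoraSpec(rank=2), seed=1)
        d = 16
        expected = len(wrapped) * lora_trainable_count(d, d, 2)
        assert model.trainable_parameter_count() == expected

    def test_only_adapters_change_after_step(self):
        model = ProbEncoder(ModelConfig(**TINY), seed=0)
        lora_wrap(model, LoraSpec(rank=2), seed=1)
        snapshot = {p.name: p.value.copy() for p in model.parameters()}
        x = _random_batch(np.random.default_rng(9), 2, 10)
        logits = model.forward(x)
        opt = AdamW(model.parameters(), lr=1e-2)
        opt.zero_grad()
        model.backward(np.ones_like(logits) / logits.size)
        opt.step()
        for p in model.parameters():
            changed = not np.array_equal(snapshot[p.name], p.value)
            assert changed == (".lora." in p.name), p.name

    def test_rank_above_min_dimension_rejected(self):
        model = ProbEncoder(ModelConfig(**TINY), seed=0)
        with pytest.raises(ValueError):
            lora_wrap(model, LoraSpec(rank=17), seed=0)  # rank > min(m,n)

    def test_full_rank_adapter_can_fit_arbitrary_update(self):
        """A rank-min(m,n) factorization reaches any dense 8x8 update."""
        from probgenome.model.layers import Linear, LoRALinear
        rng = np.random.default_rng(10)
        base = Linear(8, 8, rng, name="w")
        target_delta = rng.normal(size=(8, 8)) * 0.1
        target_w = base.W.value + target_delta
        adapter = LoRALinear(base, rank=8, rng=rng)
        x = rng.normal(size=(64, 8))
        y = x @ target_w + base.b.value
        opt = AdamW([adapter.A, adapter.B], lr=5e-2, weight_decay=0.0)
        for _ in range(400):
            pred = adapter.forward(x)
            opt.zero_grad()
            adapter.backward(2 * (pred - y) / len(x))
            opt.step()
        np.testing.assert_allclose(adapter.effective_weight(), target_w,
                                   atol=1e-2)


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        model = ProbEncoder(ModelConfig(**TINY), RopeConfig(theta0=500.0),
                            seed=0)
        x = _random_batch(np.random.default_rng(11), 1, 9)
        before = forward_mlm(model, x)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, step=42)
        loaded, step = load_checkpoint(path)
        assert step == 42
        assert loaded.rope.theta0 == 500.0
        np.testing.assert_array_equal(forward_mlm(loaded, x), before)

    def test_bad_file_rejected(self, tmp_path):
        path = tmp_path / "junk.npz"
        np.savez(path, x=np.arange(3))
        with pytest.raises(FormatVersionError):
            load_checkpoint(path)

    def test_resumption_restores_optimizer_state(self, tmp_path):
        model = ProbEncoder(ModelConfig(**TINY), seed=0)
        opt = AdamW(model.parameters(), lr=1e-3)
        x = _random_batch(np.random.default_rng(12), 1, 8)
        logits = model.forward(x)
        opt.zero_grad()
        model.backward(np.ones_like(logits) / logits.size)
        opt.step()
        path = tmp_path / "resume.npz"
        save_checkpoint(path, model, optimizer=opt, step=1)

        restored, step = load_checkpoint(path)
        opt2 = AdamW(restored.parameters(), lr=1e-3)
        load_checkpoint(path, optimizer=opt2)
        assert step == 1 and opt2.t == opt.t
        for m1, m2 in zip(opt.state_dict()["m"], opt2.state_dict()["m"]):
            np.testing.assert_array_equal(m1, m2)
        # one more identical step on both yields identical weights
        for mdl, o in ((model, opt), (restored, opt2)):
            lg = mdl.forward(x)
            o.zero_grad()
            mdl.backward(np.ones_like(lg) / lg.size)
            o.step()
        for p1, p2 in zip(model.parameters(), restored.parameters()):
            np.testing.assert_array_equal(p1.value, p2.value)
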