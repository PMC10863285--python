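"""Architecture contracts: residual units, attention, inception, assembly, counts."""

import numpy as np
import pytest

from conftest import tiny_model_config
from ssbscan.network import (
    ConsistencyError,
    Conv1d,
    InceptionCenterBlock,
    ModelConfig,
    MultiHeadSelfAttention,
    ResidualUnit,
    SSBModel,
    assemble_model,
    count_parameters,
    forward_predict,
    load_checkpoint,
    save_checkpoint,
)
from ssbscan.network import autodiff as ad


def brute_conv1d(x, w, b):
    """Direct sliding-dot-product same-padded convolution (oracle)."""
    B, C_in, L = x.shape
    C_out, _, k = w.shape
    pad = (k - 1) // 2
    out = np.zeros((B, C_out, L))
    for bi in range(B):
        for co in range(C_out):
            for pos in range(L):
                acc = b[co]
                for ci in range(C_in):
                    for j in range(k):
                        src = pos + j - pad
                        if 0 <= src < L:
                            acc += x[bi, ci, src] * w[co, ci, j]
                out[bi, co, pos] = acc
    return out


class TestConvOracle:
    def test_conv_matches_brute_force(self):
        rng = np.random.default_rng(1)
        conv = Conv1d(rng, 1, 1, 5)
        conv.w.data = rng.normal(size=(1, 1, 5)).astype(np.float32)
        conv.b.data = rng.normal(size=1).astype(np.float32)
        x = rng.normal(size=(1, 1, 7)).astype(np.float32)
        got = conv(ad.constant(x)).data
        want = brute_conv1d(x, conv.w.data, conv.b.data)
        assert np.allclose(got, want, atol=1e-5)

    def test_conv_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        conv = Conv1d(rng, 2, 3, 3)
        x = rng.normal(size=(1, 2, 6)).astype(np.float32)
        t = ad.Tensor(x, requires_grad=True)
        ad.sum_all(conv(t)).backward()
        eps = 1e-3
        for idx in [(0, 0, 0), (0, 1, 3), (0, 0, 5)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            fd = (conv(ad.constant(xp)).data.sum() - conv(ad.constant(xm)).data.sum()) / (2 * eps)
            assert abs(fd - t.grad[idx]) < 1e-2


class TestResidualUnit:
    def test_zero_branch_is_elu_identity(self):
        rng = np.random.default_rng(0)
        unit = ResidualUnit(rng, 16)
        for conv in (unit.conv_a, unit.conv_b):
            conv.w.data[:] = 0
            conv.b.data[:] = 0
        x = np.abs(np.random.default_rng(1).normal(size=(2, 16, 20))).astype(np.float32)
        out = unit(ad.constant(x)).data
        assert np.allclose(out, x, atol=1e-6)  # ELU(x) = x for x >= 0

    def test_shape_preserved(self):
        unit = ResidualUnit(np.random.default_rng(0), 16)
        x = np.random.default_rng(1).normal(size=(3, 16, 251)).astype(np.float32)
        assert unit(ad.constant(x)).data.shape == (3, 16, 251)

    def test_channel_mismatch_raises(self):
        unit = ResidualUnit(np.random.default_rng(0), 16)
        x = np.zeros((1, 8, 20), dtype=np.float32)
        with pytest.raises(ValueError, match="channel mismatch"):
            unit(ad.constant(x))


def brute_attention(x, mha):
    """Literal per-head attention equation (oracle)."""
    h, dk, dv, d = mha.heads, mha.d_k, mha.d_v, mha.d_model
    Wq, bq = mha.wq.w.data, mha.wq.b.data
    Wk, bk = mha.wk.w.data, mha.wk.b.data
    Wv, bv = mha.wv.w.data, mha.wv.b.data
    Wo, bo = mha.wo.w.data, mha.wo.b.data
    B, L, _ = x.shape
    out = np.zeros((B, L, d))
    for bi in range(B):
        heads = []
        for i in range(h):
            q = x[bi] @ Wq[:, i * dk:(i + 1) * dk] + bq[i * dk:(i + 1) * dk]
            k = x[bi] @ Wk[:, i * dk:(i + 1) * dk] + bk[i * dk:(i + 1) * dk]
            v = x[bi] @ Wv[:, i * dv:(i + 1) * dv] + bv[i * dv:(i + 1) * dv]
            logits = q @ k.T / np.sqrt(dk)
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            a = e / e.sum(axis=1, keepdims=True)
            heads.append(a @ v)
        out[bi] = np.concatenate(heads, axis=1) @ Wo + bo
    return out


class TestAttention:
    def test_single_position_ignores_query_and_key(self):
        rng = np.random.default_rng(3)
        mha = MultiHeadSelfAttention(rng, d_model=4, heads=2, d_k=3, d_v=3)
        x = rng.normal(size=(2, 1, 4)).astype(np.float32)
        got = mha(ad.constant(x)).data
        # softmax over one key is 1 regardless of W^Q, W^K
        mha.wq.w.data[:] = 0
        mha.wk.w.data[:] = 0
        unchanged = mha(ad.constant(x)).data
        assert np.allclose(got, unchanged, atol=1e-6)

    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        mha = MultiHeadSelfAttention(rng, d_model=6, heads=3, d_k=5, d_v=5)
        x = rng.normal(size=(2, 7, 6)).astype(np.float32)
        weights = mha.attention_weights(x)
        assert weights.shape == (2, 3, 7, 7)
        assert np.allclose(weights.sum(axis=-1), 1.0, atol=1e-6)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(5)
        mha = MultiHeadSelfAttention(rng, d_model=2, heads=1, d_k=2, d_v=2)
        x = rng.normal(size=(1, 3, 2)).astype(np.float32)
        got = mha(ad.constant(x)).data
        assert np.allclose(got, brute_attention(x, mha), atol=1e-5)

    def test_multi_head_matches_oracle(self):
        rng = np.random.default_rng(6)
        mha = MultiHeadSelfAttention(rng, d_model=6, heads=3, d_k=11, d_v=7)
        x = rng.normal(size=(2, 5, 6)).astype(np.float32)
        assert np.allclose(mha(ad.constant(x)).data, brute_attention(x, mha), atol=1e-4)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        mha = MultiHeadSelfAttention(rng, d_model=4, heads=2, d_k=4, d_v=4)
        x = rng.normal(size=(1, 6, 4)).astype(np.float32)
        perm = rng.permutation(6)
        out = mha(ad.constant(x)).data
        out_perm = mha(ad.constant(x[:, perm, :])).data
        assert np.allclose(out_perm, out[:, perm, :], atol=1e-5)


class TestInception:
    def test_output_shape(self):
        block = InceptionCenterBlock(np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(2, 4, 9)).astype(np.float32)
        assert block(ad.constant(x)).data.shape == (2, 16, 9)

    def test_zero_weight_layout(self):
        block = InceptionCenterBlock(np.random.default_rng(0))
        biases = []
        for i, branch in enumerate(block.branches):
            branch.w.data[:] = 0
            branch.b.data[:] = float(i + 1)
            biases.append(float(i + 1))
        x = np.random.default_rng(1).normal(size=(1, 4, 9)).astype(np.float32)
        out = block(ad.constant(x)).data
        assert np.allclose(out[0, 12:16], x[0], atol=1e-6)  # original encoding
        for i in range(3):
            assert np.allclose(out[0, 4 * i : 4 * i + 4], biases[i], atol=1e-6)

    def test_branch_matches_brute_convolution(self):
        rng = np.random.default_rng(2)
        block = InceptionCenterBlock(rng)
        x = rng.normal(size=(1, 4, 9)).astype(np.float32)
        out = block(ad.constant(x)).data
        for i, branch in enumerate(block.branches):
            want = brute_conv1d(x, branch.w.data, branch.b.data)
            assert np.allclose(out[:, 4 * i : 4 * i + 4], want, atol=1e-5)


def closed_form_count(cfg: ModelConfig) -> int:
    """Per-layer parameter arithmetic: C_out*C_in*k + C_out for convs, etc."""
    c1, c2 = cfg.stage_filters
    k5, k3 = cfg.unit_kernels
    n = 0
    n += c1 * 4 * cfg.stem_kernel + c1
    n += cfg.blocks_per_stage * (c1 * c1 * k5 + c1 + c1 * c1 * k3 + c1)
    n += c2 * c1 + c2
    n += cfg.blocks_per_stage * (c2 * c2 * k5 + c2 + c2 * c2 * k3 + c2)
    n += cfg.full_d_model * c2 + cfg.full_d_model

    def attn(d_model):
        qkv = 3 * (d_model * cfg.heads * cfg.d_k + cfg.heads * cfg.d_k)
        return qkv + cfg.heads * cfg.d_v * d_model + d_model

    n += attn(cfg.full_d_model)
    bf = cfg.center_branch_filters
    n += sum(bf * 4 * k + bf for k in cfg.center_inception_kernels)
    if cfg.center_attention:
        n += attn(cfg.center_d_model)
    full_feat = (cfg.full_length // cfg.pool_width) * cfg.full_d_model
    center_feat = cfg.center_d_model * cfg.center_length
    h1, h2 = cfg.mlp_hidden
    n += (full_feat + center_feat) * h1 + h1 + h1 * h2 + h2 + h2 * 1 + 1
    return n


class TestAssembly:
    def test_scores_in_unit_interval_for_batch_of_two(self):
        model = assemble_model(tiny_model_config())
        rng = np.random.default_rng(0)
        full = rng.random((2, 4, 251)).astype(np.float32)
        center = full[:, :, model.center_slice()]
        scores = forward_predict(model, full, center)
        assert scores.shape == (2,)
        assert np.all(scores >= 0) and np.all(scores <= 1)

    def test_default_parameter_count_rounds_to_1p9_million(self):
        model = assemble_model(ModelConfig())
        n = count_parameters(model)
        assert round(n / 1e6, 1) == 1.9

    def test_tiny_config_count_matches_closed_form(self):
        cfg = tiny_model_config(d_k=4, d_v=4, mlp_hidden=(4, 2))
        assert count_parameters(assemble_model(cfg)) == closed_form_count(cfg)

    def test_default_count_matches_closed_form(self):
        cfg = ModelConfig()
        assert count_parameters(assemble_model(cfg)) == closed_form_count(cfg)

    def test_count_is_pure_function_of_config(self):
        cfg = tiny_model_config(seed=9)
        assert count_parameters(assemble_model(cfg)) == count_parameters(assemble_model(cfg))

    def test_single_bias_free_conv_count(self):
        conv = Conv1d(np.random.default_rng(0), 4, 16, 1)
        assert conv.w.data.size == 64

    def test_pooling_is_only_length_change(self):
        model = assemble_model(tiny_model_config())
        x = ad.constant(np.random.default_rng(0).random((1, 4, 251)).astype(np.float32))
        h = model.stem(x)
        for unit in model.stage1:
            h = unit(h)
        h = model.transition(h)
        for unit in model.stage2:
            h = unit(h)
        assert h.data.shape[-1] == 251
        assert ad.avg_pool1d(h, 5).data.shape[-1] == 50


class TestForwardPredict:
    def test_duplicated_rows_score_identically(self, tiny_model):
        rng = np.random.default_rng(1)
        row = rng.random((1, 4, 251)).astype(np.float32)
        full = np.concatenate([row, row, rng.random((1, 4, 251)).astype(np.float32)])
        scores = tiny_model.predict(full)
        assert scores[0] == scores[1]

    def test_eval_mode_is_bit_deterministic(self, tiny_model):
        x = np.random.default_rng(2).random((4, 4, 251)).astype(np.float32)
        assert np.array_equal(tiny_model.predict(x), tiny_model.predict(x))

    def test_batch_permutation_permutes_outputs(self, tiny_model):
        rng = np.random.default_rng(3)
        x = rng.random((6, 4, 251)).astype(np.float32)
        perm = rng.permutation(6)
        assert np.allclose(tiny_model.predict(x)[perm], tiny_model.predict(x[perm]),
                           atol=1e-6)

    def test_center_mismatch_raises(self, tiny_model):
        x = np.random.default_rng(4).random((2, 4, 251)).astype(np.float32)
        bad_center = np.zeros((2, 4, 9), dtype=np.float32)
        with pytest.raises(ConsistencyError):
            forward_predict(tiny_model, x, bad_center)


class TestGradientFlow:
    def test_loss_decreases_after_one_adam_step(self):
        from ssbscan.training import Adam, _bce_loss

        model = assemble_model(tiny_model_config(seed=2))
        x = np.random.default_rng(0).random((1, 4, 251)).astype(np.float32)
        y = np.array([1])

        def loss_value():
            return float(_bce_loss(model.forward(ad.constant(x)), y).data)

        before = loss_value()
        opt = Adam(model.parameters(), lr=1e-3)
        scores = model.forward(ad.constant(x))
        loss = _bce_loss(scores, y)
        model.zero_grad()
        loss.backward()
        opt.step()
        assert loss_value() < before


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tiny_model, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_model, path)
        loaded = load_checkpoint(path)
        x = np.random.default_rng(5).random((3, 4, 251)).astype(np.float32)
        assert np.array_equal(tiny_model.predict(x), loaded.predict(x))
        assert loaded.config == tiny_model.config
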