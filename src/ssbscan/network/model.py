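"""The two-stream break-site classifier.

Full stream (251 bp one-hot): 1x3 stem convolution -> residual stage 1
(16 filters) -> 1x1 transition -> residual stage 2 (32 filters) -> 1x5 average
pooling (251 -> 50) -> 1x1 projection to d_model = 64 -> multi-head
self-attention -> flatten.  Each residual unit is a 1x5 then 1x3 same-padded
convolution with an identity skip; ELU activations throughout.

Center stream (middle 9 bp): single-layer inception block (parallel 1x1 / 1x3 /
1x5 convolutions, 4 filters each, concatenated with the original one-hot rows
to 16 channels) -> multi-head self-attention (d_model = 16) -> flatten.

Both feature vectors are concatenated and fed to an MLP (two hidden layers,
dropout 0.5 / 0.3) ending in a sigmoid, so scores live in [0, 1].
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


@dataclass(frozen=True)
class ModelConfig:
    """All architecture hyperparameters, with resolved defaults."""

    full_length: int = 251
    center_length: int = 9
    stem_kernel: int = 3
    blocks_per_stage: int = 15
    stage_filters: tuple[int, int] = (16, 32)
    unit_kernels: tuple[int, int] = (5, 3)
    pool_width: int = 5
    heads: int = 8
    d_k: int = 512
    d_v: int = 512
    full_d_model: int = 64
    center_inception_kernels: tuple[int, int, int] = (1, 3, 5)
    center_branch_filters: int = 4
    mlp_hidden: tuple[int, int] = (128, 64)
    dropout: tuple[float, float] = (0.5, 0.3)
    center_attention: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.full_length % 2 == 0 or self.center_length % 2 == 0:
            raise ValueError("full_length and center_length must be odd")
        if self.center_length > self.full_length:
            raise ValueError("center_length must not exceed full_length")
        if not all(0.0 <= p < 1.0 for p in self.dropout):
            raise ValueError("dropout rates must lie in [0, 1)")
        for name in ("stem_kernel", "blocks_per_stage", "pool_width", "heads",
                     "d_k", "d_v", "full_d_model", "center_branch_filters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def center_d_model(self) -> int:
        return 3 * self.center_branch_filters + 4

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        for key in ("stage_filters", "unit_kernels", "center_inception_kernels",
                    "mlp_hidden", "dropout"):
            d[key] = tuple(d[key])
        return cls(**d)


# a compact, commonly used reduced configuration for CPU-scale experiments
def reduced_config(blocks_per_stage: int = 4, **overrides) -> ModelConfig:
    return ModelConfig(blocks_per_stage=blocks_per_stage, **overrides)


def _he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = float(np.sqrt(6.0 / fan_in))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv1d:
    def __init__(self, rng, c_in: int, c_out: int, k: int):
        self.w = ad.parameter(_he_uniform(rng, (c_out, c_in, k), c_in * k))
        self.b = ad.parameter(np.zeros(c_out, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv1d(x, self.w, self.b)

    def parameters(self):
        return [self.w, self.b]


class Linear:
    def __init__(self, rng, d_in: int, d_out: int):
        self.w = ad.parameter(_he_uniform(rng, (d_in, d_out), d_in))
        self.b = ad.parameter(np.zeros(d_out, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.w), self.b)

    def parameters(self):
        return [self.w, self.b]


class ResidualUnit:
    """out = ELU(x + conv_1x3(ELU(conv_1x5(x)))); shape-preserving.

    The branch's second convolution is initialized with a 1/sqrt(2 * depth)
    scale (Fixup-style) so that activation variance stays bounded through a
    deep unnormalized residual stack.
    """

    def __init__(self, rng, channels: int, kernels: tuple[int, int] = (5, 3),
                 init_scale: float = 1.0):
        self.conv_a = Conv1d(rng, channels, channels, kernels[0])
        self.conv_b = Conv1d(rng, channels, channels, kernels[1])
        if init_scale != 1.0:
            self.conv_b.w.data *= np.float32(init_scale)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv_b(ad.elu(self.conv_a(x)))
        return ad.elu(ad.add(x, h))

    def parameters(self):
        return self.conv_a.parameters() + self.conv_b.parameters()


class MultiHeadSelfAttention:
    """Scaled dot-product self-attention over an (B, L, d_model) input.

    head_i = Softmax(M W_i^Q (M W_i^K)^T / sqrt(d_k)) M W_i^V;
    output = Concat(head_1..head_h) W^O, back to (B, L, d_model).
    """

    def __init__(self, rng, d_model: int, heads: int, d_k: int, d_v: int):
        self.d_model, self.heads, self.d_k, self.d_v = d_model, heads, d_k, d_v
        self.wq = Linear(rng, d_model, heads * d_k)
        self.wk = Linear(rng, d_model, heads * d_k)
        self.wv = Linear(rng, d_model, heads * d_v)
        self.wo = Linear(rng, heads * d_v, d_model)

    def attention_weights(self, x: np.ndarray) -> np.ndarray:
        """Softmax attention maps (B, h, L, L) for a raw input array (no grad)."""
        t = ad.constant(x)
        return self._scores(t).data

    def _per_head(self, lin: Linear, d_head: int) -> tuple[Tensor, Tensor]:
        """Reshape a (d_model, h*d_head) projection into per-head (h, d_model, d_head)."""
        w = ad.transpose(ad.reshape(lin.w, (self.d_model, self.heads, d_head)),
                         (1, 0, 2))
        b = ad.reshape(lin.b, (self.heads, 1, d_head))
        return w, b

    def _scores(self, x: Tensor) -> Tensor:
        """Softmax((x Wq + bq)(x Wk + bk)^T / sqrt(d_k)) per head.

        Evaluated in the factored form x (Wq Wk^T) x^T + rank-one bias terms,
        which is algebraically identical to projecting into d_k dimensions but
        never materializes the (B, L, h*d_k) arrays (d_k >> d_model here).
        """
        B, L, _ = x.shape
        wq, bq = self._per_head(self.wq, self.d_k)
        wk, bk = self._per_head(self.wk, self.d_k)
        scale = 1.0 / np.sqrt(self.d_k)
        core = ad.matmul(wq, ad.transpose(wk, (0, 2, 1)))  # (h, d_model, d_model)
        x1 = ad.reshape(x, (B, 1, L, self.d_model))
        xt = ad.transpose(x1, (0, 1, 3, 2))
        logits = ad.matmul(ad.matmul(x1, ad.reshape(core, (1, self.heads,
                                                           self.d_model, self.d_model))),
                           xt)  # (B, h, L, L)
        # bias cross-terms: (x Wq) bk^T varies per row, bq (x Wk)^T per column;
        # folding the bias into the weight first keeps everything d_model-sized
        w_qb = ad.matmul(wq, ad.transpose(bk, (0, 2, 1)))  # (h, d_model, 1)
        w_kb = ad.matmul(wk, ad.transpose(bq, (0, 2, 1)))
        row = ad.matmul(x1, ad.reshape(w_qb, (1, self.heads, self.d_model, 1)))
        col = ad.matmul(x1, ad.reshape(w_kb, (1, self.heads, self.d_model, 1)))
        const = ad.matmul(bq, ad.transpose(bk, (0, 2, 1)))  # (h, 1, 1)
        logits = ad.add(ad.add(logits, row), ad.transpose(col, (0, 1, 3, 2)))
        logits = ad.add(logits, ad.reshape(const, (1, self.heads, 1, 1)))
        return ad.softmax(ad.mul(logits, scale), axis=-1)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        attn = self._scores(x)
        # ctx_i = attn_i (x Wv_i + bv_i); softmax rows sum to 1, so the bias
        # passes through untouched: out = sum_i attn_i x (Wv_i Wo_i) + bv Wo + bo
        wv, _ = self._per_head(self.wv, self.d_v)
        wo_h = ad.reshape(self.wo.w, (self.heads, self.d_v, self.d_model))
        mix = ad.matmul(wv, wo_h)  # (h, d_model, d_model)
        x1 = ad.reshape(x, (B, 1, L, self.d_model))
        z = ad.matmul(x1, ad.reshape(mix, (1, self.heads, self.d_model, self.d_model)))
        y = ad.sum_axis(ad.matmul(attn, z), 1)  # (B, L, d_model)
        bias = ad.add(ad.matmul(ad.reshape(self.wv.b, (1, self.heads * self.d_v)),
                                self.wo.w), self.wo.b)
        return ad.add(y, ad.reshape(bias, (1, 1, self.d_model)))

    def parameters(self):
        return (self.wq.parameters() + self.wk.parameters()
                + self.wv.parameters() + self.wo.parameters())


class InceptionCenterBlock:
    """Parallel 1x1/1x3/1x5 convolutions (4 filters each) concatenated with the input.

    Output channel layout: [branch_1x1, branch_1x3, branch_1x5, original 4 rows],
    i.e. 16 channels at the center length.
    """

    def __init__(self, rng, kernels=(1, 3, 5), branch_filters: int = 4):
        self.branches = [Conv1d(rng, 4, branch_filters, k) for k in kernels]

    def __call__(self, x: Tensor) -> Tensor:
        outs = [branch(x) for branch in self.branches]
        return ad.concat(outs + [x], axis=1)

    def parameters(self):
        return [p for branch in self.branches for p in branch.parameters()]


class ConsistencyError(ValueError):
    """center batch does not equal the middle columns of the full batch."""


class SSBModel:
    """The assembled two-stream network; use :func:`assemble_model` to build one."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c1, c2 = config.stage_filters
        branch_scale = 1.0 / np.sqrt(2.0 * config.blocks_per_stage)
        self.stem = Conv1d(rng, 4, c1, config.stem_kernel)
        self.stage1 = [ResidualUnit(rng, c1, config.unit_kernels, branch_scale)
                       for _ in range(config.blocks_per_stage)]
        self.transition = Conv1d(rng, c1, c2, 1)
        self.stage2 = [ResidualUnit(rng, c2, config.unit_kernels, branch_scale)
                       for _ in range(config.blocks_per_stage)]
        self.projection = Conv1d(rng, c2, config.full_d_model, 1)
        self.full_attention = MultiHeadSelfAttention(
            rng, config.full_d_model, config.heads, config.d_k, config.d_v)
        self.inception = InceptionCenterBlock(
            rng, config.center_inception_kernels, config.center_branch_filters)
        self.center_attention = (
            MultiHeadSelfAttention(rng, config.center_d_model, config.heads,
                                   config.d_k, config.d_v)
            if config.center_attention else None)

        pooled = config.full_length // config.pool_width
        full_feat = pooled * config.full_d_model
        center_feat = config.center_d_model * config.center_length
        h1, h2 = config.mlp_hidden
        self.fc1 = Linear(rng, full_feat + center_feat, h1)
        self.fc2 = Linear(rng, h1, h2)
        self.fc3 = Linear(rng, h2, 1)

    # -- plumbing ----------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        params = self.stem.parameters()
        for unit in self.stage1:
            params += unit.parameters()
        params += self.transition.parameters()
        for unit in self.stage2:
            params += unit.parameters()
        params += self.projection.parameters()
        params += self.full_attention.parameters()
        params += self.inception.parameters()
        if self.center_attention is not None:
            params += self.center_attention.parameters()
        params += self.fc1.parameters() + self.fc2.parameters() + self.fc3.parameters()
        return params

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list does not match the architecture")
        for p, w in zip(params, weights):
            if p.data.shape != w.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {w.shape}")
            p.data = np.ascontiguousarray(w, dtype=np.float32)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- forward -----------------------------------------------------------
    def center_slice(self) -> slice:
        mid = self.config.full_length // 2
        half = self.config.center_length // 2
        return slice(mid - half, mid + half + 1)

    def forward(self, full: Tensor, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Scores in [0, 1] for a (B, 4, full_length) one-hot batch.

        The center stream input is taken as a differentiable view of the
        middle columns, so attribution gradients flow through both streams
        onto the same genomic window.
        """
        return ad.sigmoid(self.forward_logits(full, train=train, rng=rng))

    def forward_logits(self, full: Tensor, train: bool = False,
                       rng: np.random.Generator | None = None) -> Tensor:
        """Pre-sigmoid logits; the training loss is computed from these for
        numerical stability."""
        cfg = self.config
        if train and rng is None:
            raise ValueError("training-mode forward needs a dropout rng")
        x = self.stem(full)
        for unit in self.stage1:
            x = unit(x)
        x = self.transition(x)
        for unit in self.stage2:
            x = unit(x)
        x = ad.avg_pool1d(x, cfg.pool_width)
        x = self.projection(x)
        x = ad.transpose(x, (0, 2, 1))  # (B, L_pool, d_model)
        x = self.full_attention(x)
        B = full.shape[0]
        full_feat = ad.reshape(x, (B, -1))

        sl = self.center_slice()
        center = ad.slice_axis(full, 2, sl.start, sl.stop)
        c = self.inception(center)
        if self.center_attention is not None:
            c = ad.transpose(c, (0, 2, 1))
            c = self.center_attention(c)
            center_feat = ad.reshape(c, (B, -1))
        else:
            center_feat = ad.reshape(c, (B, -1))

        h = ad.concat([full_feat, center_feat], axis=1)
        h = ad.elu(self.fc1(h))
        if train:
            h = ad.dropout(h, cfg.dropout[0], rng)
        h = ad.elu(self.fc2(h))
        if train:
            h = ad.dropout(h, cfg.dropout[1], rng)
        return ad.reshape(self.fc3(h), (B,))

    def predict(self, full: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Eval-mode scores for a (N, 4, full_length) array, batched."""
        full = np.asarray(full, dtype=np.float32)
        out = np.empty(full.shape[0], dtype=np.float32)
        for lo in range(0, full.shape[0], batch_size):
            batch = ad.constant(full[lo : lo + batch_size])
            out[lo : lo + batch.shape[0]] = self.forward(batch).data
        return out


def assemble_model(config: ModelConfig | None = None) -> SSBModel:
    """Build the (untrained) two-stream model with seeded initialization."""
    return SSBModel(config or ModelConfig())


def count_parameters(model: SSBModel) -> int:
    """Total number of trainable scalar parameters."""
    return int(sum(p.data.size for p in model.parameters()))


def forward_predict(model: SSBModel, full_batch: np.ndarray,
                    center_batch: np.ndarray) -> np.ndarray:
    """Eval-mode scores; verifies the center batch is the middle of the full batch."""
    full_batch = np.asarray(full_batch, dtype=np.float32)
    center_batch = np.asarray(center_batch, dtype=np.float32)
    sl = model.center_slice()
    if not np.array_equal(full_batch[:, :, sl], center_batch):
        raise ConsistencyError(
            "center batch must equal the middle columns of the full batch")
    return model.predict(full_batch)


# ---------------------------------------------------------------------------
# Checkpointing: a single .npz archive holding config JSON + weights
# ---------------------------------------------------------------------------


def _config_hash(config_json: str) -> str:
    return hashlib.sha256(config_json.encode()).hexdigest()


def save_checkpoint(model: SSBModel, path: str | Path) -> None:
    cfg_json = model.config.to_json()
    arrays = {f"w{i:04d}": w for i, w in enumerate(model.get_weights())}
    np.savez(path, config=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
             config_hash=np.frombuffer(_config_hash(cfg_json).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path) -> SSBModel:
    with np.load(path) as npz:
        cfg_json = bytes(npz["config"]).decode()
        stored_hash = bytes(npz["config_hash"]).decode()
        if _config_hash(cfg_json) != stored_hash:
            raise ValueError(f"checkpoint {path} failed its config integrity check")
        model = SSBModel(ModelConfig.from_json(cfg_json))
        weights = [npz[k] for k in sorted(k for k in npz.files if k.startswith("w"))]
    model.set_weights(weights)
    return model
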