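"""The selective-kernel / squeeze-axial attention transformer (SKS-Transformer).

The classifier consumes a normalized window of tri-axial inertial samples,
``X ∈ R^{T×D}``, and produces activity-class probabilities. The computation:

1. A learnable linear projection lifts each timestep to a ``d_model``-wide
   latent vector, ``H0 = X·Wp + bp``.
2. A stack of post-norm transformer encoder layers models long-range
   temporal structure: ``H' = LN(H0 + MHSA(H0))``, ``H1 = LN(H' + FFN(H'))``.
3. Two parallel attention branches re-process ``H1``:

   * a *selective-kernel* (SK) branch — grouped temporal convolutions with
     kernel sizes {1,3,5,7}, batch-normalized and rectified, whose outputs
     are mixed by per-sample softmax weights derived from a pooled context
     vector; this adapts the temporal receptive field per input;
   * a *squeeze-enhanced axial* (SEA) branch — the latent sequence is
     reshaped to a (channels, time, feature-band) map; attention is
     factorized into a temporal (row) axis and a feature-band (column)
     axis, each squeezed by mean-pooling along the other axis before the
     softmax, which keeps cost linear instead of quadratic in the map size.

4. A gating signal ``G = sigmoid(Conv1×1(H1))`` fuses the branches by a
   convex combination ``V = G·V_SK + (1−G)·V_SEA``.
5. Temporal global average pooling and a fully connected softmax head.

Everything is built on :mod:`sksformer.nn`; the model is deterministic
given (config, seed) and runs comfortably on a single CPU at the default
widths used here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .nn import Tensor


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``T``/``D`` fix the input window shape; ``kernel_set`` the SK branch's
    temporal kernel sizes; ``d_s`` the width of the SK selection vector;
    ``c_attn`` the channel count of the axial reshape (the per-axis token
    feature width, so the axial attention scale is 1/sqrt(c_attn));
    ``gate_mode`` selects learned gating, a fixed 0.5 average, or a single
    branch; ``use_branches=False`` drops both branches and the gate so the
    head consumes the pooled encoder output directly.
    """

    T: int = 200
    D: int = 3
    K: int = 6
    d_model: int = 128
    n_layers: int = 2
    h: int = 4
    d_ff: int = 256
    kernel_set: tuple[int, ...] = (1, 3, 5, 7)
    d_s: int | None = None          # default d_model // 4
    conv_groups: int = 4
    c_attn: int = 8
    dropout: float = 0.1
    use_positional_encoding: bool = False
    sea_sigmoid: bool = True
    use_sk: bool = True
    use_sea: bool = True
    use_branches: bool = True
    gate_mode: str = "learned"      # learned | average | sk | sea
    seed: int = 0

    def __post_init__(self):
        if self.d_s is None:
            self.d_s = max(self.d_model // 4, 1)
        self.kernel_set = tuple(self.kernel_set)
        self.validate()

    @property
    def d_k(self) -> int:
        return self.d_model // self.h

    def validate(self) -> None:
        if self.d_model % self.h:
            raise ValueError("d_model must be divisible by h")
        if self.d_model % self.c_attn:
            raise ValueError("d_model must be divisible by c_attn")
        if self.d_model % self.conv_groups:
            raise ValueError("d_model must be divisible by conv_groups")
        if any(k % 2 == 0 for k in self.kernel_set):
            raise ValueError("kernel sizes must be odd for same-padding")
        if self.K < 2:
            raise ValueError("K must be at least 2")
        if self.gate_mode not in ("learned", "average", "sk", "sea"):
            raise ValueError(f"unknown gate_mode {self.gate_mode!r}")

    def replace(self, **kw) -> "ModelConfig":
        cfg = replace(self, **kw)
        return cfg


def sinusoidal_encoding(t: int, d: int) -> np.ndarray:
    """Classic fixed sin/cos positional table of shape (t, d)."""
    pos = np.arange(t)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    enc = np.zeros((t, d), dtype=np.float32)
    enc[:, 0::2] = np.sin(angle[:, 0::2])
    enc[:, 1::2] = np.cos(angle[:, 1::2])
    return enc


class MultiHeadSelfAttention(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        d = cfg.d_model
        self.h = cfg.h
        self.d_k = cfg.d_k
        self.wq = nn.Linear(d, d, rng, bias=False)
        self.wk = nn.Linear(d, d, rng, bias=False)
        self.wv = nn.Linear(d, d, rng, bias=False)
        self.wo = nn.Linear(d, d, rng, bias=False)
        self.last_attention: np.ndarray | None = None

    def __call__(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        def split(z):  # (B,T,d) -> (B,h,T,d_k)
            return z.reshape(b, t, self.h, self.d_k).transpose(0, 2, 1, 3)
        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        out, attn = nn.scaled_dot_attention(q, k, v, 1.0 / math.sqrt(self.d_k))
        self.last_attention = attn
        out = out.transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.wo(out)


class FeedForward(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.w1 = nn.Linear(cfg.d_model, cfg.d_ff, rng)
        self.w2 = nn.Linear(cfg.d_ff, cfg.d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.w2(self.w1(x).relu())


class EncoderLayer(nn.Module):
    """Post-norm layer: LayerNorm applied after each residual addition."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.mhsa = MultiHeadSelfAttention(cfg, rng)
        self.ffn = FeedForward(cfg, rng)
        self.ln1 = nn.LayerNorm(cfg.d_model)
        self.ln2 = nn.LayerNorm(cfg.d_model)
        self.drop1 = nn.Dropout(cfg.dropout, rng)
        self.drop2 = nn.Dropout(cfg.dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.ln1(x + self.drop1(self.mhsa(x)))
        return self.ln2(h + self.drop2(self.ffn(h)))


class SelectiveKernel(nn.Module):
    """Multi-scale grouped temporal convolutions with softmax branch mixing."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        d = cfg.d_model
        self.convs = [nn.Conv1d(d, d, k, rng, groups=cfg.conv_groups)
                      for k in cfg.kernel_set]
        self.bns = [nn.BatchNorm1d(d) for _ in cfg.kernel_set]
        self.w1 = nn.Linear(d, cfg.d_s, rng, bias=False)
        # one selection vector w_k per branch
        self.branch_w = nn.Parameter(
            nn._fan_in_uniform(rng, (len(cfg.kernel_set), cfg.d_s), cfg.d_s))

    def __call__(self, x: Tensor) -> tuple[Tensor, dict]:
        # x: (B, C, T)
        branches = [conv_bn[1](conv_bn[0](x)).relu()
                    for conv_bn in zip(self.convs, self.bns)]
        u = branches[0]
        for uk in branches[1:]:
            u = u + uk
        z = u.mean(axis=2)                       # (B, C) pooled context
        s = (z @ self.w1.weight).relu()          # (B, d_s)
        logits = s @ self.branch_w.swapaxes(0, 1)  # (B, n_branches)
        alpha = nn.softmax(logits, axis=1)
        # weighted fusion: V_SK = sum_k alpha_k * U_k
        out = branches[0] * _branch_weight(alpha, 0)
        for i in range(1, len(branches)):
            out = out + branches[i] * _branch_weight(alpha, i)
        inter = {"alpha": alpha.data, "U": u.data, "z": z.data, "s": s.data,
                 "branches": [bk.data for bk in branches]}
        return out, inter


def _branch_weight(alpha: Tensor, i: int) -> Tensor:
    """Slice branch i of the (B, n) mixing weights as a (B,1,1) tensor."""
    n = alpha.shape[1]
    sel = np.zeros((n, 1), dtype=np.float32)
    sel[i, 0] = 1.0
    return (alpha @ Tensor(sel)).reshape(alpha.shape[0], 1, 1)


class SqueezeAxialAttention(nn.Module):
    """Axial attention on a (B, C, H=T, W=d_model/C) map with mean squeezes.

    Depthwise temporal convolutions produce Q, K, V; the row (temporal)
    attention pools the W axis, the column (feature-band) attention pools
    the H axis; learnable additive positional vectors of lengths T and W
    are applied to the squeezed queries/keys; attended values pass through
    depthwise conv encoders and are broadcast-added back onto V before a
    pointwise projection and (by default) a sigmoid.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.c = cfg.c_attn
        self.w = cfg.d_model // cfg.c_attn
        self.t = cfg.T
        self.sigmoid_out = cfg.sea_sigmoid
        c = self.c
        self.q_conv = nn.Conv1d(c, c, 3, rng, groups=c, bias=False)
        self.k_conv = nn.Conv1d(c, c, 3, rng, groups=c, bias=False)
        self.v_conv = nn.Conv1d(c, c, 3, rng, groups=c, bias=False)
        self.row_enc = nn.Conv1d(c, c, 3, rng, groups=c)
        self.col_enc = nn.Conv1d(c, c, 3, rng, groups=c)
        self.proj = nn.Conv1d(c, c, 1, rng)
        self.pos_row = nn.Parameter(np.zeros((cfg.T, 1), dtype=np.float32))
        self.pos_col = nn.Parameter(np.zeros((self.w, 1), dtype=np.float32))
        self.last_row_attention: np.ndarray | None = None
        self.last_col_attention: np.ndarray | None = None

    def _depthwise_time(self, conv: nn.Conv1d, x4: Tensor) -> Tensor:
        # depthwise conv along H (time) for every feature band: fold W into batch
        b, c, h, w = x4.shape
        xr = x4.transpose(0, 3, 1, 2).reshape(b * w, c, h)
        yr = conv(xr)
        return yr.reshape(b, w, c, h).transpose(0, 2, 3, 1)

    def __call__(self, h1: Tensor) -> tuple[Tensor, dict]:
        # h1: (B, T, d_model) -> 4-axis map (B, C, H=T, W)
        b = h1.shape[0]
        x4 = h1.reshape(b, self.t, self.c, self.w).transpose(0, 2, 1, 3)
        q = self._depthwise_time(self.q_conv, x4)
        k = self._depthwise_time(self.k_conv, x4)
        v = self._depthwise_time(self.v_conv, x4)
        scale = 1.0 / math.sqrt(self.c)

        # row (temporal) attention: squeeze W, tokens along H with C features
        q_row = q.mean(axis=3).transpose(0, 2, 1) + self.pos_row   # (B,H,C)
        k_row = k.mean(axis=3).transpose(0, 2, 1) + self.pos_row
        v_row = v.mean(axis=3).transpose(0, 2, 1)
        a_row = nn.softmax((q_row @ k_row.transpose(0, 2, 1)) * scale, axis=-1)
        o_row = self.row_enc((a_row @ v_row).transpose(0, 2, 1))   # (B,C,H)

        # column (feature-band) attention: squeeze H, tokens along W
        q_col = q.mean(axis=2).transpose(0, 2, 1) + self.pos_col   # (B,W,C)
        k_col = k.mean(axis=2).transpose(0, 2, 1) + self.pos_col
        v_col = v.mean(axis=2).transpose(0, 2, 1)
        a_col = nn.softmax((q_col @ k_col.transpose(0, 2, 1)) * scale, axis=-1)
        o_col = self.col_enc((a_col @ v_col).transpose(0, 2, 1))   # (B,C,W)

        self.last_row_attention = a_row.data
        self.last_col_attention = a_col.data

        fused = (v
                 + o_row.reshape(b, self.c, self.t, 1)
                 + o_col.reshape(b, self.c, 1, self.w))
        proj = self.proj(fused.reshape(b, self.c, self.t * self.w))
        if self.sigmoid_out:
            proj = proj.sigmoid()
        out4 = proj.reshape(b, self.c, self.t, self.w)
        # back to (B, d_model, T); contiguous so downstream reductions sum
        # in the same order as the other branch (bit-stable fusion)
        out = out4.transpose(0, 2, 1, 3).reshape(b, self.t, self.c * self.w)
        out = out.transpose(0, 2, 1).contiguous()
        inter = {"A_row": a_row.data, "A_col": a_col.data,
                 "O_row": o_row.data, "O_col": o_col.data}
        return out, inter


class SKSTransformer(nn.Module):
    """Full classifier; see the module docstring for the signal path."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.rng = rng
        self.proj = nn.Linear(cfg.D, cfg.d_model, rng)
        self.pos_table = sinusoidal_encoding(cfg.T, cfg.d_model)
        self.encoder = [EncoderLayer(cfg, rng) for _ in range(cfg.n_layers)]
        if cfg.use_branches:
            if cfg.use_sk:
                self.sk = SelectiveKernel(cfg, rng)
            if cfg.use_sea:
                self.sea = SqueezeAxialAttention(cfg, rng)
            if cfg.use_sk and cfg.use_sea and cfg.gate_mode == "learned":
                self.gate = nn.Conv1d(cfg.d_model, 1, 1, rng)
        self.head = nn.Linear(cfg.d_model, cfg.K, rng)

    # -- stage-wise API (each stage is independently testable) ----------
    def project_input(self, x: Tensor) -> Tensor:
        if x.shape[-2:] != (self.cfg.T, self.cfg.D):
            raise ValueError(
                f"expected window shape (..., {self.cfg.T}, {self.cfg.D}), got {x.shape}")
        h0 = self.proj(x)
        if self.cfg.use_positional_encoding:
            h0 = h0 + Tensor(self.pos_table)
        return h0

    def encoder_forward(self, h0: Tensor) -> Tensor:
        h = h0
        for layer in self.encoder:
            h = layer(h)
        return h

    def sk_forward(self, h1: Tensor) -> tuple[Tensor, dict]:
        return self.sk(h1.transpose(0, 2, 1))

    def sea_forward(self, h1: Tensor) -> tuple[Tensor, dict]:
        return self.sea(h1)

    def gate_signal(self, h1: Tensor) -> Tensor:
        return self.gate(h1.transpose(0, 2, 1)).sigmoid()   # (B,1,T)

    def gate_fuse(self, g: Tensor, v_sk: Tensor, v_sea: Tensor) -> Tensor:
        return g * v_sk + (1.0 - g) * v_sea

    def classify(self, v_fused: Tensor) -> Tensor:
        pooled = v_fused.mean(axis=2)            # (B, d_model)
        return self.head(pooled)

    # -- full forward ----------------------------------------------------
    def __call__(self, x, return_intermediates: bool = False,
                 force_gate: float | None = None):
        """Window batch (B,T,D) → logits (B,K) (+ intermediates dict)."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.ndim == 2:
            x = x.reshape(1, *x.shape)
        self._check_normalized(x.data)
        cfg = self.cfg
        inter: dict = {}
        h1 = self.encoder_forward(self.project_input(x))
        if not cfg.use_branches:
            logits = self.head(h1.mean(axis=1))
            return (logits, inter) if return_intermediates else logits

        v_sk = v_sea = None
        if cfg.use_sk:
            v_sk, sk_inter = self.sk_forward(h1)
            inter["sk"] = sk_inter
        if cfg.use_sea:
            v_sea, sea_inter = self.sea_forward(h1)
            inter["sea"] = sea_inter

        if v_sk is not None and v_sea is not None:
            mode = cfg.gate_mode
            if force_gate is not None:
                g = Tensor(np.full((x.shape[0], 1, cfg.T), force_gate, dtype=np.float32))
            elif mode == "learned":
                g = self.gate_signal(h1)
            elif mode == "average":
                g = Tensor(np.full((x.shape[0], 1, cfg.T), 0.5, dtype=np.float32))
            elif mode == "sk":
                g = Tensor(np.ones((x.shape[0], 1, cfg.T), dtype=np.float32))
            else:  # "sea"
                g = Tensor(np.zeros((x.shape[0], 1, cfg.T), dtype=np.float32))
            fused = self.gate_fuse(g, v_sk, v_sea)
            inter["G"] = g.data
        else:
            fused = v_sk if v_sk is not None else v_sea
        logits = self.classify(fused)
        inter["V_fused"] = fused.data
        return (logits, inter) if return_intermediates else logits

    def predict_proba(self, x) -> np.ndarray:
        with nn.no_grad():
            logits = self(x)
            return nn.softmax(logits, axis=1).data

    def predict(self, x) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    @staticmethod
    def _check_normalized(data: np.ndarray) -> None:
        m, s = float(np.mean(data)), float(np.std(data))
        if abs(m) > 1.0 or not (0.05 < s < 20.0):
            warnings.warn(
                f"input does not look z-scored (mean {m:.3g}, std {s:.3g}); "
                "the model expects normalized windows", stacklevel=2)
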