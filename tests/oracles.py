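"""Independent straight-line reference implementations used as oracles.

Everything here is written with explicit Python loops in float64, reading
only the weight arrays of a model — never its forward code — so that a
match between these functions and the vectorized float32 implementation
is a genuine dual-route check.
"""

from __future__ import annotations

import math

import numpy as np


def int16_reference(low: int, high: int) -> int:
    """Two's-complement via explicit bit arithmetic."""
    word = high * 256 + low
    bits = [(word >> i) & 1 for i in range(16)]
    value = sum(b << i for i, b in enumerate(bits[:15]))
    return value - (bits[15] << 15)


def softmax_rows(m: np.ndarray) -> np.ndarray:
    out = np.empty_like(m, dtype=float)
    for i in range(m.shape[0]):
        e = np.exp(m[i] - m[i].max())
        out[i] = e / e.sum()
    return out


def layernorm_rows(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
                   eps: float = 1e-5) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    for t in range(x.shape[0]):
        mu = x[t].mean()
        var = ((x[t] - mu) ** 2).mean()
        out[t] = (x[t] - mu) / np.sqrt(var + eps) * gamma + beta
    return out


def encoder_layer_oracle(h0: np.ndarray, layer, h: int) -> np.ndarray:
    """Post-norm encoder layer: MHSA then FFN, loops per head/timestep."""
    t_len, d = h0.shape
    dk = d // h
    wq = layer.mhsa.wq.weight.data.astype(float)
    wk = layer.mhsa.wk.weight.data.astype(float)
    wv = layer.mhsa.wv.weight.data.astype(float)
    wo = layer.mhsa.wo.weight.data.astype(float)
    q_all, k_all, v_all = h0 @ wq, h0 @ wk, h0 @ wv
    heads = []
    for i in range(h):
        q = q_all[:, i * dk:(i + 1) * dk]
        k = k_all[:, i * dk:(i + 1) * dk]
        v = v_all[:, i * dk:(i + 1) * dk]
        scores = np.empty((t_len, t_len))
        for a in range(t_len):
            for b in range(t_len):
                scores[a, b] = float(q[a] @ k[b]) / math.sqrt(dk)
        heads.append(softmax_rows(scores) @ v)
    mhsa = np.concatenate(heads, axis=1) @ wo
    h_prime = layernorm_rows(h0 + mhsa,
                             layer.ln1.gamma.data.astype(float),
                             layer.ln1.beta.data.astype(float))
    w1 = layer.ffn.w1.weight.data.astype(float)
    b1 = layer.ffn.w1.bias.data.astype(float)
    w2 = layer.ffn.w2.weight.data.astype(float)
    b2 = layer.ffn.w2.bias.data.astype(float)
    ffn = np.maximum(h_prime @ w1 + b1, 0.0) @ w2 + b2
    return layernorm_rows(h_prime + ffn,
                          layer.ln2.gamma.data.astype(float),
                          layer.ln2.beta.data.astype(float))


def encoder_oracle(h0: np.ndarray, model) -> np.ndarray:
    h = h0.astype(float)
    for layer in model.encoder:
        h = encoder_layer_oracle(h, layer, model.cfg.h)
    return h


def conv1d_oracle(x: np.ndarray, weight: np.ndarray, bias, groups: int) -> np.ndarray:
    """Same-padded grouped 1-D convolution by explicit loops. x: (C_in, T)."""
    c_out, cpg, k = weight.shape
    c_in, t_len = x.shape
    pad = k // 2
    out = np.zeros((c_out, t_len))
    per_out = c_out // groups
    for o in range(c_out):
        g = o // per_out
        in_lo = g * cpg
        for t in range(t_len):
            acc = 0.0
            for ci in range(cpg):
                for j in range(k):
                    src = t + j - pad
                    if 0 <= src < t_len:
                        acc += weight[o, ci, j] * x[in_lo + ci, src]
            out[o, t] = acc + (bias[o] if bias is not None else 0.0)
    return out


def batchnorm_train_oracle(u: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
                           eps: float = 1e-5) -> np.ndarray:
    """Training-mode BN over (batch=1 here) × time per channel. u: (C, T)."""
    out = np.empty_like(u, dtype=float)
    for c in range(u.shape[0]):
        mu = u[c].mean()
        var = ((u[c] - mu) ** 2).mean()
        out[c] = (u[c] - mu) / np.sqrt(var + eps) * gamma[c] + beta[c]
    return out


def sk_oracle(h1: np.ndarray, sk, kernel_set, groups: int) -> np.ndarray:
    """Selective-kernel branch: convs -> BN -> ReLU, softmax branch mixing.

    h1: (T, d_model) single sample; batch statistics therefore reduce over
    time only, matching a batch of one.
    """
    x = h1.T.astype(float)                      # (C, T)
    branches = []
    for conv, bn in zip(sk.convs, sk.bns):
        u = conv1d_oracle(x, conv.weight.data.astype(float),
                          conv.bias.data.astype(float), groups)
        u = batchnorm_train_oracle(u, bn.gamma.data.astype(float),
                                   bn.beta.data.astype(float))
        branches.append(np.maximum(u, 0.0))
    u_sum = np.zeros_like(branches[0])
    for u in branches:
        u_sum = u_sum + u
    z = u_sum.mean(axis=1)                      # (C,)
    s = np.maximum(z @ sk.w1.weight.data.astype(float), 0.0)
    logits = np.array([float(w @ s) for w in sk.branch_w.data.astype(float)])
    alpha = np.exp(logits - logits.max())
    alpha = alpha / alpha.sum()
    out = np.zeros_like(branches[0])
    for a, u in zip(alpha, branches):
        out = out + a * u
    return out                                   # (C, T)


def depthwise_time_oracle(x4: np.ndarray, weight: np.ndarray, bias) -> np.ndarray:
    """Depthwise conv along H for every (c, w) slice. x4: (C, H, W)."""
    c, h, w = x4.shape
    out = np.empty_like(x4, dtype=float)
    for wi in range(w):
        out[:, :, wi] = conv1d_oracle(x4[:, :, wi], weight, bias, groups=c)
    return out


def sea_oracle(h1: np.ndarray, sea) -> np.ndarray:
    """Squeeze-axial attention for a single sample. h1: (T, d_model)."""
    t_len, d = h1.shape
    c, w = sea.c, sea.w
    x4 = h1.reshape(t_len, c, w).transpose(1, 0, 2).astype(float)  # (C,H,W)
    q = depthwise_time_oracle(x4, sea.q_conv.weight.data.astype(float), None)
    k = depthwise_time_oracle(x4, sea.k_conv.weight.data.astype(float), None)
    v = depthwise_time_oracle(x4, sea.v_conv.weight.data.astype(float), None)
    pos_row = sea.pos_row.data.astype(float)            # (T, 1)
    pos_col = sea.pos_col.data.astype(float)            # (W, 1)
    scale = 1.0 / math.sqrt(c)

    q_row = q.mean(axis=2).T + pos_row                  # (H, C)
    k_row = k.mean(axis=2).T + pos_row
    v_row = v.mean(axis=2).T                            # (H, C)
    a_row = softmax_rows((q_row * scale) @ k_row.T)
    o_row = conv1d_oracle((a_row @ v_row).T,
                          sea.row_enc.weight.data.astype(float),
                          sea.row_enc.bias.data.astype(float), groups=c)  # (C,H)

    q_col = q.mean(axis=1).T + pos_col                  # (W, C)
    k_col = k.mean(axis=1).T + pos_col
    v_col = v.mean(axis=1).T
    a_col = softmax_rows((q_col * scale) @ k_col.T)
    o_col = conv1d_oracle((a_col @ v_col).T,
                          sea.col_enc.weight.data.astype(float),
                          sea.col_enc.bias.data.astype(float), groups=c)  # (C,W)

    fused = v + o_row[:, :, None] + o_col[:, None, :]   # (C,H,W)
    pw = sea.proj.weight.data.astype(float)             # (C, C, 1)
    pb = sea.proj.bias.data.astype(float)
    proj = np.einsum("oc,chw->ohw", pw[:, :, 0], fused) + pb[:, None, None]
    out4 = 1.0 / (1.0 + np.exp(-proj)) if sea.sigmoid_out else proj
    # back to (d_model, T)
    return out4.transpose(1, 0, 2).reshape(t_len, c * w).T


def confusion_metrics_oracle(y_true, y_pred, k: int):
    """Brute-force confusion matrix and macro metrics."""
    conf = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[t, p] += 1
    precs, recs, f1s = [], [], []
    for c in range(k):
        tp = conf[c, c]
        p = tp / conf[:, c].sum() if conf[:, c].sum() else 0.0
        r = tp / conf[c].sum() if conf[c].sum() else 0.0
        f = 2 * p * r / (p + r) if (p + r) else 0.0
        precs.append(p); recs.append(r); f1s.append(f)
    acc = np.trace(conf) / conf.sum()
    return conf, acc, np.mean(precs), np.mean(recs), np.mean(f1s)
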