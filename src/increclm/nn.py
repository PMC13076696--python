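"""NumPy building blocks for the recurrent SMILES language model.

Implements embedding + (optional) batch normalization + stacked LSTM layers
+ dense projection to vocabulary logits, with full backpropagation through
time and an Adam optimizer. Sequences are teacher-forced with start/end
sentinels and post-padding; the loss is masked on padding positions, and
batch-normalization statistics are likewise computed over non-padded
positions only (padded inputs cannot influence the masked loss because the
recurrence is causal).

Parameter layout (``params`` dict of ndarrays):

- ``emb``            (V, E) token embeddings
- ``W{l}``, ``b{l}`` LSTM layer l: ((D_in + H_l), 4*H_l) and (4*H_l,),
  gate order [input, forget, cell, output]; forget bias initialized to 1
- ``g_in``, ``be_in``   batch-norm scale/shift after the embedding
- ``g_out``, ``be_out`` batch-norm scale/shift before the dense projection
- ``Wout``, ``bout`` dense projection to logits
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BN_EPS = 1e-5
BN_MOMENTUM = 0.9


@dataclass(frozen=True)
class NetSpec:
    """Shape description of the network, independent of any vocabulary object."""

    vocab_size: int
    embedding_dim: int
    recurrent_layers: tuple
    use_batchnorm: bool = True
    dropout: float = 0.0

    def __post_init__(self):
        if self.vocab_size < 4:
            raise ValueError("vocabulary must hold at least the sentinels + 1 token")
        if self.embedding_dim < 1 or any(h < 1 for h in self.recurrent_layers):
            raise ValueError("all layer dimensions must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")


def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def init_params(spec: NetSpec, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    params = {"emb": _glorot(rng, (spec.vocab_size, spec.embedding_dim))}
    d_in = spec.embedding_dim
    for l, h in enumerate(spec.recurrent_layers):
        params[f"W{l}"] = _glorot(rng, (d_in + h, 4 * h))
        b = np.zeros(4 * h)
        b[h : 2 * h] = 1.0  # forget-gate bias
        params[f"b{l}"] = b
        d_in = h
    if spec.use_batchnorm:
        params["g_in"] = np.ones(spec.embedding_dim)
        params["be_in"] = np.zeros(spec.embedding_dim)
        params["g_out"] = np.ones(d_in)
        params["be_out"] = np.zeros(d_in)
    params["Wout"] = _glorot(rng, (d_in, spec.vocab_size))
    params["bout"] = np.zeros(spec.vocab_size)
    return params


def init_bn_stats(spec: NetSpec) -> dict:
    if not spec.use_batchnorm:
        return {}
    return {
        "in_mean": np.zeros(spec.embedding_dim),
        "in_var": np.ones(spec.embedding_dim),
        "out_mean": np.zeros(spec.recurrent_layers[-1]),
        "out_var": np.ones(spec.recurrent_layers[-1]),
    }


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# batch normalization over masked (B, T, F) activations


def _bn_forward(x, gamma, beta, mask, running_mean, running_var, train):
    if train:
        m = mask[..., None]
        cnt = max(mask.sum(), 1)
        mean = (x * m).sum(axis=(0, 1)) / cnt
        var = (((x - mean) * m) ** 2).sum(axis=(0, 1)) / cnt
        running_mean *= BN_MOMENTUM
        running_mean += (1 - BN_MOMENTUM) * mean
        running_var *= BN_MOMENTUM
        running_var += (1 - BN_MOMENTUM) * var
    else:
        mean, var = running_mean, running_var
        cnt = max(mask.sum(), 1)
    inv_std = 1.0 / np.sqrt(var + BN_EPS)
    xhat = (x - mean) * inv_std
    y = gamma * xhat + beta
    cache = (xhat, inv_std, gamma, mask, cnt, train)
    return y, cache


def _bn_backward(dy, cache):
    xhat, inv_std, gamma, mask, cnt, train = cache
    m = mask[..., None]
    dy = dy * m  # padded positions carry no gradient
    dgamma = (dy * xhat).sum(axis=(0, 1))
    dbeta = dy.sum(axis=(0, 1))
    if not train:
        return dy * gamma * inv_std, dgamma, dbeta
    dxhat = dy * gamma
    sum_dxhat = dxhat.sum(axis=(0, 1))
    sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 1))
    dx = inv_std * (dxhat - (sum_dxhat + xhat * sum_dxhat_xhat) / cnt)
    return dx * m, dgamma, dbeta


# ---------------------------------------------------------------------------
# LSTM layer


def _lstm_forward(x, W, b, h0=None, c0=None):
    B, T, D = x.shape
    H = W.shape[1] // 4
    h = np.zeros((B, H)) if h0 is None else h0
    c = np.zeros((B, H)) if c0 is None else c0
    hs = np.empty((B, T, H))
    cache_i = np.empty((B, T, H))
    cache_f = np.empty((B, T, H))
    cache_g = np.empty((B, T, H))
    cache_o = np.empty((B, T, H))
    cache_tanh_c = np.empty((B, T, H))
    cache_cprev = np.empty((B, T, H))
    cache_hprev = np.empty((B, T, H))
    for t in range(T):
        cache_hprev[:, t] = h
        cache_cprev[:, t] = c
        a = x[:, t] @ W[:D] + h @ W[D:] + b
        i = _sigmoid(a[:, :H])
        f = _sigmoid(a[:, H : 2 * H])
        g = np.tanh(a[:, 2 * H : 3 * H])
        o = _sigmoid(a[:, 3 * H :])
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        hs[:, t] = h
        cache_i[:, t] = i
        cache_f[:, t] = f
        cache_g[:, t] = g
        cache_o[:, t] = o
        cache_tanh_c[:, t] = tc
    cache = (x, cache_i, cache_f, cache_g, cache_o, cache_tanh_c, cache_cprev,
             cache_hprev)
    return hs, (h, c), cache


def _lstm_backward(dhs, cache, W):
    x, i, f, g, o, tanh_c, c_prev, h_prev = cache
    B, T, D = x.shape
    H = i.shape[2]
    dW = np.zeros_like(W)
    db = np.zeros(4 * H)
    dx = np.empty_like(x)
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    dA = np.empty((B, 4 * H))
    for t in range(T - 1, -1, -1):
        dh = dhs[:, t] + dh_next
        it, ft, gt, ot, tct = i[:, t], f[:, t], g[:, t], o[:, t], tanh_c[:, t]
        dc = dh * ot * (1 - tct * tct) + dc_next
        dA[:, :H] = (dc * gt) * it * (1 - it)
        dA[:, H : 2 * H] = (dc * c_prev[:, t]) * ft * (1 - ft)
        dA[:, 2 * H : 3 * H] = (dc * it) * (1 - gt * gt)
        dA[:, 3 * H :] = (dh * tct) * ot * (1 - ot)
        dW[:D] += x[:, t].T @ dA
        dW[D:] += h_prev[:, t].T @ dA
        db += dA.sum(axis=0)
        dx[:, t] = dA @ W[:D].T
        dh_next = dA @ W[D:].T
        dc_next = dc * f[:, t]
    return dx, dW, db


def _lstm_step(x, W, b, h, c):
    D = x.shape[1]
    H = W.shape[1] // 4
    a = x @ W[:D] + h @ W[D:] + b
    i = _sigmoid(a[:, :H])
    f = _sigmoid(a[:, H : 2 * H])
    g = np.tanh(a[:, 2 * H : 3 * H])
    o = _sigmoid(a[:, 3 * H :])
    c = f * c + i * g
    h = o * np.tanh(c)
    return h, c


# ---------------------------------------------------------------------------
# full network


def forward(params, spec: NetSpec, X, bn_stats, train=False, dropout_rng=None,
            mask=None):
    """Teacher-forced forward pass.

    ``X``: (B, T) int token indices (inputs); ``mask``: (B, T) bool marking
    positions that contribute to the loss (defaults to X != 0, i.e. non-pad).
    Returns ``(logits, caches)``.
    """
    if mask is None:
        mask = X != 0
    x = params["emb"][X]
    caches = {"X": X, "mask": mask}
    if spec.use_batchnorm:
        x, caches["bn_in"] = _bn_forward(
            x, params["g_in"], params["be_in"], mask,
            bn_stats["in_mean"], bn_stats["in_var"], train,
        )
    drop = spec.dropout if train else 0.0
    caches["layers"] = []
    caches["drop_masks"] = []
    for l in range(len(spec.recurrent_layers)):
        hs, _, cache = _lstm_forward(x, params[f"W{l}"], params[f"b{l}"])
        caches["layers"].append(cache)
        if drop > 0.0:
            dm = (dropout_rng.random(size=(hs.shape[0], 1, hs.shape[2])) >= drop)
            dm = dm / (1.0 - drop)
            hs = hs * dm
            caches["drop_masks"].append(dm)
        else:
            caches["drop_masks"].append(None)
        x = hs
    if spec.use_batchnorm:
        x, caches["bn_out"] = _bn_forward(
            x, params["g_out"], params["be_out"], mask,
            bn_stats["out_mean"], bn_stats["out_var"], train,
        )
    caches["pre_dense"] = x
    logits = x @ params["Wout"] + params["bout"]
    return logits, caches


def loss_and_grads(params, spec: NetSpec, X, Y, bn_stats, train=True,
                   dropout_rng=None):
    """Masked categorical cross-entropy and gradients for one batch.

    ``X`` are the teacher-forced inputs, ``Y`` the next-token targets;
    positions where ``Y == 0`` (pad) are excluded from the loss.
    """
    mask = Y != 0
    logits, caches = forward(params, spec, X, bn_stats, train=train,
                             dropout_rng=dropout_rng, mask=mask)
    B, T, V = logits.shape
    z = logits - logits.max(axis=2, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=2, keepdims=True)
    cnt = max(mask.sum(), 1)
    logp = np.log(np.take_along_axis(probs, Y[..., None], axis=2)[..., 0] + 1e-30)
    loss = -(logp * mask).sum() / cnt

    dlogits = probs.copy()
    np.put_along_axis(
        dlogits, Y[..., None],
        np.take_along_axis(dlogits, Y[..., None], axis=2) - 1.0, axis=2,
    )
    dlogits *= mask[..., None] / cnt

    grads = {}
    x = caches["pre_dense"]
    grads["Wout"] = x.reshape(-1, x.shape[2]).T @ dlogits.reshape(-1, V)
    grads["bout"] = dlogits.sum(axis=(0, 1))
    dx = dlogits @ params["Wout"].T
    if spec.use_batchnorm:
        dx, grads["g_out"], grads["be_out"] = _bn_backward(dx, caches["bn_out"])
    for l in range(len(spec.recurrent_layers) - 1, -1, -1):
        dm = caches["drop_masks"][l]
        if dm is not None:
            dx = dx * dm
        dx, grads[f"W{l}"], grads[f"b{l}"] = _lstm_backward(
            dx, caches["layers"][l], params[f"W{l}"]
        )
    if spec.use_batchnorm:
        dx, grads["g_in"], grads["be_in"] = _bn_backward(dx, caches["bn_in"])
    demb = np.zeros_like(params["emb"])
    np.add.at(demb, caches["X"].ravel(), dx.reshape(-1, dx.shape[2]))
    grads["emb"] = demb
    return loss, grads


def eval_loss(params, spec: NetSpec, X, Y, bn_stats) -> float:
    """Masked cross-entropy in evaluation mode (running BN stats, no dropout)."""
    mask = Y != 0
    logits, _ = forward(params, spec, X, bn_stats, train=False, mask=mask)
    z = logits - logits.max(axis=2, keepdims=True)
    logprobs = z - np.log(np.exp(z).sum(axis=2, keepdims=True))
    logp = np.take_along_axis(logprobs, Y[..., None], axis=2)[..., 0]
    return float(-(logp * mask).sum() / max(mask.sum(), 1))


def sequence_log_probs(params, spec: NetSpec, X, Y, bn_stats) -> tuple:
    """Per-sequence summed log probability of the realized targets.

    Returns ``(logp_sums, counts)`` where counts is the number of scored
    (non-pad) positions per sequence.
    """
    mask = Y != 0
    logits, _ = forward(params, spec, X, bn_stats, train=False, mask=mask)
    z = logits - logits.max(axis=2, keepdims=True)
    logprobs = z - np.log(np.exp(z).sum(axis=2, keepdims=True))
    logp = np.take_along_axis(logprobs, Y[..., None], axis=2)[..., 0]
    return (logp * mask).sum(axis=1), mask.sum(axis=1)


# ---------------------------------------------------------------------------
# stepwise API for sampling


def init_step_state(spec: NetSpec, batch: int) -> list:
    return [
        (np.zeros((batch, h)), np.zeros((batch, h))) for h in spec.recurrent_layers
    ]


def step(params, spec: NetSpec, tokens, hc, bn_stats):
    """One decoding step in evaluation mode: token indices -> logits."""
    x = params["emb"][tokens]
    if spec.use_batchnorm:
        inv = 1.0 / np.sqrt(bn_stats["in_var"] + BN_EPS)
        x = params["g_in"] * (x - bn_stats["in_mean"]) * inv + params["be_in"]
    new_hc = []
    for l in range(len(spec.recurrent_layers)):
        h, c = _lstm_step(x, params[f"W{l}"], params[f"b{l}"], *hc[l])
        new_hc.append((h, c))
        x = h
    if spec.use_batchnorm:
        inv = 1.0 / np.sqrt(bn_stats["out_var"] + BN_EPS)
        x = params["g_out"] * (x - bn_stats["out_mean"]) * inv + params["be_out"]
    return x @ params["Wout"] + params["bout"], new_hc


# ---------------------------------------------------------------------------
# Adam


@dataclass
class AdamState:
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)
    t: int = 0

    def copy(self) -> "AdamState":
        return AdamState(
            m={k: v.copy() for k, v in self.m.items()},
            v={k: v.copy() for k, v in self.v.items()},
            t=self.t,
        )


def adam_step(params, grads, opt: AdamState, lr, beta1=0.9, beta2=0.999,
              eps=1e-8) -> None:
    opt.t += 1
    b1t = 1 - beta1**opt.t
    b2t = 1 - beta2**opt.t
    for k, g in grads.items():
        if k not in opt.m:
            opt.m[k] = np.zeros_like(g)
            opt.v[k] = np.zeros_like(g)
        opt.m[k] = beta1 * opt.m[k] + (1 - beta1) * g
        opt.v[k] = beta2 * opt.v[k] + (1 - beta2) * (g * g)
        params[k] -= lr * (opt.m[k] / b1t) / (np.sqrt(opt.v[k] / b2t) + eps)
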