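"""A small, fully deterministic multilayer perceptron in NumPy.

Architecture per hidden layer: dense (no bias) -> batch normalization ->
ReLU; linear dense output with bias.  Loss is mean absolute error plus an
L2 kernel penalty (``l2 * sum(W**2)`` over dense weights only, matching the
usual kernel-regularizer convention).  Optimization is Adam with mini-batch
shuffling driven by a seeded generator, so identical seeds and data yield
bit-identical training histories on a fixed BLAS configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


@dataclass
class TrainConfig:
    hidden: tuple = (1024, 512, 256, 128)
    epochs: int = 150
    batch_size: int = 300
    learning_rate: float = 1e-3
    l2: float = 0.01
    seed: int = 0
    val_fraction: float = 0.1
    lr_decay: float = 0.1      # multiplier applied at 2/3 of the epochs
    augment_dihedral: bool = True  # interpreted by the window-level trainer
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8


@dataclass
class MLPParams:
    """Flat parameter store: per hidden layer W, gamma, beta + running
    batch-norm statistics; output layer W_out, b_out."""

    Ws: list
    gammas: list
    betas: list
    run_mean: list
    run_var: list
    W_out: np.ndarray = None
    b_out: np.ndarray = None


def init_params(n_in: int, hidden, n_out: int, rng) -> MLPParams:
    """He-normal dense kernels, unit gamma, zero beta."""
    Ws, gammas, betas, rmean, rvar = [], [], [], [], []
    fan = n_in
    for width in hidden:
        Ws.append(rng.normal(0.0, np.sqrt(2.0 / fan), size=(fan, width)))
        gammas.append(np.ones(width))
        betas.append(np.zeros(width))
        rmean.append(np.zeros(width))
        rvar.append(np.ones(width))
        fan = width
    W_out = rng.normal(0.0, np.sqrt(2.0 / fan), size=(fan, n_out))
    b_out = np.zeros(n_out)
    return MLPParams(Ws, gammas, betas, rmean, rvar, W_out, b_out)


def forward(params: MLPParams, x: np.ndarray, training: bool):
    """Forward pass; returns (prediction, caches for backprop)."""
    h = x
    caches = []
    for k, W in enumerate(params.Ws):
        z = h @ W
        if training:
            mu = z.mean(axis=0)
            var = z.var(axis=0)
            params.run_mean[k] = (_BN_MOMENTUM * params.run_mean[k]
                                  + (1 - _BN_MOMENTUM) * mu)
            params.run_var[k] = (_BN_MOMENTUM * params.run_var[k]
                                 + (1 - _BN_MOMENTUM) * var)
        else:
            mu = params.run_mean[k]
            var = params.run_var[k]
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        zhat = (z - mu) * inv_std
        pre = params.gammas[k] * zhat + params.betas[k]
        a = np.maximum(pre, 0.0)
        caches.append((h, z, mu, inv_std, zhat, pre))
        h = a
    y = h @ params.W_out + params.b_out
    return y, (caches, h)


def backward(params: MLPParams, cache, grad_y: np.ndarray, l2: float):
    """Gradients of loss + l2*sum(W^2) w.r.t. all parameters."""
    caches, h_last = cache
    grads = MLPParams([None] * len(params.Ws), [None] * len(params.Ws),
                      [None] * len(params.Ws), None, None)
    grads.W_out = h_last.T @ grad_y + 2.0 * l2 * params.W_out
    grads.b_out = grad_y.sum(axis=0)
    da = grad_y @ params.W_out.T
    B = grad_y.shape[0]
    for k in reversed(range(len(params.Ws))):
        h, z, mu, inv_std, zhat, pre = caches[k]
        dpre = da * (pre > 0)
        grads.gammas[k] = (dpre * zhat).sum(axis=0)
        grads.betas[k] = dpre.sum(axis=0)
        dzhat = dpre * params.gammas[k]
        # batch-norm backward (training statistics)
        dvar = (dzhat * (z - mu)).sum(axis=0) * (-0.5) * inv_std ** 3
        dmu = -(dzhat.sum(axis=0)) * inv_std + dvar * (-2.0 / B) * \
            (z - mu).sum(axis=0)
        dz = dzhat * inv_std + dvar * 2.0 * (z - mu) / B + dmu / B
        grads.Ws[k] = h.T @ dz + 2.0 * l2 * params.Ws[k]
        da = dz @ params.Ws[k].T
    return grads


class Adam:
    def __init__(self, cfg: TrainConfig):
        self.cfg = cfg
        self.lr = cfg.learning_rate
        self.m = None
        self.v = None
        self.t = 0

    def step(self, params: MLPParams, grads: MLPParams):
        flat_p = _flatten(params)
        flat_g = _flatten(grads)
        if self.m is None:
            self.m = [np.zeros_like(p) for p in flat_p]
            self.v = [np.zeros_like(p) for p in flat_p]
        self.t += 1
        c = self.cfg
        bc1 = 1.0 - c.beta1 ** self.t
        bc2 = 1.0 - c.beta2 ** self.t
        for p, g, m, v in zip(flat_p, flat_g, self.m, self.v):
            m *= c.beta1
            m += (1 - c.beta1) * g
            v *= c.beta2
            v += (1 - c.beta2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + c.adam_eps)


def _flatten(p: MLPParams):
    out = list(p.Ws) + list(p.gammas) + list(p.betas)
    out.append(p.W_out)
    out.append(p.b_out)
    return out


def fit(x: np.ndarray, y: np.ndarray, cfg: TrainConfig, augment=None):
    """Train the MLP; returns (params, history dict).

    ``history['train_mae']`` is the running mean data-term MAE per epoch;
    ``history['val_mae']`` the held-out MAE (empty if val_fraction == 0).
    ``augment``, if given, is called per mini-batch as
    ``xb, yb = augment(xb, yb, rng)`` before the forward pass.
    """
    n, n_in = x.shape
    n_out = y.shape[1]
    rng = np.random.default_rng(cfg.seed)
    params = init_params(n_in, cfg.hidden, n_out, rng)
    opt = Adam(cfg)

    n_val = int(round(cfg.val_fraction * n)) if n > 1 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:
        raise ValueError("no training samples after validation split")
    xt, yt = x[tr_idx], y[tr_idx]
    xv, yv = x[val_idx], y[val_idx]

    history = {"train_mae": [], "val_mae": []}
    n_tr = xt.shape[0]
    decay_at = int(np.ceil(2 * cfg.epochs / 3))
    base_lr = cfg.learning_rate
    for epoch in range(cfg.epochs):
        opt.lr = base_lr * (cfg.lr_decay if epoch >= decay_at else 1.0)
        order = rng.permutation(n_tr)
        epoch_abs = 0.0
        for start in range(0, n_tr, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = xt[idx], yt[idx]
            if augment is not None:
                xb, yb = augment(xb, yb, rng)
            pred, cache = forward(params, xb, training=True)
            resid = pred - yb
            epoch_abs += np.abs(resid).sum()
            grad_y = np.sign(resid) / resid.size
            grads = backward(params, cache, grad_y, cfg.l2)
            opt.step(params, grads)
        mae = epoch_abs / (n_tr * n_out)
        if not np.isfinite(mae):
            raise FloatingPointError(
                f"training diverged: non-finite loss at epoch "
                f"{len(history['train_mae'])}")
        history["train_mae"].append(float(mae))
        if n_val:
            pv, _ = forward(params, xv, training=False)
            history["val_mae"].append(float(np.abs(pv - yv).mean()))
    return params, history


def predict(params: MLPParams, x: np.ndarray,
            chunk: int = 4096) -> np.ndarray:
    """Inference with running batch-norm statistics (stateless)."""
    outs = []
    for start in range(0, x.shape[0], chunk):
        y, _ = forward(params, x[start:start + chunk], training=False)
        outs.append(y)
    return np.concatenate(outs, axis=0) if outs else \
        np.empty((0, params.W_out.shape[1]))


def weight_sq_norm(params: MLPParams) -> float:
    """Sum of squared dense-kernel entries (the L2-penalized set)."""
    return float(sum((W ** 2).sum() for W in params.Ws)
                 + (params.W_out ** 2).sum())
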