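"""Numpy implementation of the multi-head self-attention fusion block.

One token per model: block ``m`` (width ``d_m``) is projected to ``proj_dim``
by a learned linear map, giving a ``(batch, n_models, proj_dim)`` token
tensor.  Standard scaled dot-product multi-head self-attention mixes the
tokens, the result is mean-pooled over tokens, and a temporary linear
classification head provides the cross-entropy training signal.  Everything
is trained jointly with Adam; the head is dropped after training and only the
projection + attention parameters are kept.

Gradients are derived by hand (the network is four matrix products, a
softmax, and a mean-pool); a finite-difference check in the test suite
guards the derivation.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .errors import TrainingDivergenceError


def init_params(
    dims: Sequence[int], n_heads: int, d_head: int, n_classes: int, seed: int
) -> dict:
    """Xavier-initialised parameter dict, including the temporary head."""
    rng = np.random.default_rng(seed)
    P = n_heads * d_head

    def xavier(fan_in: int, fan_out: int) -> np.ndarray:
        scale = math.sqrt(2.0 / (fan_in + fan_out))
        return rng.normal(scale=scale, size=(fan_in, fan_out))

    return {
        "n_heads": n_heads,
        "d_head": d_head,
        "Wp": [xavier(d, P) for d in dims],
        "bp": [np.zeros(P) for _ in dims],
        "Wq": xavier(P, P),
        "Wk": xavier(P, P),
        "Wv": xavier(P, P),
        "Wo": xavier(P, P),
        "Wc": xavier(P, n_classes),
        "bc": np.zeros(n_classes),
    }


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def project_tokens(params: dict, Xs: Sequence[np.ndarray]) -> np.ndarray:
    """Per-model linear projections: list of (B, d_m) -> (B, M, P) tokens."""
    cols = [X @ Wp + bp for X, Wp, bp in zip(Xs, params["Wp"], params["bp"])]
    return np.stack(cols, axis=1)


def attend(params: dict, T: np.ndarray) -> np.ndarray:
    """Scaled dot-product MHSA over tokens, mean-pooled: (B, M, P) -> (B, P)."""
    pooled, _ = _attend_cache(params, T)
    return pooled


def _split_heads(X: np.ndarray, H: int, Dh: int) -> np.ndarray:
    B, M, _ = X.shape
    return X.reshape(B, M, H, Dh).transpose(0, 2, 1, 3)  # (B,H,M,Dh)


def _merge_heads(X: np.ndarray) -> np.ndarray:
    B, H, M, Dh = X.shape
    return X.transpose(0, 2, 1, 3).reshape(B, M, H * Dh)


def _attend_cache(params: dict, T: np.ndarray):
    H, Dh = params["n_heads"], params["d_head"]
    B, M, P = T.shape
    Q, K, V = T @ params["Wq"], T @ params["Wk"], T @ params["Wv"]
    qh, kh, vh = (_split_heads(X, H, Dh) for X in (Q, K, V))
    S = qh @ kh.transpose(0, 1, 3, 2) / math.sqrt(Dh)  # (B,H,M,M)
    A = _softmax(S, axis=-1)
    C = _merge_heads(A @ vh)  # (B,M,P)
    O = C @ params["Wo"]
    pooled = O.mean(axis=1)
    return pooled, (T, qh, kh, vh, A, C)


def fuse(params: dict, Xs: Sequence[np.ndarray]) -> np.ndarray:
    """Full fusion forward pass (no classification head): blocks -> (B, P)."""
    return attend(params, project_tokens(params, Xs))


def _loss_and_dlogits(logits: np.ndarray, y: np.ndarray):
    """Cross-entropy loss and its gradient w.r.t. logits.

    1-D integer ``y``: softmax cross-entropy; 2-D 0/1 ``y``: per-label
    sigmoid cross-entropy (multi-label).
    """
    B = logits.shape[0]
    if y.ndim == 1:
        p = _softmax(logits, axis=-1)
        eps = 1e-12
        loss = -np.log(p[np.arange(B), y] + eps).mean()
        d = p.copy()
        d[np.arange(B), y] -= 1.0
        return loss, d / B
    p = 1.0 / (1.0 + np.exp(-logits))
    eps = 1e-12
    loss = -(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)).mean()
    return loss, (p - y) / y.size


def _forward_backward(params: dict, Xs: Sequence[np.ndarray], y: np.ndarray):
    """One forward + backward pass; returns (loss, grads)."""
    H, Dh = params["n_heads"], params["d_head"]
    T = project_tokens(params, Xs)
    B, M, P = T.shape
    pooled, (T, qh, kh, vh, A, C) = _attend_cache(params, T)
    logits = pooled @ params["Wc"] + params["bc"]
    loss, dlogits = _loss_and_dlogits(logits, y)

    grads: dict = {}
    grads["Wc"] = pooled.T @ dlogits
    grads["bc"] = dlogits.sum(axis=0)
    dpooled = dlogits @ params["Wc"].T
    dO = np.broadcast_to(dpooled[:, None, :] / M, (B, M, P))

    C2 = C.reshape(-1, P)
    dO2 = dO.reshape(-1, P)
    grads["Wo"] = C2.T @ dO2
    dC = dO @ params["Wo"].T
    dOh = _split_heads(dC, H, Dh)

    dA = dOh @ vh.transpose(0, 1, 3, 2)
    dvh = A.transpose(0, 1, 3, 2) @ dOh
    dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
    scale = 1.0 / math.sqrt(Dh)
    dqh = dS @ kh * scale
    dkh = dS.transpose(0, 1, 3, 2) @ qh * scale

    dQ, dK, dV = (_merge_heads(X) for X in (dqh, dkh, dvh))
    T2 = T.reshape(-1, P)
    grads["Wq"] = T2.T @ dQ.reshape(-1, P)
    grads["Wk"] = T2.T @ dK.reshape(-1, P)
    grads["Wv"] = T2.T @ dV.reshape(-1, P)
    dT = dQ @ params["Wq"].T + dK @ params["Wk"].T + dV @ params["Wv"].T

    grads["Wp"] = [X.T @ dT[:, m, :] for m, X in enumerate(Xs)]
    grads["bp"] = [dT[:, m, :].sum(axis=0) for m in range(M)]
    return loss, grads


class _Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999):
        self.lr, self.b1, self.b2 = lr, beta1, beta2
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for key, g in grads.items():
            gs = g if isinstance(g, list) else [g]
            ps = params[key] if isinstance(g, list) else [params[key]]
            for i, (p, gi) in enumerate(zip(ps, gs)):
                slot = (key, i)
                m = self.m.setdefault(slot, np.zeros_like(gi))
                v = self.v.setdefault(slot, np.zeros_like(gi))
                m[:] = self.b1 * m + (1 - self.b1) * gi
                v[:] = self.b2 * v + (1 - self.b2) * gi**2
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + 1e-8)


def _predict_accuracy(params: dict, Xs: Sequence[np.ndarray], y: np.ndarray) -> float:
    logits = fuse(params, Xs) @ params["Wc"] + params["bc"]
    if y.ndim == 1:
        return float((logits.argmax(axis=1) == y).mean())
    return float(((logits > 0).astype(int) == y).mean())


def _copy_params(params: dict) -> dict:
    out = {}
    for k, v in params.items():
        if isinstance(v, list):
            out[k] = [x.copy() for x in v]
        elif isinstance(v, np.ndarray):
            out[k] = v.copy()
        else:
            out[k] = v
    return out


def train(
    Xs: Sequence[np.ndarray],
    y: np.ndarray,
    n_heads: int,
    d_head: int,
    epochs: int = 100,
    learning_rate: float = 1e-3,
    batch_size: int = 64,
    patience: int = 10,
    seed: int = 0,
    valid: tuple[Sequence[np.ndarray], np.ndarray] | None = None,
) -> dict:
    """Train the fusion block; returns the parameter dict without the head.

    Early stopping monitors validation accuracy (when a validation split is
    given) with the given patience; otherwise all epochs run.  Deterministic
    given ``seed``.
    """
    y = np.asarray(y)
    n_classes = int(y.shape[1]) if y.ndim == 2 else int(y.max()) + 1
    params = init_params([X.shape[1] for X in Xs], n_heads, d_head, n_classes, seed)
    opt = _Adam(learning_rate)
    rng = np.random.default_rng(seed + 1)
    n = Xs[0].shape[0]

    best = _copy_params(params)
    best_acc, stale = -np.inf, 0
    for epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            loss, grads = _forward_backward(params, [X[idx] for X in Xs], y[idx])
            if not np.isfinite(loss):
                raise TrainingDivergenceError(
                    f"non-finite loss at epoch {epoch}, lr={learning_rate}"
                )
            opt.step(params, grads)
        if valid is not None:
            acc = _predict_accuracy(params, valid[0], valid[1])
            if acc > best_acc:
                best_acc, best, stale = acc, _copy_params(params), 0
            else:
                stale += 1
                if stale >= patience:
                    break
    result = best if valid is not None else params
    result = _copy_params(result)
    result.pop("Wc", None)
    result.pop("bc", None)
    return result
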