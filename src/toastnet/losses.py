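"""Training losses: focal loss, KL regularizer, and their sum.

The classifier's native objective is the KL-focal loss: the scalar focal
term ``FL(p) = -(1-p)^gamma * log(p)`` on the true-class probability,
which down-weights easy confident samples under heavy class imbalance,
plus the divergence ``KL(P||Q) = sum_j P_j log(P_j / Q_j)`` between the
predicted distribution P and the target distribution Q, which keeps the
predictive distribution from collapsing during iterative fine-tuning.

A one-hot Q makes ``log(P/Q)`` diverge, so Q is label-smoothed (default
0.05) and both distributions are clipped at ``clip_epsilon`` and
renormalized before the divergence is taken; this is the central numerical
safeguard of the module. A menu of conventional losses (mean errors,
cross-entropy, forward KL) is provided for the comparison harness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LOSS_NAMES = (
    "mae",
    "mape",
    "mse",
    "msle",
    "cross_entropy",
    "kl",
    "focal",
    "kl_focal",
)


@dataclass(frozen=True)
class LossConfig:
    name: str = "kl_focal"
    gamma: float = 2.0
    clip_epsilon: float = 1e-7
    label_smoothing: float = 0.05

    def validate(self) -> None:
        if self.name not in LOSS_NAMES:
            raise ValueError(f"unknown loss '{self.name}'; choose from {LOSS_NAMES}")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if not 0 < self.clip_epsilon < 0.5:
            raise ValueError("clip_epsilon must lie in (0, 0.5)")
        if not 0 <= self.label_smoothing < 0.5:
            raise ValueError("label_smoothing must lie in [0, 0.5)")


def _clip_renorm(P: np.ndarray, eps: float) -> np.ndarray:
    P = np.clip(P, eps, 1.0)
    return P / P.sum(axis=-1, keepdims=True)


def smooth_labels(
    y: np.ndarray, n_classes: int, smoothing: float = 0.05
) -> np.ndarray:
    """One-hot targets with mass ``smoothing`` spread uniformly."""
    Q = np.full((len(y), n_classes), smoothing / n_classes)
    Q[np.arange(len(y)), y] += 1.0 - smoothing
    return Q


def focal_loss(
    p_true: np.ndarray | float, gamma: float = 2.0, clip_epsilon: float = 1e-7
) -> float:
    """Mean focal loss ``-(1-p)^gamma log(p)`` over samples.

    ``gamma = 0`` recovers the plain cross-entropy of the true class;
    larger gamma shrinks the contribution of well-classified samples.
    """
    p = np.clip(np.atleast_1d(np.asarray(p_true, dtype=float)), clip_epsilon, 1.0)
    return float(np.mean(-((1.0 - p) ** gamma) * np.log(p)))


def kl_term(
    P: np.ndarray, Q: np.ndarray, clip_epsilon: float = 1e-7
) -> np.ndarray | float:
    """Per-sample reverse divergence ``sum_j P_j log(P_j / Q_j)``.

    Both distributions are clipped to ``[clip_epsilon, 1]`` and
    renormalized first; the result is non-negative and zero iff P = Q.
    Accepts single rows or matrices (one value per row).
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if P.shape != Q.shape:
        raise ValueError(f"shape mismatch: P {P.shape} vs Q {Q.shape}")
    Pc = _clip_renorm(P, clip_epsilon)
    Qc = _clip_renorm(Q, clip_epsilon)
    out = np.sum(Pc * np.log(Pc / Qc), axis=-1)
    return float(out[0]) if out.shape == (1,) else out


def kl_focal_loss(
    P: np.ndarray, y_true: np.ndarray, config: LossConfig | None = None
) -> float:
    """Mean KL-focal loss over a batch: focal term + KL(P || smoothed Q)."""
    config = config or LossConfig()
    config.validate()
    P = np.atleast_2d(np.asarray(P, dtype=float))
    y = np.atleast_1d(np.asarray(y_true, dtype=int))
    Q = smooth_labels(y, P.shape[1], config.label_smoothing)
    p_true = P[np.arange(len(y)), y]
    fl = -((1.0 - np.clip(p_true, config.clip_epsilon, 1.0)) ** config.gamma) * np.log(
        np.clip(p_true, config.clip_epsilon, 1.0)
    )
    kl = np.atleast_1d(kl_term(P, Q, config.clip_epsilon))
    return float(np.mean(fl + kl))


def _focal_grad(p: np.ndarray, gamma: float, eps: float) -> np.ndarray:
    """d/dp of -(1-p)^gamma log(p), kept finite at p -> 1."""
    pm = np.clip(p, eps, 1.0 - eps)
    if gamma == 0.0:
        return -1.0 / pm
    return gamma * (1.0 - pm) ** (gamma - 1.0) * np.log(pm) - (1.0 - pm) ** gamma / pm


def loss_and_grad(
    P: np.ndarray, y_true: np.ndarray, config: LossConfig
) -> tuple[float, np.ndarray]:
    """Batch-mean loss and its gradient with respect to P.

    Used by the training loop; the clip/renormalize safeguards are treated
    as identity in the gradient (straight-through), which keeps gradients
    finite on one-hot targets.
    """
    config.validate()
    P = np.atleast_2d(np.asarray(P, dtype=float))
    y = np.atleast_1d(np.asarray(y_true, dtype=int))
    n, k = P.shape
    eps = config.clip_epsilon
    Q = smooth_labels(y, k, config.label_smoothing)
    Pc = np.clip(P, eps, 1.0)
    Qc = np.clip(Q, eps, 1.0)
    name = config.name
    rows = np.arange(n)

    if name == "mae":
        loss = np.mean(np.abs(Pc - Qc))
        grad = np.sign(Pc - Qc) / (n * k)
    elif name == "mape":
        loss = np.mean(np.abs(Pc - Qc) / Qc)
        grad = np.sign(Pc - Qc) / Qc / (n * k)
    elif name == "mse":
        loss = np.mean((Pc - Qc) ** 2)
        grad = 2.0 * (Pc - Qc) / (n * k)
    elif name == "msle":
        diff = np.log1p(Pc) - np.log1p(Qc)
        loss = np.mean(diff**2)
        grad = 2.0 * diff / (1.0 + Pc) / (n * k)
    elif name == "cross_entropy":
        loss = np.mean(-np.sum(Qc * np.log(Pc), axis=1))
        grad = -Qc / Pc / n
    elif name == "kl":
        # forward divergence KL(Q||P), the conventional "KL loss"
        loss = np.mean(np.sum(Qc * np.log(Qc / Pc), axis=1))
        grad = -Qc / Pc / n
    elif name == "focal":
        p = Pc[rows, y]
        loss = np.mean(-((1.0 - p) ** config.gamma) * np.log(p))
        grad = np.zeros_like(P)
        grad[rows, y] = _focal_grad(p, config.gamma, eps) / n
    elif name == "kl_focal":
        p = Pc[rows, y]
        g = config.gamma
        fl = -((1.0 - p) ** g) * np.log(p)
        kl = np.sum(Pc * np.log(Pc / Qc), axis=1)
        loss = np.mean(fl + kl)
        grad = (np.log(Pc / Qc) + 1.0) / n
        grad[rows, y] += _focal_grad(p, g, eps) / n
    else:  # pragma: no cover - guarded by validate()
        raise ValueError(name)
    return float(loss), grad
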