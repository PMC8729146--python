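"""Causal-convolution classifier in its four architectural variants.

The network reads a patient's features as an importance-ordered sequence
``x_0, x_1, ..., x_t`` (most important first) and predicts the subtype
distribution from the final representation, ``Y_t = f(x_0, ..., x_t)``.
Every convolution uses causal (left-only) padding, so activations at
sequence position t never depend on features ranked after t — the network
cannot peek at less-important features when interpreting an earlier one,
mirroring how a clinician layers evidence.

All four variants share a first causal convolution; they differ in what
follows it:

* **V1** — a second, strided causal convolution.
* **V2** — temporal max pooling instead of the second convolution.
* **V3** — both branches of V1 and V2, concatenated channel-wise.
* **V4** — V3 plus the (down-sampled) output of the first convolution
  fused in as a third branch; the richest receptive-field mix.

The head pools each branch over time and applies a two-layer dense
classifier with a softmax output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .losses import LossConfig, loss_and_grad
from .nn import (
    Adam,
    CausalConv1D,
    Dense,
    Downsample,
    GlobalAvgPool,
    MaxPool1D,
    ReLU,
    softmax,
    softmax_backward,
)

VARIANTS = ("V1", "V2", "V3", "V4")


@dataclass(frozen=True)
class NetworkSpec:
    """Hyperparameters of the causal classifier.

    ``conv1``/``conv2`` are (filters, kernel, stride) triples; ``pool`` is
    (window, stride). Defaults give the parameter-count ordering
    V2 < V1 < V3 < V4 across variants.
    """

    variant: str = "V4"
    sequence_length: int = 93
    conv1: tuple[int, int, int] = (32, 4, 1)
    conv2: tuple[int, int, int] = (24, 3, 2)
    pool: tuple[int, int] = (2, 2)
    head_width: int = 64
    n_classes: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        for name, triple in (("conv1", self.conv1), ("conv2", self.conv2)):
            if any(v < 1 for v in triple):
                raise ValueError(f"{name} filters/kernel/stride must be positive")
        if any(v < 1 for v in self.pool):
            raise ValueError("pool window/stride must be positive")
        min_len = max(self.conv1[1], self.conv2[1], self.pool[0])
        if self.sequence_length < min_len:
            raise ValueError(
                f"sequence_length {self.sequence_length} shorter than the "
                f"largest kernel/window ({min_len})"
            )


class CausalCNN:
    """A built network: layers, forward/backward, and training state."""

    def __init__(self, spec: NetworkSpec) -> None:
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        f1, k1, s1 = spec.conv1
        f2, k2, s2 = spec.conv2
        self.conv1 = CausalConv1D(1, f1, k1, s1, rng)
        self.relu1 = ReLU()
        self.conv2 = CausalConv1D(f1, f2, k2, s2, rng)
        self.relu2 = ReLU()
        self.pool = MaxPool1D(*spec.pool)
        self.down = Downsample(s2)
        self.gap = GlobalAvgPool()
        head_in = {
            "V1": f2,
            "V2": f1,
            "V3": f1 + f2,
            "V4": f1 + f2 + f1,
        }[spec.variant]
        self.dense1 = Dense(head_in, spec.head_width, rng)
        self.relu3 = ReLU()
        self.dense2 = Dense(spec.head_width, spec.n_classes, rng)
        self._branch_lengths: list[int] = []

    # -- plumbing ---------------------------------------------------------

    def _layers(self) -> list:
        # V2 has no second convolution; its weights must not count or train
        if self.spec.variant == "V2":
            return [self.conv1, self.dense1, self.dense2]
        return [self.conv1, self.conv2, self.dense1, self.dense2]

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._layers() for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers():
            out.extend([layer.dW, layer.db])
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p[...] = w

    # -- forward / backward ----------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Probabilities for ``x`` of shape (batch, sequence_length)."""
        if x.ndim != 2 or x.shape[1] != self.spec.sequence_length:
            raise ValueError(
                f"expected input of shape (n, {self.spec.sequence_length}), "
                f"got {x.shape}"
            )
        h = self.relu1.forward(self.conv1.forward(x[:, :, None]))
        variant = self.spec.variant
        if variant == "V1":
            branches = [self.relu2.forward(self.conv2.forward(h))]
        elif variant == "V2":
            branches = [self.pool.forward(h)]
        elif variant == "V3":
            branches = [
                self.pool.forward(h),
                self.relu2.forward(self.conv2.forward(h)),
            ]
        else:  # V4
            branches = [
                self.pool.forward(h),
                self.relu2.forward(self.conv2.forward(h)),
                self.down.forward(h),
            ]
        m = min(b.shape[1] for b in branches)
        self._branch_lengths = [b.shape[1] for b in branches]
        merged = np.concatenate([b[:, :m, :] for b in branches], axis=2)
        feat = self.gap.forward(merged)
        z = self.dense2.forward(self.relu3.forward(self.dense1.forward(feat)))
        self._P = softmax(z)
        self._channels = [b.shape[2] for b in branches]
        return self._P

    def backward(self, dP: np.ndarray) -> None:
        dz = softmax_backward(self._P, dP)
        dfeat = self.dense1.backward(self.relu3.backward(self.dense2.backward(dz)))
        dmerged = self.gap.backward(dfeat)
        variant = self.spec.variant
        splits = np.cumsum(self._channels)[:-1]
        parts = np.split(dmerged, splits, axis=2)
        dh = None
        for part, full_len, kind in zip(
            parts, self._branch_lengths, self._branch_kinds()
        ):
            if part.shape[1] < full_len:  # undo the crop
                pad = full_len - part.shape[1]
                part = np.pad(part, ((0, 0), (0, pad), (0, 0)))
            if kind == "pool":
                g = self.pool.backward(part)
            elif kind == "conv2":
                g = self.conv2.backward(self.relu2.backward(part))
            else:  # identity branch
                g = self.down.backward(part)
            dh = g if dh is None else dh + g
        self.conv1.backward(self.relu1.backward(dh))

    def _branch_kinds(self) -> list[str]:
        return {
            "V1": ["conv2"],
            "V2": ["pool"],
            "V3": ["pool", "conv2"],
            "V4": ["pool", "conv2", "down"],
        }[self.spec.variant]

    # -- introspection ----------------------------------------------------

    def conv_trace(self, x: np.ndarray) -> dict[str, tuple[np.ndarray, int]]:
        """Causal-convolution activations with their input strides.

        Returns ``{layer: (activation, stride)}`` where output position i
        of the layer depends only on input positions ``<= i * stride``.
        """
        h1 = self.conv1.forward(x[:, :, None])
        s1 = self.spec.conv1[2]
        out = {"conv1": (h1, s1)}
        if self.spec.variant != "V2":
            h2 = self.conv2.forward(self.relu1.forward(h1))
            out["conv2"] = (h2, s1 * self.spec.conv2[2])
        return out

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {f"w{i}": p for i, p in enumerate(self.parameters())}
        np.savez(path, spec=json.dumps(asdict(self.spec)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CausalCNN":
        with np.load(path, allow_pickle=False) as archive:
            raw = json.loads(str(archive["spec"]))
            raw["conv1"] = tuple(raw["conv1"])
            raw["conv2"] = tuple(raw["conv2"])
            raw["pool"] = tuple(raw["pool"])
            model = cls(NetworkSpec(**raw))
            model.set_weights(
                [archive[f"w{i}"] for i in range(len(model.parameters()))]
            )
        return model


def build_network(spec: NetworkSpec) -> CausalCNN:
    """Instantiate the variant described by ``spec`` with seeded weights."""
    return CausalCNN(spec)


def count_parameters(model: CausalCNN) -> int:
    """Total number of trainable scalar parameters."""
    return int(sum(p.size for p in model.parameters()))


def train(
    model: CausalCNN,
    X: np.ndarray,
    y: np.ndarray,
    loss: LossConfig | None = None,
    epochs: int = 100,
    batch_size: int = 32,
    seed: int = 0,
    learning_rate: float = 1e-3,
    optimizer: Adam | None = None,
) -> list[float]:
    """Mini-batch training; returns the per-epoch mean loss history.

    ``epochs = 0`` leaves the model untouched. Passing an existing
    ``optimizer`` continues its moment estimates (used by fine-tuning);
    otherwise a fresh Adam state is created.
    """
    loss = loss or LossConfig()
    loss.validate()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if len(X) == 0:
        raise ValueError("empty training data")
    if y.min() < 0 or y.max() >= model.spec.n_classes:
        raise ValueError(
            f"labels must lie in [0, {model.spec.n_classes - 1}], "
            f"got range [{y.min()}, {y.max()}]"
        )
    if epochs == 0:
        return []
    rng = np.random.default_rng(seed)
    opt = optimizer or Adam(model.parameters(), lr=learning_rate)
    history = []
    n = len(X)
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            P = model.forward(X[idx])
            value, dP = loss_and_grad(P, y[idx], loss)
            model.backward(dP)
            opt.step(model.gradients())
            epoch_loss += value * len(idx)
        history.append(epoch_loss / n)
    return history


def predict_proba(model: CausalCNN, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Row-normalized class probabilities, one row per sample."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.spec.sequence_length:
        raise ValueError(
            f"feature length {X.shape[1] if X.ndim == 2 else '?'} does not "
            f"match the network's sequence_length {model.spec.sequence_length}"
        )
    chunks = [
        model.forward(X[i : i + batch_size]) for i in range(0, len(X), batch_size)
    ]
    P = np.vstack(chunks)
    return P / P.sum(axis=1, keepdims=True)
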