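"""Tabular MLP encoder trained with imbalance-aware objectives.

The encoder maps a mixed-type patient record to a dense latent vector:
z-scored (and importance-weighted) continuous inputs are concatenated with
learned embeddings of the categorical/boolean features (each embedding
scaled by its feature's importance weight), passed through two fully
connected ReLU layers (hidden1 -> hidden2) with dropout, and a single-logit
head used only for pre-training.  The post-activation values of the second
hidden layer are the latent representation consumed by the downstream
random-forest head.

Implemented directly on numpy (manual backpropagation, Adam, linear
learning-rate warm-up, early stopping on validation AUROC with best-weight
restoration); training is fully reproducible under fixed seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .losses import (
    compute_pos_weight,
    focal_grad,
    focal_loss,
    make_sampler_weights,
    weighted_bce_grad,
    weighted_bce_loss,
)

__all__ = [
    "EncoderConfig",
    "TrainingConfig",
    "WeightedInput",
    "TabularEncoder",
    "train_encoder",
    "extract_latents",
]


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture of the tabular encoder (tuned defaults)."""

    hidden1: int = 256
    hidden2: int = 64
    dropout: float = 0.43
    embedding_dim: int = 8
    activation: str = "relu"
    seed: int = 0

    def __post_init__(self):
        if self.hidden1 <= 0 or self.hidden2 <= 0 or self.embedding_dim <= 0:
            raise ValueError("layer widths must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.activation not in ("relu", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings (tuned defaults)."""

    batch_size: int = 256
    learning_rate: float = 2.16e-3
    max_epochs: int = 50
    warmup_epochs: int = 5
    early_stopping_patience: int = 10
    pos_weight: float | str = "auto"
    loss_kind: str = "weighted_bce"  # "weighted_bce" | "focal"
    focal_alpha: float = 1.0
    focal_gamma: float = 2.0
    sampler: str = "weighted"  # "weighted" | "plain"
    seed: int = 0

    def __post_init__(self):
        if self.warmup_epochs >= self.max_epochs:
            raise ValueError("warmup_epochs must be smaller than max_epochs")
        if isinstance(self.pos_weight, (int, float)) and self.pos_weight <= 0:
            raise ValueError("pos_weight must be positive")
        if self.loss_kind not in ("weighted_bce", "focal"):
            raise ValueError(f"unknown loss kind {self.loss_kind!r}")
        if self.sampler not in ("weighted", "plain"):
            raise ValueError(f"unknown sampler {self.sampler!r}")


@dataclass
class WeightedInput:
    """Encoder-ready input: weighted numerics plus categorical codes.

    ``numeric`` already carries the per-feature importance weights;
    ``code_weights[j]`` scales the whole embedding vector of code feature j
    at lookup time.
    """

    numeric: np.ndarray
    codes: np.ndarray
    code_weights: np.ndarray
    cardinalities: tuple[int, ...]
    numeric_names: tuple[str, ...]
    code_names: tuple[str, ...]
    labels: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.numeric.shape[0]

    def take(self, idx: np.ndarray) -> "WeightedInput":
        return WeightedInput(
            self.numeric[idx],
            self.codes[idx],
            self.code_weights,
            self.cardinalities,
            self.numeric_names,
            self.code_names,
            None if self.labels is None else self.labels[idx],
        )


def warmup_lr(base_lr: float, epoch: int, warmup_epochs: int) -> float:
    """Linear ramp from base_lr/10 (epoch 1) to base_lr (epoch == warmup)."""
    if warmup_epochs <= 1 or epoch >= warmup_epochs:
        return base_lr
    frac = (epoch - 1) / (warmup_epochs - 1)
    return base_lr * (0.1 + 0.9 * frac)


class TabularEncoder:
    """Two-hidden-layer MLP with categorical embeddings (numpy)."""

    def __init__(
        self,
        n_numeric: int,
        cardinalities: Sequence[int],
        config: EncoderConfig | None = None,
    ):
        self.config = config or EncoderConfig()
        self.n_numeric = int(n_numeric)
        self.cardinalities = tuple(int(c) for c in cardinalities)
        c = self.config
        self.d_in = self.n_numeric + len(self.cardinalities) * c.embedding_dim
        rng = np.random.default_rng(c.seed)
        he = lambda fan_in, shape: rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
        self.params: dict[str, np.ndarray] = {
            "W0": he(self.d_in, (self.d_in, c.hidden1)),
            "b0": np.zeros(c.hidden1),
            "W1": he(c.hidden1, (c.hidden1, c.hidden2)),
            "b1": np.zeros(c.hidden2),
            "W2": he(c.hidden2, (c.hidden2, 1)),
            "b2": np.zeros(1),
        }
        for j, card in enumerate(self.cardinalities):
            self.params[f"E{j}"] = rng.normal(0.0, 0.1, size=(card, c.embedding_dim))

    # -- forward -------------------------------------------------------------

    def _act(self, a: np.ndarray) -> np.ndarray:
        return np.maximum(a, 0.0) if self.config.activation == "relu" else np.tanh(a)

    def _act_grad(self, a: np.ndarray, h: np.ndarray) -> np.ndarray:
        return (a > 0).astype(float) if self.config.activation == "relu" else 1.0 - h**2

    def _assemble(self, batch: WeightedInput) -> np.ndarray:
        parts = [batch.numeric]
        for j in range(len(self.cardinalities)):
            emb = self.params[f"E{j}"][batch.codes[:, j]]
            parts.append(emb * batch.code_weights[j])
        return np.hstack(parts) if parts else batch.numeric

    def forward(
        self, batch: WeightedInput, train: bool = False, rng: np.random.Generator | None = None
    ):
        p, c = self.params, self.config
        X = self._assemble(batch)
        a0 = X @ p["W0"] + p["b0"]
        h0 = self._act(a0)
        if train and c.dropout > 0:
            m0 = (rng.random(h0.shape) >= c.dropout) / (1.0 - c.dropout)
            h0d = h0 * m0
        else:
            m0, h0d = None, h0
        a1 = h0d @ p["W1"] + p["b1"]
        h1 = self._act(a1)
        if train and c.dropout > 0:
            m1 = (rng.random(h1.shape) >= c.dropout) / (1.0 - c.dropout)
            h1d = h1 * m1
        else:
            m1, h1d = None, h1
        logit = (h1d @ p["W2"] + p["b2"])[:, 0]
        cache = (X, a0, h0, m0, h0d, a1, h1, m1, h1d)
        return logit, cache

    def backward(self, batch: WeightedInput, cache, dlogit: np.ndarray):
        p, c = self.params, self.config
        X, a0, h0, m0, h0d, a1, h1, m1, h1d = cache
        g: dict[str, np.ndarray] = {}
        dl = dlogit[:, None]
        g["W2"] = h1d.T @ dl
        g["b2"] = dl.sum(axis=0)
        dh1d = dl @ p["W2"].T
        if m1 is not None:
            dh1d = dh1d * m1
        da1 = dh1d * self._act_grad(a1, h1)
        g["W1"] = h0d.T @ da1
        g["b1"] = da1.sum(axis=0)
        dh0d = da1 @ p["W1"].T
        if m0 is not None:
            dh0d = dh0d * m0
        da0 = dh0d * self._act_grad(a0, h0)
        g["W0"] = X.T @ da0
        g["b0"] = da0.sum(axis=0)
        dX = da0 @ p["W0"].T
        off = self.n_numeric
        k = c.embedding_dim
        for j, card in enumerate(self.cardinalities):
            dEj = np.zeros_like(p[f"E{j}"])
            demb = dX[:, off : off + k] * batch.code_weights[j]
            np.add.at(dEj, batch.codes[:, j], demb)
            g[f"E{j}"] = dEj
            off += k
        return g

    # -- inference -----------------------------------------------------------

    def predict_logits(self, inputs: WeightedInput) -> np.ndarray:
        logit, _ = self.forward(inputs, train=False)
        return logit

    def latents(self, inputs: WeightedInput) -> np.ndarray:
        """Post-activation second-hidden-layer values (dropout disabled)."""
        _, cache = self.forward(inputs, train=False)
        return cache[6]

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}


class _Adam:
    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params, grads, lr):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, gk in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk**2
            params[k] -= lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def train_encoder(
    train_inputs: WeightedInput,
    val_inputs: WeightedInput,
    enc_config: EncoderConfig | None = None,
    train_config: TrainingConfig | None = None,
) -> tuple[TabularEncoder, pd.DataFrame]:
    """Train the encoder; returns the best-validation-AUROC snapshot.

    The history DataFrame records per-epoch mean training loss, the learning
    rate actually used (showing the warm-up ramp) and validation AUROC.
    """
    enc_config = enc_config or EncoderConfig()
    tr = train_config or TrainingConfig()
    y = train_inputs.labels
    if y is None or val_inputs.labels is None:
        raise ValueError("labelled train and validation inputs are required")

    encoder = TabularEncoder(
        train_inputs.numeric.shape[1], train_inputs.cardinalities, enc_config
    )
    rng = np.random.default_rng(tr.seed)
    optimizer = _Adam(encoder.params)

    pos_weight = (
        compute_pos_weight(y) if tr.pos_weight == "auto" else float(tr.pos_weight)
    )
    sample_p = make_sampler_weights(y) if tr.sampler == "weighted" else None

    n = train_inputs.n
    steps = max(1, int(np.ceil(n / tr.batch_size)))
    best_auc = -np.inf
    best_params = encoder.copy_params()
    best_epoch = 0
    rows = []
    for epoch in range(1, tr.max_epochs + 1):
        lr = warmup_lr(tr.learning_rate, epoch, tr.warmup_epochs)
        if sample_p is None:
            order = rng.permutation(n)
        losses = []
        for step in range(steps):
            if sample_p is not None:
                idx = rng.choice(n, size=min(tr.batch_size, n), replace=True, p=sample_p)
            else:
                idx = order[step * tr.batch_size : (step + 1) * tr.batch_size]
                if idx.size == 0:
                    continue
            batch = train_inputs.take(idx)
            logit, cache = encoder.forward(batch, train=True, rng=rng)
            yb = batch.labels.astype(float)
            if tr.loss_kind == "weighted_bce":
                loss = weighted_bce_loss(logit, yb, pos_weight)
                dlogit = weighted_bce_grad(logit, yb, pos_weight)
            else:
                loss = focal_loss(logit, yb, tr.focal_alpha, tr.focal_gamma)
                dlogit = focal_grad(logit, yb, tr.focal_alpha, tr.focal_gamma)
            mean_loss = float(np.mean(loss))
            if not np.isfinite(mean_loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, step {step} "
                    f"(lr={lr:g}, loss_kind={tr.loss_kind})"
                )
            losses.append(mean_loss)
            grads = encoder.backward(batch, cache, dlogit / len(idx))
            optimizer.step(encoder.params, grads, lr)

        val_logits = encoder.predict_logits(val_inputs)
        val_auc = float(roc_auc_score(val_inputs.labels, val_logits))
        rows.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_loss": float(np.mean(losses)),
                "val_auroc": val_auc,
            }
        )
        if val_auc > best_auc:
            best_auc = val_auc
            best_params = encoder.copy_params()
            best_epoch = epoch
        elif epoch - best_epoch >= tr.early_stopping_patience:
            break

    encoder.set_params(best_params)
    history = pd.DataFrame(rows)
    history.attrs["best_epoch"] = best_epoch
    history.attrs["best_val_auroc"] = best_auc
    return encoder, history


def extract_latents(encoder: TabularEncoder, inputs: WeightedInput) -> np.ndarray:
    """Latent matrix (n x hidden2) of penultimate post-activation values."""
    return encoder.latents(inputs)
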