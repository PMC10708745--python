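"""Multi-input-multi-output attention CNN for the three maturity targets.

The network ingests a (samples, L, 3) stack of three pre-treatments of the
same spectrum -- reflectance, SNV of pseudo-absorbance, and the first SG
derivative of pseudo-absorbance -- chosen for their complementary
information (albedo/scatter, baseline-corrected shape, fine absorption
structure).  An 8-head self-attention layer over the L wavelength positions
(query/key/value dimension 64 per head, output projected back to width 3)
feeds a three-stage convolutional stack

    conv(128, k=5) -> dropout 0.2 -> pool 2 ->
    conv(64, k=7)  -> dropout 0.2 -> pool 2 ->
    conv(32, k=7)  -> flatten -> dense 128 -> 64 -> 32

with ReLU activations throughout, L2 kernel penalty 0.01 on every
convolutional layer, and three single-unit linear regression heads (Brix,
pH, TA).  Training minimizes the equally weighted sum of per-output mean
squared errors with Adam at learning rate 0.001.

Targets are z-scored per output on the training rows before the loss is
computed (equal-weight MSE across degrees Brix, pH units and g/L would
otherwise be dominated by the widest scale) and de-standardized at
prediction.  Input channels are standardized per channel by a
:class:`ChannelScaler` fitted on calibration rows only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import nn, pretreat
from .io import SpectralLibrary

#: channel order of the multi-input stack; immutable contract
CHANNEL_SOURCES = ("REF", "ABS_SNV", "ABS_SG1")

OUTPUT_NAMES = ("brix", "ph", "ta")


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass(frozen=True)
class ArchitectureSpec:
    """The fixed network architecture (see module docstring)."""

    heads: int = 8
    head_dim: int = 64
    conv_filters: tuple[int, ...] = (128, 64, 32)
    conv_kernels: tuple[int, ...] = (5, 7, 7)
    dense_units: tuple[int, ...] = (128, 64, 32)
    dropout: float = 0.2
    pool: int = 2
    conv_l2: float = 0.01


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization contract: Adam at lr 0.001, summed per-output MSE."""

    learning_rate: float = 1e-3
    epochs: int = 500
    batch_size: int = 16
    patience: int = 50
    val_fraction: float = 0.1
    seed: int = 0


@dataclass
class ChannelScaler:
    """Per-channel standardization, fitted on calibration rows only.

    Each of the three input channels is centred and scaled to unit standard
    deviation over all calibration samples and wavelengths.  Channel-wise
    standardization (rather than squashing into [0, 1]) matters here: the
    attention scores are quadratic in the input values, so unit-scale
    inputs give the softmax enough initial dynamic range for the query/key
    weights to receive usable gradients.
    """

    means: Optional[np.ndarray] = None
    sds: Optional[np.ndarray] = None

    def fit(self, x: np.ndarray) -> "ChannelScaler":
        self.means = x.mean(axis=(0, 1))
        sds = x.std(axis=(0, 1))
        sds[sds == 0] = 1.0
        self.sds = sds
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.means is None:
            raise RuntimeError("scaler not fitted")
        return (x - self.means) / self.sds


def stack_channels(lib: SpectralLibrary) -> np.ndarray:
    """(samples, L, 3) stack in the order REF, ABS_SNV, ABS_SG1 (unscaled)."""
    mats = [pretreat.apply_source(lib, src) for src in CHANNEL_SOURCES]
    return np.stack(mats, axis=-1)


class AttentionCNN:
    """The built network: attention + conv trunk + three regression heads."""

    def __init__(self, L: int, D: int = 3, spec: ArchitectureSpec | None = None,
                 seed: int = 0):
        if L < 8:
            raise ValueError(f"sequence length L={L} too short (min 8)")
        spec = spec or ArchitectureSpec()
        self.L, self.D, self.spec, self.seed = L, D, spec, seed
        rng = np.random.default_rng(seed)

        self.attention_layer = nn.MultiHeadSelfAttention(
            D, spec.heads, spec.head_dim, rng
        )
        layers: list[nn.Layer] = [self.attention_layer]
        length, channels = L, D
        f1, f2, f3 = spec.conv_filters
        k1, k2, k3 = spec.conv_kernels
        layers += [
            nn.Conv1D(channels, f1, k1, rng, l2=spec.conv_l2),
            nn.Dropout(spec.dropout),
            nn.MaxPool1D(spec.pool),
        ]
        length //= spec.pool
        layers += [
            nn.Conv1D(f1, f2, k2, rng, l2=spec.conv_l2),
            nn.Dropout(spec.dropout),
            nn.MaxPool1D(spec.pool),
        ]
        length //= spec.pool
        layers += [nn.Conv1D(f2, f3, k3, rng, l2=spec.conv_l2), nn.Flatten()]
        self.flat_width = length * f3
        width = self.flat_width
        for units in spec.dense_units:
            layers.append(nn.Dense(width, units, rng))
            width = units
        self.trunk = nn.Sequential(layers)
        self.heads = [
            nn.Dense(width, 1, rng, activation="linear") for _ in OUTPUT_NAMES
        ]
        # target standardization, set by train()
        self.y_mean = np.zeros(len(OUTPUT_NAMES))
        self.y_std = np.ones(len(OUTPUT_NAMES))

    # -- plumbing ---------------------------------------------------------
    def _forward(self, x, training, rng):
        h = self.trunk.forward(x, training, rng)
        cols = [head.forward(h, training, rng) for head in self.heads]
        return np.concatenate(cols, axis=1)  # standardized predictions

    def _backward(self, dpred):
        dh = sum(
            head.backward(dpred[:, [j]]) for j, head in enumerate(self.heads)
        )
        self.trunk.backward(dh)

    def _all_layers(self):
        return self.trunk.layers + self.heads

    def get_weights(self):
        return [{k: v.copy() for k, v in l.params.items()}
                for l in self._all_layers()]

    def set_weights(self, weights):
        for layer, w in zip(self._all_layers(), weights):
            for k in layer.params:
                layer.params[k][...] = w[k]

    # -- public API -------------------------------------------------------
    def predict(self, x: np.ndarray) -> np.ndarray:
        """(N, 3) predictions on the original target scales."""
        x = np.asarray(x)
        if x.ndim != 3 or x.shape[1] != self.L or x.shape[2] != self.D:
            raise ValueError(
                f"expected input of shape (N, {self.L}, {self.D}), got {x.shape}"
            )
        z = self._forward(x, training=False, rng=None)
        return z * self.y_std + self.y_mean

    def attention_weights(self, x: np.ndarray) -> np.ndarray:
        """Attention tensor (N, heads, L, L), softmax over the key axis."""
        x = np.asarray(x)
        if x.ndim != 3 or x.shape[1] != self.L or x.shape[2] != self.D:
            raise ValueError(
                f"expected input of shape (N, {self.L}, {self.D}), got {x.shape}"
            )
        return self.attention_layer.weights(x)


def build_network(
    L: int, D: int = 3, spec: ArchitectureSpec | None = None, seed: int = 0
) -> AttentionCNN:
    """Construct the (untrained) network with seeded initialization."""
    return AttentionCNN(L, D, spec, seed)


def _batch_losses(pred: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.mean((pred - y) ** 2, axis=0)


def train(
    model: AttentionCNN,
    X: np.ndarray,
    Y: np.ndarray,
    cfg: TrainingConfig | None = None,
) -> pd.DataFrame:
    """Train in place; returns the per-epoch loss history.

    History columns: epoch, loss_total, loss_brix, loss_ph, loss_ta (training
    losses on standardized targets, averaged over batches) and, when a
    validation split is active, val_loss_total.  Early stopping monitors the
    validation loss with the configured patience and restores the best
    weights.  Fully deterministic given ``cfg.seed`` and threading.
    """
    cfg = cfg or TrainingConfig()
    X = np.asarray(X, dtype=nn.DTYPE)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != len(OUTPUT_NAMES):
        raise ValueError(f"Y must be (N, {len(OUTPUT_NAMES)})")
    if X.shape[0] < cfg.batch_size and X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    rng = np.random.default_rng(cfg.seed)

    n = X.shape[0]
    n_val = int(round(cfg.val_fraction * n)) if cfg.val_fraction > 0 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, Ytr = X[tr_idx], Y[tr_idx]
    Xva, Yva = X[val_idx], Y[val_idx]

    model.y_mean = Ytr.mean(axis=0)
    std = Ytr.std(axis=0)
    std[std == 0] = 1.0
    model.y_std = std
    Ztr = ((Ytr - model.y_mean) / model.y_std).astype(nn.DTYPE)
    Zva = ((Yva - model.y_mean) / model.y_std).astype(nn.DTYPE)

    optimizer = nn.Adam(learning_rate=cfg.learning_rate)
    layers = model._all_layers()

    best_val = np.inf
    best_weights = model.get_weights()
    wait = 0
    rows = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(tr_idx))
        batch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, zb = Xtr[idx], Ztr[idx]
            pred = model._forward(xb, training=True, rng=rng)
            per_out = _batch_losses(pred, zb)
            total = per_out.sum() + model.trunk.penalty()
            if not np.isfinite(total):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}: per-output {per_out}"
                )
            batch_losses.append(per_out)
            dpred = (2.0 / len(idx)) * (pred - zb)
            model._backward(dpred.astype(nn.DTYPE))
            optimizer.step(layers)
        mean_losses = np.mean(batch_losses, axis=0)
        row = {
            "epoch": epoch,
            "loss_total": float(mean_losses.sum() + model.trunk.penalty()),
            **{
                f"loss_{name}": float(mean_losses[j])
                for j, name in enumerate(OUTPUT_NAMES)
            },
        }
        if n_val:
            val_pred = model._forward(Xva, training=False, rng=None)
            val_total = float(_batch_losses(val_pred, Zva).sum())
            row["val_loss_total"] = val_total
            if val_total < best_val - 1e-7:
                best_val = val_total
                best_weights = model.get_weights()
                wait = 0
            else:
                wait += 1
                if wait >= cfg.patience:
                    rows.append(row)
                    break
        rows.append(row)
    if n_val:
        model.set_weights(best_weights)
    return pd.DataFrame(rows)


def predict(model: AttentionCNN, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


def attention_weights(model: AttentionCNN, X: np.ndarray) -> np.ndarray:
    return model.attention_weights(X)


def save_model(model: AttentionCNN, path) -> None:
    """Serialize architecture, scaling and weights to an .npz checkpoint."""
    arrays = {"y_mean": model.y_mean, "y_std": model.y_std,
              "meta": np.array([model.L, model.D, model.seed])}
    for li, layer in enumerate(model._all_layers()):
        for k, v in layer.params.items():
            arrays[f"w_{li}_{k}"] = v
    np.savez(path, **arrays)


def load_model(path, spec: ArchitectureSpec | None = None) -> AttentionCNN:
    with np.load(path) as data:
        L, D, seed = (int(v) for v in data["meta"])
        model = AttentionCNN(L, D, spec, seed)
        model.y_mean = data["y_mean"]
        model.y_std = data["y_std"]
        for li, layer in enumerate(model._all_layers()):
            for k in layer.params:
                layer.params[k][...] = data[f"w_{li}_{k}"]
    return model
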