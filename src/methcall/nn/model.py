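"""Dual-branch convolutional read classifier.

The sequence branch consumes an l x 9 tensor (4 signal statistics + 5-channel
one-hot sequence) through 6 stride-1 convolutional layers of 256 size-4
filters, each followed by batch normalization and ReLU, ending in global
average pooling. The error branch consumes an l x 9 tensor (quality +
mismatch/insertion/deletion indicators + one-hot) through 3 convolutional
layers of 128 size-3 filters, a size-2 max pool, 3 locally connected layers
of 128 size-3 filters (untied weights per position), and global average
pooling. Pooled branch outputs are concatenated into a 512-unit fully
connected layer and a single sigmoid output: the per-read methylation
probability of the centre base. A read is called methylated when the score
is >= 0.5. Either branch can run as a standalone model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ..features import CORE_SIGNAL_FEATURES, ERROR_FEATURES, ReadWindow, one_hot_encode
from .layers import (
    DTYPE,
    Adam,
    BatchNorm1D,
    Conv1D,
    Dense,
    GlobalAvgPool1D,
    Layer,
    LocallyConnected1D,
    MaxPool1D,
    ReLU,
    Sequential,
    bce_loss,
    sigmoid,
)

#: Phred qualities are mapped to [0,1] by this divisor before entering the net
QUALITY_SCALE = 40.0

MODES = ("joint", "sequence_only", "error_only")


@dataclass(frozen=True)
class ConvSpec:
    n_layers: int
    n_filters: int
    kernel_size: int
    stride: int = 1
    padding: str = "same"
    batch_norm: bool = True
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.stride != 1:
            raise ValueError("stride is fixed to 1")
        if self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")


@dataclass(frozen=True)
class ModelSpec:
    mode: str = "joint"
    sequence_conv: ConvSpec = field(default_factory=lambda: ConvSpec(6, 256, 4))
    error_conv: ConvSpec = field(default_factory=lambda: ConvSpec(3, 128, 3))
    error_local: ConvSpec = field(default_factory=lambda: ConvSpec(3, 128, 3))
    head_units: int = 512
    pool_size: int = 2

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclass
class TrainingConfig:
    learning_rate: float = 0.00125
    batch_size: int = 512
    max_epochs: int = 10
    patience: int = 3
    seed: int = 0
    class_balance: bool = True

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.learning_rate < 0:
            raise ValueError("invalid training configuration")


def windows_to_tensors(
    windows: list[ReadWindow],
    signal_features: tuple[str, ...] = CORE_SIGNAL_FEATURES,
    error_features: tuple[str, ...] = ERROR_FEATURES,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack feature vectors + one-hot sequence into (X_seq, X_err, y) tensors.

    y entries are -1 for unlabeled windows. Quality is rescaled to [0,1].
    """
    B = len(windows)
    if B == 0:
        raise ValueError("no windows")
    l = windows[0].l
    n_sig, n_err = len(signal_features), len(error_features)
    X_seq = np.zeros((B, l, n_sig + 5), dtype=DTYPE)
    X_err = np.zeros((B, l, n_err + 5), dtype=DTYPE)
    y = np.full(B, -1.0, dtype=DTYPE)
    for i, w in enumerate(windows):
        onehot = one_hot_encode(w.sequence)
        for j, name in enumerate(signal_features):
            X_seq[i, :, j] = w.features[name]
        X_seq[i, :, n_sig:] = onehot
        for j, name in enumerate(error_features):
            vec = w.features[name]
            if name == "quality":
                vec = np.clip(vec / QUALITY_SCALE, 0.0, 1.0)
            X_err[i, :, j] = vec
        X_err[i, :, n_err:] = onehot
        if w.label is not None:
            y[i] = w.label
    return X_seq, X_err, y


def _conv_stack(spec: ConvSpec, c_in: int, rng: np.random.Generator) -> list[Layer]:
    layers: list[Layer] = []
    c = c_in
    for _ in range(spec.n_layers):
        layers.append(Conv1D(c, spec.n_filters, spec.kernel_size, rng))
        if spec.batch_norm:
            layers.append(BatchNorm1D(spec.n_filters))
        layers.append(ReLU())
        c = spec.n_filters
    return layers


class ReadClassifier:
    """Forward/backward network over (sequence, error) window tensors."""

    def __init__(self, spec: ModelSpec, l: int = 17, n_channels: int = 9, seed: int = 0):
        if l % 2 == 0:
            raise ValueError("window length l must be odd")
        self.spec = spec
        self.l = l
        self.n_channels = n_channels
        self.seed = seed
        rng = np.random.default_rng(seed)

        head_in = 0
        self.seq_branch: Sequential | None = None
        self.err_branch: Sequential | None = None
        if spec.mode in ("joint", "sequence_only"):
            self.seq_branch = Sequential(
                _conv_stack(spec.sequence_conv, n_channels, rng) + [GlobalAvgPool1D()]
            )
            head_in += spec.sequence_conv.n_filters
        if spec.mode in ("joint", "error_only"):
            layers = _conv_stack(spec.error_conv, n_channels, rng)
            layers.append(MaxPool1D(spec.pool_size))
            l_cur = l // spec.pool_size
            c_cur = spec.error_conv.n_filters
            for _ in range(spec.error_local.n_layers):
                lc = LocallyConnected1D(
                    c_cur, spec.error_local.n_filters, spec.error_local.kernel_size, l_cur, rng
                )
                layers.append(lc)
                layers.append(ReLU())
                l_cur, c_cur = lc.l_out, lc.c_out
            layers.append(GlobalAvgPool1D())
            self.err_branch = Sequential(layers)
            head_in += spec.error_local.n_filters
        self.head = Sequential(
            [Dense(head_in, spec.head_units, rng), ReLU(), Dense(spec.head_units, 1, rng)]
        )

    # ------------------------------------------------------------- plumbing

    def all_layers(self) -> list[Layer]:
        layers: list[Layer] = []
        for branch in (self.seq_branch, self.err_branch):
            if branch is not None:
                layers.extend(branch.all_layers())
        layers.extend(self.head.all_layers())
        return layers

    def forward(
        self, X_seq: np.ndarray | None, X_err: np.ndarray | None, training: bool = False
    ) -> np.ndarray:
        feats = []
        if self.seq_branch is not None:
            if X_seq is None:
                raise ValueError("sequence tensor required in this mode")
            feats.append(self.seq_branch.forward(X_seq.astype(DTYPE), training))
        if self.err_branch is not None:
            if X_err is None:
                raise ValueError("error tensor required in this mode")
            feats.append(self.err_branch.forward(X_err.astype(DTYPE), training))
        h = np.concatenate(feats, axis=1) if len(feats) > 1 else feats[0]
        self._split = feats[0].shape[1] if len(feats) > 1 else None
        z = self.head.forward(h, training)
        return sigmoid(z[:, 0])

    def backward(self, dz: np.ndarray) -> None:
        """Backprop from d(loss)/d(logit); call after a training forward pass."""
        dh = self.head.backward(dz[:, None].astype(DTYPE))
        if self._split is not None:
            self.seq_branch.backward(dh[:, : self._split])
            self.err_branch.backward(dh[:, self._split :])
        elif self.seq_branch is not None:
            self.seq_branch.backward(dh)
        else:
            self.err_branch.backward(dh)

    def predict(self, X_seq, X_err, batch_size: int = 1024) -> np.ndarray:
        n = (X_seq if X_seq is not None else X_err).shape[0]
        out = np.empty(n, dtype=DTYPE)
        for i in range(0, n, batch_size):
            sl = slice(i, i + batch_size)
            out[sl] = self.forward(
                None if X_seq is None else X_seq[sl],
                None if X_err is None else X_err[sl],
                training=False,
            )
        return out

    def get_state(self) -> list[dict[str, np.ndarray]]:
        state = []
        for ly in self.all_layers():
            d = {k: v.copy() for k, v in ly.params.items()}
            if isinstance(ly, BatchNorm1D):
                d["running_mean"] = ly.running_mean.copy()
                d["running_var"] = ly.running_var.copy()
            state.append(d)
        return state

    def set_state(self, state: list[dict[str, np.ndarray]]) -> None:
        for ly, d in zip(self.all_layers(), state):
            for k in ly.params:
                ly.params[k][:] = d[k]
            if isinstance(ly, BatchNorm1D):
                ly.running_mean[:] = d["running_mean"]
                ly.running_var[:] = d["running_var"]

    # ---------------------------------------------------------- persistence

    def save(self, model_dir: str | Path, feature_schema: list[str]) -> None:
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        cfg = {
            "spec": asdict(self.spec),
            "l": self.l,
            "n_channels": self.n_channels,
            "seed": self.seed,
            "feature_schema": feature_schema,
        }
        (model_dir / "architecture.json").write_text(json.dumps(cfg, indent=2))
        arrays = {}
        for i, d in enumerate(self.get_state()):
            for k, v in d.items():
                arrays[f"layer{i}:{k}"] = v
        np.savez(model_dir / "weights.npz", **arrays)

    @classmethod
    def load(cls, model_dir: str | Path) -> tuple["ReadClassifier", list[str]]:
        model_dir = Path(model_dir)
        cfg = json.loads((model_dir / "architecture.json").read_text())
        spec_d = cfg["spec"]
        spec = ModelSpec(
            mode=spec_d["mode"],
            sequence_conv=ConvSpec(**spec_d["sequence_conv"]),
            error_conv=ConvSpec(**spec_d["error_conv"]),
            error_local=ConvSpec(**spec_d["error_local"]),
            head_units=spec_d["head_units"],
            pool_size=spec_d["pool_size"],
        )
        model = cls(spec, l=cfg["l"], n_channels=cfg["n_channels"], seed=cfg["seed"])
        with np.load(model_dir / "weights.npz") as npz:
            state: list[dict[str, np.ndarray]] = [{} for _ in model.all_layers()]
            for key in npz.files:
                tag, name = key.split(":", 1)
                state[int(tag[5:])][name] = npz[key]
        model.set_state(state)
        return model, cfg["feature_schema"]


def train_model(
    model: ReadClassifier,
    train: tuple[np.ndarray | None, np.ndarray | None, np.ndarray],
    validation: tuple[np.ndarray | None, np.ndarray | None, np.ndarray],
    cfg: TrainingConfig,
) -> dict[str, list[float]]:
    """Mini-batch Adam training with early stopping on validation loss.

    Stops when validation loss fails to improve for ``cfg.patience`` epochs
    (or at ``cfg.max_epochs``) and restores the best weights seen. Returns a
    history dict with per-epoch train/validation losses.
    """
    Xs, Xe, y = train
    if y.size == 0:
        raise ValueError("empty training set")
    vXs, vXe, vy = validation
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.all_layers(), lr=cfg.learning_rate)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_loss, best_state, since_best = np.inf, None, 0

    n = y.size
    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            yb = y[idx]
            yhat = model.forward(
                None if Xs is None else Xs[idx],
                None if Xe is None else Xe[idx],
                training=True,
            )
            epoch_loss += bce_loss(yb, yhat) * idx.size
            seen += idx.size
            if cfg.learning_rate > 0:
                dz = (yhat - yb) / idx.size  # d(BCE)/d(logit) through the sigmoid
                model.backward(dz)
                opt.step()
        history["train_loss"].append(epoch_loss / seen)
        val_scores = model.predict(vXs, vXe)
        vloss = bce_loss(vy, val_scores)
        history["val_loss"].append(vloss)
        if vloss < best_loss - 1e-6:
            best_loss, best_state, since_best = vloss, model.get_state(), 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if best_state is not None:
        model.set_state(best_state)
    return history


def call_reads(model: ReadClassifier, windows: list[ReadWindow]) -> pd.DataFrame:
    """Score windows and apply the 0.5 read-call threshold (ties methylated)."""
    Xs, Xe, y = windows_to_tensors(windows)
    scores = model.predict(
        Xs if model.seq_branch is not None else None,
        Xe if model.err_branch is not None else None,
    )
    scores = np.asarray(scores, dtype=float)
    df = pd.DataFrame(
        {
            "read_id": [w.read_id for w in windows],
            "chrom": [w.chrom for w in windows],
            "strand": [w.strand for w in windows],
            "position": [w.center_position for w in windows],
            "score": scores,
            "call": (scores >= 0.5).astype(int),
            "label": [-1 if w.label is None else w.label for w in windows],
        }
    )
    return df
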