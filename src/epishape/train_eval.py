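"""Training protocol and physical-unit evaluation.

Model selection uses 5-fold cross validation: each architecture is trained
five times from scratch, every sample serving once as validation, and
compared by the validation mean absolute error averaged over folds and over
the four encoded targets.  The selected architecture is then retrained once on
the full training set, keeping a small held-out fraction (10%) for early
stopping.  All reported errors are in physical units: pixels for the axes
(after inverting the axis scaler) and radians for the orientation (after the
doubled-angle decoding, folded modulo pi to [0, pi/2]).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .encoding import (
    AxisScaler,
    decode_orientation,
    encode_orientation,
    fold_angle_difference,
    normalize_image,
)
from .ground_truth import anisotropy
from .model_zoo import ArchSpec, build_cnn

__all__ = [
    "TrainConfig",
    "ShapeDataset",
    "ModelScore",
    "TrainedModel",
    "cross_validate",
    "final_retrain",
    "evaluate",
    "error_vs_anisotropy",
    "training_size_ablation",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: Adam(0.001), MSE, early stopping patience 20."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.patience >= self.max_epochs:
            object.__setattr__(self, "patience", self.max_epochs - 1)


class ShapeDataset:
    """Image tiles plus their (L, l, alpha) targets.

    ``images`` is (n, size, size) uint8; ``targets`` a DataFrame with at least
    columns L, l, alpha (alpha may be absent for axes-only datasets).
    """

    def __init__(self, images, targets: pd.DataFrame):
        if len(images) != len(targets):
            raise ValueError("images and targets disagree in length")
        self.images = np.asarray(images)
        self.targets = targets.reset_index(drop=True)

    def __len__(self):
        return len(self.images)

    @property
    def has_orientation(self):
        return "alpha" in self.targets.columns

    def subset(self, idx):
        return ShapeDataset(self.images[idx], self.targets.iloc[idx])

    def X(self):
        """Normalized NCHW float32 input tensor."""
        return normalize_image(self.images)[:, None, :, :]

    def encoded_y(self, scaler: AxisScaler):
        """Network targets: (zL, zl[, cos 2a, sin 2a]) as float32."""
        zL, zl = scaler.transform(self.targets["L"], self.targets["l"])
        cols = [zL, zl]
        if self.has_orientation:
            c, s = encode_orientation(self.targets["alpha"].to_numpy())
            cols += [c, s]
        return np.column_stack(cols).astype(np.float32)

    def anisotropy(self):
        return (self.targets["L"] / self.targets["l"] - 1.0).to_numpy()


@dataclass
class TrainedModel:
    """A fitted network bundled with its architecture and axis scaler."""

    net: nn.Network
    arch: ArchSpec
    scaler: AxisScaler
    history: nn.TrainHistory | None = None

    def predict_encoded(self, tiles_u8):
        X = normalize_image(np.asarray(tiles_u8))[:, None, :, :]
        return self.net.predict(X)

    def predict_shapes(self, tiles_u8):
        """Physical predictions: arrays (L px, l px, alpha rad or None)."""
        pred = self.predict_encoded(tiles_u8)
        L, l = self.scaler.inverse_transform(pred[:, 0], pred[:, 1])
        alpha = None
        if self.arch.n_outputs >= 4:
            alpha = decode_orientation(pred[:, 2], pred[:, 3])
        return L, l, alpha


@dataclass
class ModelScore:
    """Cross-validation scores of one architecture."""

    arch: ArchSpec
    fold_encoded_mae: list = field(default_factory=list)
    fold_mae_L: list = field(default_factory=list)
    fold_mae_l: list = field(default_factory=list)
    fold_mae_orient: list = field(default_factory=list)

    @property
    def mean_encoded_mae(self):
        """Selection criterion: MAE over the encoded targets, mean of folds."""
        return float(np.mean(self.fold_encoded_mae))

    @property
    def mean_mae_L(self):
        return float(np.mean(self.fold_mae_L))

    @property
    def mean_mae_l(self):
        return float(np.mean(self.fold_mae_l))

    @property
    def mean_mae_orient(self):
        return float(np.mean(self.fold_mae_orient)) if self.fold_mae_orient else np.nan


def _train_once(arch, train_ds, val_ds, config, seed):
    """Fit scaler on train only, train a fresh network, return both."""
    scaler = AxisScaler().fit(train_ds.targets["L"], train_ds.targets["l"])
    net = build_cnn(arch, seed=seed)
    hist = nn.fit(
        net,
        train_ds.X(),
        train_ds.encoded_y(scaler),
        val_ds.X() if val_ds is not None else None,
        val_ds.encoded_y(scaler) if val_ds is not None else None,
        epochs=config.max_epochs,
        batch_size=config.batch_size,
        lr=config.learning_rate,
        patience=config.patience,
        seed=seed,
    )
    return TrainedModel(net=net, arch=arch, scaler=scaler, history=hist)


def cross_validate(arch, dataset, config: TrainConfig, n_folds: int = 5):
    """5-fold CV: five models from scratch, scaler refit per fold."""
    from sklearn.model_selection import KFold

    if len(dataset) < n_folds * 2:
        raise ValueError(f"dataset of {len(dataset)} too small for {n_folds}-fold CV")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=config.seed)
    score = ModelScore(arch=arch)
    for fold, (tr, va) in enumerate(kf.split(np.arange(len(dataset)))):
        model = _train_once(
            arch,
            dataset.subset(tr),
            dataset.subset(va),
            config,
            seed=config.seed + 1000 * fold,
        )
        rep = evaluate(model, dataset.subset(va))
        score.fold_encoded_mae.append(rep["encoded_mae"])
        score.fold_mae_L.append(rep["mae_L"])
        score.fold_mae_l.append(rep["mae_l"])
        if "mae_orient" in rep:
            score.fold_mae_orient.append(rep["mae_orient"])
    return score


def final_retrain(arch, dataset, config: TrainConfig, val_fraction: float = 0.1):
    """One model on (1 - val_fraction) of the data, early-stopped on the rest."""
    rng = np.random.default_rng(config.seed)
    idx = rng.permutation(len(dataset))
    n_val = max(1, int(round(val_fraction * len(dataset))))
    val, tr = idx[:n_val], idx[n_val:]
    return _train_once(arch, dataset.subset(tr), dataset.subset(val), config,
                       seed=config.seed)


def evaluate(model: TrainedModel, dataset: ShapeDataset):
    """Per-target MAE report in physical units after all inverse transforms."""
    pred = model.predict_encoded(dataset.images)
    y = dataset.encoded_y(model.scaler)
    rep = {"encoded_mae": float(np.mean(np.abs(pred - y))), "n": len(dataset)}
    L_pred, l_pred = model.scaler.inverse_transform(pred[:, 0], pred[:, 1])
    L_true = dataset.targets["L"].to_numpy()
    l_true = dataset.targets["l"].to_numpy()
    rep["mae_L"] = float(np.mean(np.abs(L_pred - L_true)))
    rep["mae_l"] = float(np.mean(np.abs(l_pred - l_true)))
    if model.arch.n_outputs >= 4 and dataset.has_orientation:
        alpha_pred = decode_orientation(pred[:, 2], pred[:, 3])
        alpha_true = dataset.targets["alpha"].to_numpy()
        err = np.abs(fold_angle_difference(alpha_pred, alpha_true))
        rep["mae_orient"] = float(np.mean(err))
        rep["orient_errors"] = err
        rep["cos2_plus_sin2"] = pred[:, 2] ** 2 + pred[:, 3] ** 2
    return rep


def error_vs_anisotropy(model, dataset, bins=8):
    """Orientation MAE binned by ground-truth anisotropy (L/l - 1).

    ``bins`` may be an integer (equal-width bins over the observed range) or
    explicit edges.  Empty bins are reported with count 0 and NaN error.
    """
    rep = evaluate(model, dataset)
    if "orient_errors" not in rep:
        raise ValueError("model/dataset carry no orientation information")
    aniso = dataset.anisotropy()
    edges = (
        np.histogram_bin_edges(aniso, bins=bins)
        if np.isscalar(bins)
        else np.asarray(bins, dtype=float)
    )
    which = np.clip(np.digitize(aniso, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        rows.append(
            dict(
                bin_center=0.5 * (edges[b] + edges[b + 1]),
                mean_abs_error=float(np.mean(rep["orient_errors"][sel]))
                if sel.any()
                else np.nan,
                count=int(sel.sum()),
            )
        )
    return pd.DataFrame(rows)


def training_size_ablation(arch, train_ds, test_ds, sizes, config: TrainConfig):
    """MAE on a fixed test set as a function of training-set size.

    For each size a seeded random subset of the training set is drawn and a
    fresh model is retrained with the standard protocol.
    """
    rows = []
    for n in sizes:
        if n > len(train_ds):
            raise ValueError(f"requested {n} > available {len(train_ds)}")
        rng = np.random.default_rng((config.seed, int(n)))
        sub = train_ds.subset(rng.choice(len(train_ds), size=int(n), replace=False))
        model = final_retrain(arch, sub, config)
        rep = evaluate(model, test_ds)
        rows.append(
            dict(n_train=int(n), mae_L=rep["mae_L"], mae_l=rep["mae_l"],
                 mae_orient=rep.get("mae_orient", np.nan),
                 encoded_mae=rep["encoded_mae"])
        )
    return pd.DataFrame(rows)
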