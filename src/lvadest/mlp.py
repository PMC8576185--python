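"""Multilayer-perceptron inverse estimator.

Fully connected network mapping the Fourier feature vector to the four
heart-failure parameters: ReLU hidden layers, sigmoid output (hence labels
are min-max scaled into (0,1)), mean-squared-error loss minimized by Adam
(learning rate 0.001, batch size 32 by default), with early stopping on the
validation loss and best-epoch checkpointing.  Inputs are standardized with
training-set statistics stored inside the model artifact.

The implementation is deliberately compact and dependency-free (numpy
forward/backward passes); networks at this scale (199 -> ~2x64 -> 4) train
in seconds on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MLPSpec",
    "TrainConfig",
    "LabelScaler",
    "MLPModel",
    "split_dataset",
    "fit_label_scaler",
    "train_mlp",
    "select_architecture",
    "predict",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class MLPSpec:
    """Layer layout: input size, hidden sizes, output size (= 4 labels)."""

    input_size: int = 199
    hidden: tuple = (64, 64)
    output_size: int = 4

    def __post_init__(self) -> None:
        if self.output_size < 1 or self.input_size < 1:
            raise ValueError("layer sizes must be positive")
        if len(self.hidden) < 1:
            raise ValueError("at least one hidden layer required")

    @property
    def layer_sizes(self) -> tuple:
        return (self.input_size, *self.hidden, self.output_size)

    @property
    def n_parameters(self) -> int:
        s = self.layer_sizes
        return sum(s[i] * s[i + 1] + s[i + 1] for i in range(len(s) - 1))


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (loss is MSE, optimizer is Adam)."""

    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    test_fraction: float = 0.05
    validation_fraction: float = 0.20   # of the non-test remainder
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.test_fraction < 1 and 0 < self.validation_fraction < 1):
            raise ValueError("fractions must lie in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


class LabelScaler:
    """Affine map of each label coordinate onto [0, 1] and back.

    Fitted either from data (empirical min/max) or from the configured
    sampling ranges; the sigmoid output layer requires targets in (0, 1).
    Out-of-range values map outside [0, 1] without error; clipping happens
    only at prediction decode.
    """

    def __init__(self, mins, maxs):
        self.mins = np.asarray(mins, dtype=float)
        self.maxs = np.asarray(maxs, dtype=float)
        if np.any(self.mins >= self.maxs):
            raise ValueError("degenerate label range")

    def scale(self, y):
        return (np.asarray(y, dtype=float) - self.mins) / (self.maxs - self.mins)

    def unscale(self, z):
        return self.mins + np.asarray(z, dtype=float) * (self.maxs - self.mins)


def fit_label_scaler(labels) -> LabelScaler:
    labels = np.asarray(labels, dtype=float)
    return LabelScaler(labels.min(axis=0), labels.max(axis=0))


def split_dataset(n_records: int, cfg: TrainConfig,
                  speeds=None):
    """Disjoint, exhaustive train/validation/test index sets.

    The test fraction is held out first, then the remainder is split into
    train/validation.  Counts are floored per stratum with the remainder
    going to train; when ``speeds`` is given the split is stratified by
    pump speed.  Reproducible from ``cfg.seed``.
    """
    if n_records < 20:
        raise ValueError("dataset too small to split")
    rng = np.random.default_rng(cfg.seed)
    if speeds is None:
        strata = [np.arange(n_records)]
    else:
        speeds = np.asarray(speeds)
        strata = [np.flatnonzero(speeds == v) for v in np.unique(speeds)]
    train, val, test = [], [], []
    for idx in strata:
        idx = idx.copy()
        rng.shuffle(idx)
        n_test = int(len(idx) * cfg.test_fraction)
        rest = idx[n_test:]
        n_val = int(len(rest) * cfg.validation_fraction)
        test.append(idx[:n_test])
        val.append(rest[:n_val])
        train.append(rest[n_val:])
    return (np.sort(np.concatenate(train)), np.sort(np.concatenate(val)),
            np.sort(np.concatenate(test)))


# ---------------------------------------------------------------------------
# network internals
# ---------------------------------------------------------------------------

def _init_weights(spec: MLPSpec, rng: np.random.Generator):
    Ws, bs = [], []
    sizes = spec.layer_sizes
    for i in range(len(sizes) - 1):
        fan_in, fan_out = sizes[i], sizes[i + 1]
        if i < len(sizes) - 2:  # He initialization for ReLU layers
            W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out))
        else:  # Glorot for the sigmoid output
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            W = rng.uniform(-lim, lim, (fan_in, fan_out))
        Ws.append(W)
        bs.append(np.zeros(fan_out))
    return Ws, bs


def _forward(Ws, bs, X):
    acts = [X]
    a = X
    n_layers = len(Ws)
    for i, (W, b) in enumerate(zip(Ws, bs)):
        z = a @ W + b
        if i < n_layers - 1:
            a = np.maximum(z, 0.0)
        else:
            a = 1.0 / (1.0 + np.exp(-z))
        acts.append(a)
    return acts


def _backward(Ws, acts, Yb):
    """Gradients of the batch MSE w.r.t. weights and biases."""
    B = Yb.shape[0]
    out = acts[-1]
    delta = (2.0 / (B * Yb.shape[1])) * (out - Yb) * out * (1.0 - out)
    gWs = [None] * len(Ws)
    gbs = [None] * len(Ws)
    for i in range(len(Ws) - 1, -1, -1):
        gWs[i] = acts[i].T @ delta
        gbs[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ Ws[i].T) * (acts[i] > 0)
    return gWs, gbs


@dataclass
class MLPModel:
    """Trained estimator: weights plus the input/label transforms."""

    spec: MLPSpec
    Ws: list
    bs: list
    feat_mean: np.ndarray
    feat_std: np.ndarray
    scaler: LabelScaler
    label_names: tuple = ("Emax_lv", "Emax_lv0", "G_Emaxlv", "kE_lv")
    history: pd.DataFrame | None = None
    best_epoch: int | None = None

    def forward_scaled(self, X) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.feat_mean) / self.feat_std
        return _forward(self.Ws, self.bs, np.atleast_2d(Xs))[-1]


def predict(model: MLPModel, x) -> np.ndarray:
    """Decode network output back to physical label units; values are
    clipped to the scaler range (the sigmoid cannot leave it anyway)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if x.shape[-1] != model.spec.input_size:
        raise ValueError(
            f"feature length {x.shape[-1]} != input size {model.spec.input_size}")
    z = model.forward_scaled(x)
    y = model.scaler.unscale(z)
    y = np.clip(y, model.scaler.mins, model.scaler.maxs)
    return y[0] if single else y


def train_mlp(X_train, Y_train, X_val, Y_val, spec: MLPSpec | None = None,
              cfg: TrainConfig | None = None,
              scaler: LabelScaler | None = None) -> MLPModel:
    """Train on raw features/labels; returns the best-validation checkpoint.

    The per-epoch history records train/validation loss (scaled-label MSE)
    and mean absolute error.
    """
    cfg = cfg or TrainConfig()
    X_train = np.asarray(X_train, dtype=float)
    Y_train = np.asarray(Y_train, dtype=float)
    spec = spec or MLPSpec(input_size=X_train.shape[1],
                           output_size=Y_train.shape[1])
    if Y_train.shape[1] != spec.output_size:
        raise ValueError("label dimension does not match spec")
    if X_train.shape[1] != spec.input_size:
        raise ValueError("feature dimension does not match spec")

    feat_mean = X_train.mean(axis=0)
    feat_std = X_train.std(axis=0)
    feat_std[feat_std < 1e-12] = 1.0
    scaler = scaler or fit_label_scaler(Y_train)

    Xt = (X_train - feat_mean) / feat_std
    Yt = scaler.scale(Y_train)
    Xv = (np.asarray(X_val, dtype=float) - feat_mean) / feat_std
    Yv = scaler.scale(np.asarray(Y_val, dtype=float))

    rng = np.random.default_rng(cfg.seed)
    Ws, bs = _init_weights(spec, rng)
    mWs = [np.zeros_like(W) for W in Ws]
    vWs = [np.zeros_like(W) for W in Ws]
    mbs = [np.zeros_like(b) for b in bs]
    vbs = [np.zeros_like(b) for b in bs]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t_step = 0

    n = Xt.shape[0]
    best_loss = np.inf
    best = None
    best_epoch = -1
    rows = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            acts = _forward(Ws, bs, Xt[sel])
            gWs, gbs = _backward(Ws, acts, Yt[sel])
            t_step += 1
            corr1 = 1.0 - beta1 ** t_step
            corr2 = 1.0 - beta2 ** t_step
            for i in range(len(Ws)):
                mWs[i] = beta1 * mWs[i] + (1 - beta1) * gWs[i]
                vWs[i] = beta2 * vWs[i] + (1 - beta2) * gWs[i] ** 2
                Ws[i] -= cfg.learning_rate * (mWs[i] / corr1) / (
                    np.sqrt(vWs[i] / corr2) + eps)
                mbs[i] = beta1 * mbs[i] + (1 - beta1) * gbs[i]
                vbs[i] = beta2 * vbs[i] + (1 - beta2) * gbs[i] ** 2
                bs[i] -= cfg.learning_rate * (mbs[i] / corr1) / (
                    np.sqrt(vbs[i] / corr2) + eps)
        out_tr = _forward(Ws, bs, Xt)[-1]
        out_va = _forward(Ws, bs, Xv)[-1]
        tr_loss = float(np.mean((out_tr - Yt) ** 2))
        va_loss = float(np.mean((out_va - Yv) ** 2))
        if not np.isfinite(tr_loss):
            raise RuntimeError("training diverged (non-finite loss)")
        rows.append({
            "epoch": epoch,
            "train_loss": tr_loss, "val_loss": va_loss,
            "train_mae": float(np.mean(np.abs(out_tr - Yt))),
            "val_mae": float(np.mean(np.abs(out_va - Yv))),
        })
        if va_loss < best_loss:
            best_loss = va_loss
            best = ([W.copy() for W in Ws], [b.copy() for b in bs])
            best_epoch = epoch
        elif epoch - best_epoch >= cfg.patience:
            break

    Ws, bs = best
    return MLPModel(spec=spec, Ws=Ws, bs=bs, feat_mean=feat_mean,
                    feat_std=feat_std, scaler=scaler,
                    history=pd.DataFrame(rows), best_epoch=best_epoch)


def select_architecture(candidates, X_train, Y_train, X_val, Y_val,
                        cfg: TrainConfig | None = None,
                        scaler: LabelScaler | None = None,
                        tolerance: float = 0.05):
    """Train every candidate hidden layout identically; report validation
    loss and MAE; return the smallest model within ``tolerance`` of the best
    validation loss, together with the comparison table."""
    if not candidates:
        raise ValueError("need at least one candidate")
    cfg = cfg or TrainConfig()
    results = []
    models = []
    for hidden in candidates:
        spec = MLPSpec(input_size=np.asarray(X_train).shape[1],
                       hidden=tuple(hidden),
                       output_size=np.asarray(Y_train).shape[1])
        model = train_mlp(X_train, Y_train, X_val, Y_val, spec, cfg,
                          scaler=scaler)
        h = model.history
        best = h.loc[h.val_loss.idxmin()]
        results.append({
            "hidden": "x".join(str(s) for s in hidden),
            "n_parameters": spec.n_parameters,
            "val_loss": best.val_loss,
            "val_mae": best.val_mae,
        })
        models.append(model)
    table = pd.DataFrame(results)
    best_loss = table.val_loss.min()
    ok = table.val_loss <= best_loss * (1.0 + tolerance)
    chosen = table[ok].n_parameters.idxmin()
    return models[chosen], table


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: MLPModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {"feat_mean": model.feat_mean, "feat_std": model.feat_std,
              "scaler_mins": model.scaler.mins, "scaler_maxs": model.scaler.maxs}
    for i, (W, b) in enumerate(zip(model.Ws, model.bs)):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    np.savez(out / "weights.npz", **arrays)
    meta = {"spec": asdict(model.spec), "label_names": list(model.label_names),
            "best_epoch": model.best_epoch, "n_layers": len(model.Ws)}
    (out / "model.json").write_text(json.dumps(meta, indent=2))
    if model.history is not None:
        model.history.to_csv(out / "history.csv", index=False)


def load_model(out_dir: str | Path) -> MLPModel:
    out = Path(out_dir)
    meta = json.loads((out / "model.json").read_text())
    data = np.load(out / "weights.npz")
    spec = MLPSpec(input_size=meta["spec"]["input_size"],
                   hidden=tuple(meta["spec"]["hidden"]),
                   output_size=meta["spec"]["output_size"])
    Ws = [data[f"W{i}"] for i in range(meta["n_layers"])]
    bs = [data[f"b{i}"] for i in range(meta["n_layers"])]
    history_path = out / "history.csv"
    history = pd.read_csv(history_path) if history_path.exists() else None
    return MLPModel(spec=spec, Ws=Ws, bs=bs,
                    feat_mean=data["feat_mean"], feat_std=data["feat_std"],
                    scaler=LabelScaler(data["scaler_mins"], data["scaler_maxs"]),
                    label_names=tuple(meta["label_names"]),
                    history=history, best_epoch=meta["best_epoch"])
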