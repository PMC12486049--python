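"""Multi-detector fusion estimator of fetal arterial oxygen saturation.

A multilayer perceptron maps the ten per-detector, per-wavelength EPRs (or
the five per-detector RoRs of the conventional baseline) to fSpO2 in
percent.  Architecture: a first hidden layer of ``n`` units, halving at
each stage down to 8, each hidden stage ``linear -> ReLU -> batch
normalization`` (order switchable), and a single linear output unit.
Training minimises (optionally sample-weighted) mean squared error with
Adam (learning rate 1e-3, weight decay 1e-4), batch size 32, at most 300
epochs, early stopping with patience 25 and best-validation-weight restore.
Weights are initialised from a normal distribution (He scaling), biases at
zero.

The implementation is a compact, fully deterministic NumPy MLP: given the
seed, the parameter trajectory is reproducible bit-for-bit.

Two validation schemes mirror the two study arms: a per-geometry random
80/20 split (simulation arm) and contiguous temporal folds with
inverse-round-size sample weights (in-vivo arm).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .optics_model import ConfigError

__all__ = [
    "Dataset",
    "TrainConfig",
    "FitResult",
    "MLPRegressor",
    "build_model",
    "random_split",
    "temporal_split",
    "round_weights",
    "train",
    "evaluate",
    "run_comparison",
]


@dataclass
class Dataset:
    """Feature matrix, labels in percent, and a grouping key per sample.

    Groups are fetal depths for the simulation arm or round ids for the
    longitudinal arm; splits and weights operate on them.
    """

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ConfigError("X must be 2-d with one label per row")
        if self.groups.shape[0] != self.y.shape[0]:
            raise ConfigError("one group key per sample required")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise ConfigError("dataset contains missing values")
        if np.any(self.y < 0) or np.any(self.y > 100):
            raise ConfigError("labels must be percentages in [0, 100]")

    @property
    def n_samples(self) -> int:
        return int(self.y.size)


@dataclass
class TrainConfig:
    """Hyperparameters; defaults follow the training protocol described above."""

    hidden: int = 64  # first hidden width; halves down to 8
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 300
    patience: int = 25
    bn_after_activation: bool = True  # linear -> ReLU -> BN (switchable)
    bn_momentum: float = 0.1
    init_scale: float | None = None  # None = He scaling sqrt(2/fan_in)
    standardize: bool = True  # z-score features and target internally
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.hidden
        if n < 8 or (n & (n - 1)) != 0 or n % 8 != 0:
            raise ConfigError(
                f"first hidden width must be a power-of-two multiple of 8, got {n}"
            )

    @property
    def hidden_widths(self) -> tuple[int, ...]:
        widths = []
        n = self.hidden
        while n >= 8:
            widths.append(n)
            n //= 2
        return tuple(widths)


@dataclass
class FitResult:
    """Trained model with validation predictions, metrics and history."""

    model: "MLPRegressor"
    val_indices: np.ndarray
    val_predictions: np.ndarray
    mae: float
    error_std: float
    pearson_r: float
    pearson_p: float
    history: dict
    best_epoch: int


class MLPRegressor:
    """Feed-forward regressor with per-stage batch normalization."""

    BN_EPS = 1e-5

    def __init__(self, input_width: int, cfg: TrainConfig):
        if input_width < 1:
            raise ConfigError("input width must be >= 1")
        self.cfg = cfg
        self.input_width = int(input_width)
        self.widths = (self.input_width, *cfg.hidden_widths, 1)
        self._rng = np.random.default_rng(cfg.seed)
        self.params: list[dict] = []
        for d_in, d_out in zip(self.widths[:-1], self.widths[1:]):
            scale = cfg.init_scale if cfg.init_scale is not None else math.sqrt(2.0 / d_in)
            layer = {
                "W": self._rng.normal(0.0, scale, (d_in, d_out)),
                "b": np.zeros(d_out),
            }
            self.params.append(layer)
        # batch-norm state for every hidden stage (not the output layer)
        self.bn: list[dict] = [
            {
                "gamma": np.ones(d),
                "beta": np.zeros(d),
                "mean": np.zeros(d),
                "var": np.ones(d),
            }
            for d in cfg.hidden_widths
        ]
        self._adam: list[dict] = []
        self._t = 0
        self.x_mean = np.zeros(self.input_width)
        self.x_std = np.ones(self.input_width)
        self.y_mean = 0.0
        self.y_std = 1.0

    # -- introspection -----------------------------------------------------
    @property
    def parameter_count(self) -> int:
        """Learnable parameters: weights, biases, and BN gamma/beta."""
        n = sum(p["W"].size + p["b"].size for p in self.params)
        n += sum(s["gamma"].size + s["beta"].size for s in self.bn)
        return int(n)

    # -- forward / backward ------------------------------------------------
    def _forward(self, X: np.ndarray, training: bool):
        cache = []
        h = X
        n_hidden = len(self.bn)
        for i, layer in enumerate(self.params):
            z = h @ layer["W"] + layer["b"]
            if i == n_hidden:  # output layer: linear
                cache.append({"h_in": h, "z": z})
                h = z
                break
            bn = self.bn[i]
            if self.cfg.bn_after_activation:
                a = np.maximum(z, 0.0)
                out, bn_cache = self._bn_forward(a, bn, training)
            else:
                out_bn, bn_cache = self._bn_forward(z, bn, training)
                out = np.maximum(out_bn, 0.0)
                bn_cache["post_relu_mask"] = out_bn > 0
            cache.append({"h_in": h, "z": z, "bn": bn_cache})
            h = out
        return h[:, 0], cache

    def _bn_forward(self, a: np.ndarray, bn: dict, training: bool):
        if training:
            mean = a.mean(axis=0)
            var = a.var(axis=0)
            m = self.cfg.bn_momentum
            bn["mean"] = (1 - m) * bn["mean"] + m * mean
            bn["var"] = (1 - m) * bn["var"] + m * var
        else:
            mean, var = bn["mean"], bn["var"]
        ivar = 1.0 / np.sqrt(var + self.BN_EPS)
        xhat = (a - mean) * ivar
        out = bn["gamma"] * xhat + bn["beta"]
        return out, {"a": a, "mean": mean, "ivar": ivar, "xhat": xhat}

    @staticmethod
    def _bn_backward(dout: np.ndarray, bn: dict, bc: dict):
        m = dout.shape[0]
        xhat, ivar = bc["xhat"], bc["ivar"]
        dgamma = (dout * xhat).sum(axis=0)
        dbeta = dout.sum(axis=0)
        dxhat = dout * bn["gamma"]
        da = (
            ivar / m * (m * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        )
        return da, dgamma, dbeta

    def _backward(self, X, y, w, cache, y_pred):
        grads = [dict() for _ in self.params]
        bn_grads = [dict() for _ in self.bn]
        n_hidden = len(self.bn)
        wsum = w.sum()
        dy = (2.0 * w * (y_pred - y) / wsum)[:, None]

        # output layer
        c = cache[n_hidden]
        grads[n_hidden]["W"] = c["h_in"].T @ dy
        grads[n_hidden]["b"] = dy.sum(axis=0)
        dh = dy @ self.params[n_hidden]["W"].T

        for i in range(n_hidden - 1, -1, -1):
            c = cache[i]
            bc = c["bn"]
            if self.cfg.bn_after_activation:
                da, dgamma, dbeta = self._bn_backward(dh, self.bn[i], bc)
                dz = da * (c["z"] > 0)
            else:
                d_bn_out = dh * bc["post_relu_mask"]
                dz, dgamma, dbeta = self._bn_backward(d_bn_out, self.bn[i], bc)
            bn_grads[i]["gamma"] = dgamma
            bn_grads[i]["beta"] = dbeta
            grads[i]["W"] = c["h_in"].T @ dz
            grads[i]["b"] = dz.sum(axis=0)
            dh = dz @ self.params[i]["W"].T
        return grads, bn_grads

    # -- optimisation ------------------------------------------------------
    def _adam_init(self):
        self._adam = []
        for layer in self.params:
            self._adam.append(
                {k: {"m": np.zeros_like(v), "v": np.zeros_like(v)} for k, v in layer.items()}
            )
        for bn in self.bn:
            self._adam.append(
                {
                    k: {"m": np.zeros_like(bn[k]), "v": np.zeros_like(bn[k])}
                    for k in ("gamma", "beta")
                }
            )
        self._t = 0

    def _adam_step(self, grads, bn_grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._t += 1
        t = self._t
        wd = self.cfg.weight_decay

        def update(param, grad, state):
            state["m"] = beta1 * state["m"] + (1 - beta1) * grad
            state["v"] = beta2 * state["v"] + (1 - beta2) * grad**2
            mhat = state["m"] / (1 - beta1**t)
            vhat = state["v"] / (1 - beta2**t)
            param -= lr * mhat / (np.sqrt(vhat) + eps)

        for i, layer in enumerate(self.params):
            g_w = grads[i]["W"] + wd * layer["W"]  # L2 decay on weights only
            update(layer["W"], g_w, self._adam[i]["W"])
            update(layer["b"], grads[i]["b"], self._adam[i]["b"])
        off = len(self.params)
        for i, bn in enumerate(self.bn):
            update(bn["gamma"], bn_grads[i]["gamma"], self._adam[off + i]["gamma"])
            update(bn["beta"], bn_grads[i]["beta"], self._adam[off + i]["beta"])

    # -- public API --------------------------------------------------------
    def fit(
        self,
        X_train: np.ndarray,
        y_train: np.ndarray,
        X_val: np.ndarray,
        y_val: np.ndarray,
        sample_weight: np.ndarray | None = None,
    ) -> dict:
        X_train = np.asarray(X_train, dtype=float)
        y_train = np.asarray(y_train, dtype=float)
        X_val = np.asarray(X_val, dtype=float)
        y_val = np.asarray(y_val, dtype=float)
        n = y_train.size
        w = (
            np.ones(n)
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float)
        )
        if w.shape != (n,) or np.any(w < 0):
            raise ConfigError("sample weights must be non-negative, one per sample")

        if self.cfg.standardize:
            self.x_mean = X_train.mean(axis=0)
            std = X_train.std(axis=0)
            self.x_std = np.where(std > 0, std, 1.0)
            self.y_mean = float(y_train.mean())
            y_sd = float(y_train.std())
            self.y_std = y_sd if y_sd > 0 else 1.0
        Xt = (X_train - self.x_mean) / self.x_std
        Xv = (X_val - self.x_mean) / self.x_std
        yt = (y_train - self.y_mean) / self.y_std
        yv = (y_val - self.y_mean) / self.y_std

        self._adam_init()
        best = {"loss": np.inf, "epoch": -1, "params": None, "bn": None}
        history = {"train_loss": [], "val_loss": []}
        stale = 0
        cfg = self.cfg

        for epoch in range(cfg.max_epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start: start + cfg.batch_size]
                xb, yb, wb = Xt[idx], yt[idx], w[idx]
                y_pred, cache = self._forward(xb, training=True)
                if not np.all(np.isfinite(y_pred)):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch}; history: {history}"
                    )
                loss = float((wb * (y_pred - yb) ** 2).sum() / wb.sum())
                epoch_loss += loss * idx.size
                grads, bn_grads = self._backward(xb, yb, wb, cache, y_pred)
                self._adam_step(grads, bn_grads, cfg.learning_rate)
            history["train_loss"].append(epoch_loss / n)

            val_pred, _ = self._forward(Xv, training=False)
            val_loss = float(np.mean((val_pred - yv) ** 2))
            history["val_loss"].append(val_loss)

            if val_loss < best["loss"] - 1e-12:
                best = {
                    "loss": val_loss,
                    "epoch": epoch,
                    "params": copy.deepcopy(self.params),
                    "bn": copy.deepcopy(self.bn),
                }
                stale = 0
            else:
                stale += 1
                if stale > cfg.patience:
                    break

        if best["params"] is not None:  # restore best validation weights
            self.params = best["params"]
            self.bn = best["bn"]
        history["best_epoch"] = best["epoch"]
        return history

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = (np.asarray(X, dtype=float) - self.x_mean) / self.x_std
        y, _ = self._forward(X, training=False)
        return y * self.y_std + self.y_mean

    # -- serialization -----------------------------------------------------
    def state_dict(self) -> dict:
        return {
            "widths": self.widths,
            "params": copy.deepcopy(self.params),
            "bn": copy.deepcopy(self.bn),
            "x_mean": self.x_mean.copy(),
            "x_std": self.x_std.copy(),
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "cfg": copy.deepcopy(self.cfg),
        }

    @classmethod
    def from_state_dict(cls, state: dict) -> "MLPRegressor":
        model = cls(state["widths"][0], state["cfg"])
        model.params = copy.deepcopy(state["params"])
        model.bn = copy.deepcopy(state["bn"])
        model.x_mean = state["x_mean"].copy()
        model.x_std = state["x_std"].copy()
        model.y_mean = state.get("y_mean", 0.0)
        model.y_std = state.get("y_std", 1.0)
        return model


def build_model(cfg: TrainConfig, input_width: int) -> MLPRegressor:
    """Untrained MLP with widths ``[input, n, n/2, ..., 8, 1]``."""
    return MLPRegressor(input_width, cfg)


# ---------------------------------------------------------------------------
# Splits and weights
# ---------------------------------------------------------------------------

def random_split(
    groups: np.ndarray, frac: float = 0.8, seed: int = 0, min_group: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Per-group random train/validation split (disjoint, exhaustive).

    The split is performed independently within each group (each fetal
    depth), allocating ``frac`` for training.
    """
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for gval in np.unique(groups):
        idx = np.flatnonzero(groups == gval)
        if idx.size < min_group:
            raise ConfigError(
                f"group {gval!r} has {idx.size} samples (< {min_group})"
            )
        perm = rng.permutation(idx)
        cut = int(round(frac * idx.size))
        train_idx.append(perm[:cut])
        val_idx.append(perm[cut:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def temporal_split(
    n_samples: int, k: int = 5, fold: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Contiguous k-fold split of time-ordered samples.

    Validation is the ``fold``-th contiguous block; blocks are disjoint,
    cover all samples and differ in size by at most one.
    """
    if n_samples < k:
        raise ConfigError(f"need at least {k} samples for {k} folds")
    if not 0 <= fold < k:
        raise ConfigError(f"fold must be in [0, {k})")
    blocks = np.array_split(np.arange(n_samples), k)
    val = blocks[fold]
    train = np.concatenate([b for i, b in enumerate(blocks) if i != fold])
    return train, val


def round_weights(round_ids: np.ndarray) -> np.ndarray:
    """Per-sample weights inversely proportional to round size.

    Normalised so the total weight equals the number of samples; every round
    then carries equal total weight.
    """
    round_ids = np.asarray(round_ids)
    uniq, inverse, counts = np.unique(round_ids, return_inverse=True, return_counts=True)
    if np.any(counts == 0):
        raise ConfigError("empty round")
    scale = round_ids.size / uniq.size
    return scale / counts[inverse]


# ---------------------------------------------------------------------------
# Training and metrics
# ---------------------------------------------------------------------------

def evaluate(predictions: np.ndarray, labels: np.ndarray):
    """(MAE %, std of |errors| %, Pearson r, two-sided p).

    Pearson r is reported as NaN when either side has zero variance.
    """
    pred = np.asarray(predictions, dtype=float)
    lab = np.asarray(labels, dtype=float)
    if pred.shape != lab.shape or pred.size < 2:
        raise ConfigError("need equal-length prediction/label vectors, size >= 2")
    err = np.abs(pred - lab)
    mae = float(err.mean())
    std = float(err.std(ddof=0))
    if np.std(pred) == 0.0 or np.std(lab) == 0.0:
        return mae, std, float("nan"), float("nan")
    r, p = scipy.stats.pearsonr(pred, lab)
    return mae, std, float(r), float(p)


def train(
    dataset: Dataset,
    split: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
    sample_weight: np.ndarray | None = None,
) -> FitResult:
    """Fit the MLP on the given split and score it on the validation part."""
    train_idx, val_idx = split
    model = build_model(cfg, dataset.X.shape[1])
    sw = None if sample_weight is None else np.asarray(sample_weight)[train_idx]
    history = model.fit(
        dataset.X[train_idx], dataset.y[train_idx],
        dataset.X[val_idx], dataset.y[val_idx],
        sample_weight=sw,
    )
    val_pred = model.predict(dataset.X[val_idx])
    mae, std, r, p = evaluate(val_pred, dataset.y[val_idx])
    return FitResult(
        model=model,
        val_indices=np.asarray(val_idx),
        val_predictions=val_pred,
        mae=mae, error_std=std, pearson_r=r, pearson_p=p,
        history=history, best_epoch=history["best_epoch"],
    )


def run_comparison(
    dataset_epr: Dataset,
    dataset_ror: Dataset,
    cfg: TrainConfig,
    trials: int = 5,
    split: tuple[np.ndarray, np.ndarray] | None = None,
    sample_weight: np.ndarray | None = None,
) -> dict:
    """EPR-vs-RoR comparison: average metrics over differently seeded trainings.

    Both datasets must describe the same samples (same labels/groups); the
    same split is reused across trials while the network initialisation seed
    varies.  Improvements are percent reductions of the RoR metric, e.g.
    ``(MAE_RoR - MAE_EPR) / MAE_RoR x 100``.
    """
    if dataset_epr.n_samples != dataset_ror.n_samples or not np.allclose(
        dataset_epr.y, dataset_ror.y
    ):
        raise ConfigError("EPR/RoR datasets must describe identical samples")
    if split is None:
        split = random_split(dataset_epr.groups, seed=cfg.seed)

    metrics = {"EPR": [], "RoR": []}
    fits = {"EPR": [], "RoR": []}
    for trial in range(trials):
        trial_cfg = copy.deepcopy(cfg)
        trial_cfg.seed = cfg.seed + 1000 * (trial + 1)
        for key, ds in (("EPR", dataset_epr), ("RoR", dataset_ror)):
            fit = train(ds, split, trial_cfg, sample_weight=sample_weight)
            metrics[key].append((fit.mae, fit.error_std, fit.pearson_r))
            fits[key].append(fit)

    out = {}
    for key in ("EPR", "RoR"):
        arr = np.asarray(metrics[key])
        out[key] = {
            "mae": float(arr[:, 0].mean()),
            "error_std": float(arr[:, 1].mean()),
            "pearson_r": float(arr[:, 2].mean()),
            "per_trial": arr,
        }
    out["improvement"] = {
        "mae_pct": 100.0 * (out["RoR"]["mae"] - out["EPR"]["mae"]) / out["RoR"]["mae"],
        "error_std_pct": 100.0
        * (out["RoR"]["error_std"] - out["EPR"]["error_std"]) / out["RoR"]["error_std"],
        "pearson_r_pct": 100.0
        * (out["EPR"]["pearson_r"] - out["RoR"]["pearson_r"])
        / abs(out["RoR"]["pearson_r"]),
    }
    out["fits"] = fits
    out["split"] = split
    return out
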