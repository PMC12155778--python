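"""Descriptor-based regression for retention-time and response-factor prediction.

The same machinery serves both uses: a seeded random search over a declared
space of penalized-linear (ridge / lasso / elastic-net) and feed-forward
neural-network configurations, each scored by k-fold cross-validated RMSE on
the training split, with the best-RMSE configuration refit on the full
training set.  Descriptor matrices from 2-D structure suites are
rank-deficient at library scale (a few dozen standards vs thousands of
descriptors), so zero-variance and pairwise-duplicate descriptors are
dropped and the rest standardized before fitting.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, Ridge
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor

__all__ = [
    "SplitSpec",
    "TrainedModel",
    "split_data",
    "train_regressor",
    "predict",
    "evaluate",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test split: train fraction defaults to the 8:2 protocol."""

    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def split_data(X, y, spec: SplitSpec = SplitSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive, seed-reproducible split; |train| = round(f * n)."""
    n = len(X)
    if len(y) != n:
        raise ValueError("X and y length mismatch")
    if n < 10:
        raise ValueError(f"need at least 10 observations to split, got {n}")
    n_train = int(round(spec.train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(spec.seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


@dataclass
class TrainedModel:
    """A fitted regressor plus its preprocessing state and search log."""

    columns: list[str]            # training descriptor columns, in order
    kept_mask: np.ndarray         # columns surviving variance/duplicate drop
    center: np.ndarray
    scale: np.ndarray
    regressor: Any
    config: dict                  # the selected configuration
    search_log: list[dict]        # every configuration tried, with CV RMSE
    training_rmse: float
    floor: float | None = None    # optional lower bound on predictions (RFs > 0)


def _drop_degenerate(X: np.ndarray) -> np.ndarray:
    """Mask of columns to keep: positive variance, first of each duplicate pair."""
    keep = X.std(axis=0) > 0
    seen: dict[bytes, int] = {}
    for j in np.flatnonzero(keep):
        key = np.round(X[:, j], 12).tobytes()
        if key in seen:
            keep[j] = False
        else:
            seen[key] = j
    return keep


class RelaxedLasso(BaseEstimator, RegressorMixin):
    """Lasso for support selection, then an unpenalized OLS refit on the
    selected descriptors (falls back to the lasso fit when nothing is
    selected).  Removes the shrinkage bias that plain lasso leaves on
    strong sparse signals."""

    def __init__(self, alpha: float = 1e-2):
        self.alpha = alpha

    def fit(self, X, y):
        self.lasso_ = Lasso(alpha=self.alpha, max_iter=20000).fit(X, y)
        self.support_ = np.flatnonzero(self.lasso_.coef_)
        if self.support_.size:
            self.ols_ = LinearRegression().fit(X[:, self.support_], y)
        else:
            self.ols_ = None
        return self

    def predict(self, X):
        if self.ols_ is None:
            return self.lasso_.predict(X)
        return self.ols_.predict(X[:, self.support_])


# Fixed baseline configurations always evaluated first (within the budget);
# the remainder of the budget is spent on random draws.
_BASELINE_CONFIGS: tuple[dict, ...] = (
    {"kind": "relaxed_lasso", "alpha": 1e-2},
    {"kind": "ridge", "alpha": 1.0},
    {"kind": "lasso", "alpha": 1e-2},
    {"kind": "elasticnet", "alpha": 1e-3, "l1_ratio": 0.5},
)


def _draw_config(rng: np.random.Generator) -> dict:
    u = rng.random()
    if u < 0.20:
        return {"kind": "ridge",
                "alpha": float(10.0 ** rng.uniform(-3, 3))}
    if u < 0.40:
        return {"kind": "lasso",
                "alpha": float(10.0 ** rng.uniform(-5, 0))}
    if u < 0.55:
        return {"kind": "relaxed_lasso",
                "alpha": float(10.0 ** rng.uniform(-4, 0))}
    if u < 0.65:
        return {"kind": "elasticnet",
                "alpha": float(10.0 ** rng.uniform(-4, 0)),
                "l1_ratio": float(rng.uniform(0.1, 0.9))}
    width = int(rng.choice([16, 32, 64]))
    depth = int(rng.choice([1, 2]))
    return {"kind": "mlp",
            "hidden_layer_sizes": (width,) * depth,
            "alpha": float(10.0 ** rng.uniform(-5, -1)),
            "random_state": int(rng.integers(0, 2**31 - 1))}


def _build(config: dict):
    kind = config["kind"]
    if kind == "ridge":
        return Ridge(alpha=config["alpha"])
    if kind == "lasso":
        return Lasso(alpha=config["alpha"], max_iter=20000)
    if kind == "relaxed_lasso":
        return RelaxedLasso(alpha=config["alpha"])
    if kind == "elasticnet":
        return ElasticNet(alpha=config["alpha"], l1_ratio=config["l1_ratio"],
                          max_iter=20000)
    if kind == "mlp":
        return MLPRegressor(hidden_layer_sizes=config["hidden_layer_sizes"],
                            alpha=config["alpha"], max_iter=600,
                            random_state=config["random_state"])
    raise ValueError(f"unknown configuration kind {kind!r}")


def train_regressor(
    X_train,
    y_train,
    budget: int = 50,
    seed: int = 0,
    cv_folds: int = 3,
    floor: float | None = None,
) -> TrainedModel:
    """Budgeted seeded random search; the minimum-CV-RMSE configuration wins.

    ``budget`` configurations are drawn from the declared ridge / lasso /
    elastic-net / MLP space and scored by ``cv_folds``-fold CV RMSE on the
    training split only.  Deterministic for fixed (data, budget, seed).
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    X_df = pd.DataFrame(X_train)
    columns = [str(c) for c in X_df.columns]
    X = X_df.to_numpy(dtype=float)
    y = np.asarray(y_train, dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in training data")

    kept = _drop_degenerate(X)
    Xk = X[:, kept]
    center = Xk.mean(axis=0)
    scale = Xk.std(axis=0)
    Z = (Xk - center) / scale

    rng = np.random.default_rng(seed)
    cv = KFold(n_splits=cv_folds, shuffle=True,
               random_state=int(rng.integers(0, 2**31 - 1)))
    folds = list(cv.split(Z))

    configs = [dict(c) for c in _BASELINE_CONFIGS[:budget]]
    configs += [_draw_config(rng) for _ in range(budget - len(configs))]

    log: list[dict] = []
    for config in configs:
        sq_err, n_val = 0.0, 0
        for tr, va in folds:
            reg = _build(config)
            reg.fit(Z[tr], y[tr])
            resid = y[va] - reg.predict(Z[va])
            sq_err += float(np.sum(resid ** 2))
            n_val += len(va)
        log.append({**config, "cv_rmse": float(np.sqrt(sq_err / n_val))})

    best_idx = int(np.argmin([e["cv_rmse"] for e in log]))
    best = log[best_idx]
    config = {k: v for k, v in best.items() if k != "cv_rmse"}
    reg = _build(config)
    reg.fit(Z, y)
    training_rmse = float(np.sqrt(np.mean((y - reg.predict(Z)) ** 2)))
    return TrainedModel(columns=columns, kept_mask=kept, center=center,
                        scale=scale, regressor=reg, config=config,
                        search_log=log, training_rmse=training_rmse, floor=floor)


def predict(model: TrainedModel, X_new) -> np.ndarray:
    """One finite prediction per row; applies the model's floor if set."""
    X_df = pd.DataFrame(X_new)
    cols = [str(c) for c in X_df.columns]
    missing = [c for c in model.columns if c not in cols]
    if missing:
        raise ValueError(f"X_new is missing descriptor columns: {missing}")
    X = X_df[model.columns].to_numpy(dtype=float)
    Z = (X[:, model.kept_mask] - model.center) / model.scale
    pred = np.asarray(model.regressor.predict(Z), dtype=float)
    if not np.all(np.isfinite(pred)):
        raise ValueError("non-finite prediction")
    if model.floor is not None:
        pred = np.maximum(pred, model.floor)
    return pred


def evaluate(model: TrainedModel, X_test, y_test) -> dict[str, float]:
    """Test-set RMSE and R^2 (standard definitions, response units)."""
    y = np.asarray(y_test, dtype=float)
    if len(y) == 0:
        raise ValueError("empty test set")
    pred = predict(model, X_test)
    resid = y - pred
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    rmse = float(np.sqrt(ss_res / len(y)))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return {"rmse": rmse, "r2": r2}


def save_model(model: TrainedModel, path) -> None:
    """Serialize the model (preprocessing, regressor and search log) to one file."""
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path) -> TrainedModel:
    with open(path, "rb") as fh:
        return pickle.load(fh)
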