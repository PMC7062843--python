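"""Linear epsilon-SVR on selected edge features.

The severity score is approximated by the affine model f(x) = w'x + b,
where w and b solve the epsilon-insensitive primal problem

    min  1/2 ||w||^2 + C * sum_i (xi_i + xi*_i)
    s.t. (w'x_i + b) - y_i <= eps + xi_i
         y_i - (w'x_i + b) <= eps + xi*_i
         xi_i, xi*_i >= 0.

Residuals inside the tube of radius eps incur no loss; C trades data fit
against the ||w||^2 regularizer.  The solver is the libsvm SMO backend
(via scikit-learn); the contract here is objective-level, so any
convergent epsilon-SVR solver would do.

Defaults: linear kernel, C = 1, eps = 0.1 (the conventional default of
the libsvm family).  Features are not standardized by default - Fisher-z
edges share a common scale - but an opt-in flag exists for sensitivity
analysis; when used, the scaler is folded back into (w, b) so the model
stays a plain affine map on raw features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.svm import SVR

from .selection import SelectionError


class EmptyFeatureSetError(SelectionError):
    """Regression refused: the selected feature set is empty."""


@dataclass(frozen=True)
class SvrConfig:
    """epsilon-SVR hyperparameters (linear kernel is fixed)."""

    C: float = 1.0
    epsilon: float = 0.1
    tol: float = 1e-6
    standardize: bool = False

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass
class SvrModel:
    """A fitted linear epsilon-SVR: weights, bias and slack diagnostics."""

    w: np.ndarray          # score units per z-unit, one weight per edge
    b: float               # score units
    config: SvrConfig
    selected_edge_ids: np.ndarray | None = None
    objective: float = np.nan
    xi: np.ndarray = field(default_factory=lambda: np.empty(0))
    xi_star: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def total_slack(self) -> float:
        return float(self.xi.sum() + self.xi_star.sum())


def primal_objective(w, b, X, y, config: SvrConfig) -> float:
    """Value of the epsilon-SVR primal objective at (w, b)."""
    w = np.asarray(w, dtype=float)
    resid = np.abs(np.asarray(X) @ w + b - np.asarray(y))
    slack = np.clip(resid - config.epsilon, 0.0, None)
    return float(0.5 * w @ w + config.C * slack.sum())


def fit(X: np.ndarray, y: np.ndarray, config: SvrConfig | None = None,
        selected_edge_ids=None) -> SvrModel:
    """Fit a linear epsilon-SVR; returns the primal solution with diagnostics.

    Requires at least 2 training subjects, at least one feature and
    non-constant y.  An empty feature set raises
    :class:`EmptyFeatureSetError` rather than fitting a bias-only model.
    """
    config = config or SvrConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"X must be 2-D (subjects x features), got {X.shape}")
    if X.shape[1] == 0:
        raise EmptyFeatureSetError("refusing to fit on an empty feature set")
    if X.shape[0] != len(y):
        raise ValueError("X and y lengths differ")
    if X.shape[0] < 2:
        raise ValueError("need >= 2 training subjects")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in training data")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; regression is degenerate")

    if config.standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        Xs = (X - mean) / scale
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
        Xs = X

    est = SVR(kernel="linear", C=config.C, epsilon=config.epsilon, tol=config.tol)
    est.fit(Xs, y)
    w_s = est.coef_.ravel().astype(float)
    b_s = float(est.intercept_[0])
    # Fold the scaler into (w, b) so predict is a plain affine map on raw X.
    w = w_s / scale
    b = b_s - float((w_s * mean / scale).sum())

    f = X @ w + b
    xi = np.clip(f - y - config.epsilon, 0.0, None)
    xi_star = np.clip(y - f - config.epsilon, 0.0, None)
    model = SvrModel(
        w=w,
        b=b,
        config=config,
        selected_edge_ids=None if selected_edge_ids is None
        else np.asarray(selected_edge_ids, dtype=int),
        xi=xi,
        xi_star=xi_star,
    )
    model.objective = primal_objective(w, b, X, y, config)
    return model


def predict(model: SvrModel, X: np.ndarray) -> np.ndarray:
    """f(x) = w'x + b per subject."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.w.shape[0]:
        raise ValueError(
            f"feature count mismatch: model has {model.w.shape[0]}, X has "
            f"{X.shape[1] if X.ndim == 2 else '?'}"
        )
    return X @ model.w + model.b


def save_model(path, model: SvrModel) -> None:
    """Serialize a fitted model as JSON (edge ids, w, b, config)."""
    payload = {
        "w": model.w.tolist(),
        "b": model.b,
        "config": asdict(model.config),
        "selected_edge_ids": None if model.selected_edge_ids is None
        else model.selected_edge_ids.tolist(),
        "objective": model.objective,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path) -> SvrModel:
    payload = json.loads(Path(path).read_text())
    return SvrModel(
        w=np.asarray(payload["w"], dtype=float),
        b=float(payload["b"]),
        config=SvrConfig(**payload["config"]),
        selected_edge_ids=None if payload["selected_edge_ids"] is None
        else np.asarray(payload["selected_edge_ids"], dtype=int),
        objective=float(payload["objective"]),
    )
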