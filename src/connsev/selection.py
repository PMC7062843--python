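"""Correlation-filtered edge selection with a p-value threshold.

Each edge feature is scored by its Pearson correlation r with the observed
severity scores across training subjects; the two-sided p-value follows
from t = r * sqrt(n-2) / sqrt(1 - r^2) on n-2 degrees of freedom.  Edges
with p strictly below the threshold are retained.

The threshold itself is a hyperparameter.  Two grid procedures are
provided:

- **stage 1**: nested leave-one-out on the training set over the grid
  0.0005-0.05 (step 0.0005, 100 candidates), choosing the candidate with
  the minimum mean squared error of the inner predictions;
- **stage 2**: a refined grid 0.002-0.003 (step 0.0001, 11 candidates)
  evaluated by running the outer cross-validation directly and maximizing
  the Pearson correlation between cross-validated predictions and the
  observed scores.

Ties are broken toward the smallest threshold (fewer features, more
conservative).  Stage 1 is quadratic in the sample size and is off by
default in the main pipeline; the default protocol is a user-fixed
threshold (0.0023) or the stage-2 grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import svr

DEFAULT_THRESHOLD = 0.0023


class SelectionError(RuntimeError):
    """Feature selection could not produce a usable feature set."""


@dataclass
class EdgeScores:
    """Per-edge correlation with the observed scores and two-sided p-value.

    The sign of r defines the edge's positive/negative-correlation class.
    Constant edges get r=0, p=1 so vector shapes stay stable.
    """

    r: np.ndarray
    p: np.ndarray
    n_subjects: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "edge_id": np.arange(len(self.r)),
            "r": self.r,
            "p": self.p,
        })


def score_edges(X: np.ndarray, y: np.ndarray) -> EdgeScores:
    """Pearson r and two-sided t-test p-value of every edge against y.

    Requires at least 4 subjects and non-constant y.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X.ndim != 2 or X.shape[0] != n:
        raise ValueError(f"X must be (subjects x edges) aligned with y, got {X.shape}")
    if n < 4:
        raise ValueError(f"need >= 4 subjects, got {n}")
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    if sy == 0:
        raise ValueError("y is constant; correlations are undefined")
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    const = sx == 0
    r = np.zeros(X.shape[1])
    np.divide(Xc.T @ yc, sx * sy, out=r, where=~const)
    r = np.clip(r, -1.0, 1.0)

    p = np.ones_like(r)
    nz = ~const
    with np.errstate(divide="ignore"):
        t = np.abs(r[nz]) * np.sqrt((n - 2) / np.maximum(1 - r[nz] ** 2, 1e-300))
    p[nz] = 2 * stats.t.sf(t, df=n - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)  # p in (0, 1]
    return EdgeScores(r=r, p=p, n_subjects=n)


def select_edges(scores, p_threshold: float) -> np.ndarray:
    """Boolean mask of edges with p strictly below the threshold."""
    if not (0 < p_threshold <= 1):
        raise ValueError(f"p_threshold must be in (0, 1], got {p_threshold}")
    p = scores.p if isinstance(scores, EdgeScores) else np.asarray(scores, dtype=float)
    return p < p_threshold


@dataclass
class ThresholdSearchResult:
    """Grid search outcome: every candidate's criterion and the winner."""

    grid: np.ndarray
    criterion: np.ndarray
    chosen: float
    stage: int
    criterion_name: str


def stage1_grid() -> np.ndarray:
    """100 candidates: 0.0005 to 0.05 inclusive, step 0.0005."""
    return np.arange(1, 101) * 0.0005


def stage2_grid() -> np.ndarray:
    """11 candidates: 0.002 to 0.003 inclusive, step 0.0001."""
    return np.round(np.arange(20, 31) * 1e-4, 6)


def stage1_threshold_search(
    X_train: np.ndarray,
    y_train: np.ndarray,
    grid: np.ndarray | None = None,
    svr_config: "svr.SvrConfig | None" = None,
) -> ThresholdSearchResult:
    """Inner-LOOCV grid search minimizing the MSE of inner predictions.

    For each candidate threshold, selection and SVR fitting are repeated
    inside every inner fold of the training set; candidates for which any
    inner fold selects no edge get an infinite criterion.  Raises
    :class:`SelectionError` if every candidate does.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    n = len(y_train)
    if n < 10:
        raise ValueError(f"need >= 10 training subjects, got {n}")
    grid = stage1_grid() if grid is None else np.asarray(grid, dtype=float)

    # Edge p-values depend on the inner fold only, not the threshold.
    fold_p = []
    for k in range(n):
        idx = np.concatenate([np.arange(k), np.arange(k + 1, n)])
        fold_p.append(score_edges(X_train[idx], y_train[idx]).p)

    criterion = np.full(len(grid), np.inf)
    for g, thr in enumerate(grid):
        preds = np.empty(n)
        ok = True
        for k in range(n):
            mask = fold_p[k] < thr
            if not mask.any():
                ok = False
                break
            idx = np.concatenate([np.arange(k), np.arange(k + 1, n)])
            model = svr.fit(X_train[idx][:, mask], y_train[idx], svr_config)
            preds[k] = svr.predict(model, X_train[k][mask][None, :])[0]
        if ok:
            criterion[g] = float(np.mean((preds - y_train) ** 2))
    if not np.isfinite(criterion).any():
        raise SelectionError("every candidate threshold yields an empty feature set")
    best = int(np.argmin(criterion))  # first minimum = smallest threshold
    return ThresholdSearchResult(grid, criterion, float(grid[best]), 1, "MSE")


def stage2_threshold_search(
    X: np.ndarray,
    y: np.ndarray,
    cv_scheme=None,
    grid: np.ndarray | None = None,
    svr_config: "svr.SvrConfig | None" = None,
) -> ThresholdSearchResult:
    """Refined grid search maximizing cross-validated prediction R.

    Runs the given cross-validation scheme (leave-one-out by default) at
    every candidate threshold and keeps the candidate whose predictions
    correlate best with the observed scores.
    """
    from . import evaluation  # deferred: evaluation imports this module

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 10:
        raise ValueError(f"need >= 10 subjects, got {len(y)}")
    grid = stage2_grid() if grid is None else np.asarray(grid, dtype=float)
    scheme = cv_scheme if cv_scheme is not None else evaluation.CvScheme("loocv")

    criterion = np.full(len(grid), -np.inf)
    any_ok = False
    for g, thr in enumerate(grid):
        try:
            run = evaluation.run_cv(X, y, scheme=scheme, threshold=float(thr),
                                    svr_config=svr_config)
        except evaluation.FoldSelectionError:
            continue
        m = evaluation.cv_metrics(run, y)
        if np.isfinite(m["R"]):
            criterion[g] = m["R"]
            any_ok = True
    if not any_ok:
        raise SelectionError("no candidate threshold produced a finite criterion")
    best = int(np.argmax(criterion))  # first maximum = smallest threshold
    return ThresholdSearchResult(grid, criterion, float(grid[best]), 2, "R")
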