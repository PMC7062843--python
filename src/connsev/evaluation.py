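"""Cross-validated severity estimation and fold-stability contributions.

Feature selection is nested inside cross-validation: each fold scores and
filters edges on its training subjects only, fits a linear epsilon-SVR on
the surviving edges, and predicts the held-out subjects.  Accuracy is
summarized by the Pearson correlation R between cross-validated
predictions and observed scores, the mean absolute error (MAE) and the
mean squared error (MSE), all in severity-score units.

Stability of the selection is expressed as *contributions*:

- edge contribution = (# folds selecting the edge) / (# folds), in [0, 1];
  for repeated k-fold the denominator is the total fold count across
  repeats, keeping the scale comparable with leave-one-out;
- ROI contribution = sum of contributions of incident edges, min-max
  normalized to [0, 1] over the ROIs incident to at least one selected
  edge;
- division contributions = percentage shares of total contribution over a
  partition of edges (intra/inter-network; hemisphere classes) or over
  endpoint-keyed divisions (six networks; six lobes), split by the sign of
  each edge's full-sample correlation with the scores.

For endpoint-keyed schemes an edge whose ends lie in different divisions
gives half its contribution to each; an edge within one division
contributes fully to it.  This attribution makes every scheme's shares sum
to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import LeaveOneOut, RepeatedKFold

from . import features, svr
from .selection import EdgeScores, score_edges, select_edges, DEFAULT_THRESHOLD

DIVISION_SCHEMES = ("intra_inter", "network", "hemisphere", "lobe")


class FoldSelectionError(RuntimeError):
    """A fold selected no edges; carries per-fold diagnostics."""

    def __init__(self, fold: int, threshold: float, min_p: float):
        self.fold = fold
        self.threshold = threshold
        self.min_p = min_p
        super().__init__(
            f"fold {fold}: no edge with p < {threshold} (smallest p = {min_p:.3g})"
        )


@dataclass(frozen=True)
class CvScheme:
    """Cross-validation scheme: leave-one-out or seeded repeated k-fold."""

    kind: str = "loocv"
    k: int = 10
    repeats: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("loocv", "kfold"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.kind == "kfold" and (self.k < 2 or self.repeats < 1):
            raise ValueError("kfold needs k >= 2 and repeats >= 1")


@dataclass
class FoldResult:
    """One fold: indices, selection mask and the fitted model."""

    fold: int
    repeat: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    mask: np.ndarray
    threshold: float
    model: svr.SvrModel


@dataclass
class CvRun:
    """A completed cross-validation with per-fold selection records.

    ``predictions`` has shape (n_subjects,) for leave-one-out and
    (repeats, n_subjects) for repeated k-fold, where every subject is
    tested exactly once per repeat.
    """

    scheme: CvScheme
    n_subjects: int
    n_edges: int
    threshold: float
    predictions: np.ndarray
    folds: list = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def _folds(scheme: CvScheme, n: int):
    if scheme.kind == "loocv":
        for f, (tr, te) in enumerate(LeaveOneOut().split(np.arange(n))):
            yield f, 0, tr, te
    else:
        rkf = RepeatedKFold(n_splits=scheme.k, n_repeats=scheme.repeats,
                            random_state=scheme.seed)
        for f, (tr, te) in enumerate(rkf.split(np.arange(n))):
            yield f, f // scheme.k, tr, te


def run_cv(
    X: np.ndarray,
    y: np.ndarray,
    scheme: CvScheme | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    svr_config: svr.SvrConfig | None = None,
) -> CvRun:
    """Cross-validate with fold-wise selection; fully seeded and reproducible.

    Selection masks derive only from each fold's training subjects.  A fold
    whose filter retains no edge aborts the run with
    :class:`FoldSelectionError` diagnostics.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError(f"need >= 10 subjects, got {n}")
    if X.shape[0] != n:
        raise ValueError("X and y lengths differ")
    scheme = scheme or CvScheme("loocv")

    if scheme.kind == "loocv":
        predictions = np.full(n, np.nan)
    else:
        predictions = np.full((scheme.repeats, n), np.nan)

    folds = []
    for f, rep, tr, te in _folds(scheme, n):
        scores = score_edges(X[tr], y[tr])
        mask = select_edges(scores, threshold)
        if not mask.any():
            raise FoldSelectionError(f, threshold, float(scores.p.min()))
        model = svr.fit(X[tr][:, mask], y[tr], svr_config,
                        selected_edge_ids=np.flatnonzero(mask))
        preds = svr.predict(model, X[te][:, mask])
        if scheme.kind == "loocv":
            predictions[te] = preds
        else:
            predictions[rep, te] = preds
        folds.append(FoldResult(f, rep, tr.copy(), te.copy(), mask, threshold, model))

    return CvRun(scheme=scheme, n_subjects=n, n_edges=X.shape[1],
                 threshold=threshold, predictions=predictions, folds=folds)


def metrics(predictions: np.ndarray, y: np.ndarray) -> dict:
    """R (with its p-value), MAE and MSE of predictions against y.

    Constant predictions leave R undefined (NaN) while MAE/MSE stay valid.
    """
    predictions = np.asarray(predictions, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if predictions.shape != y.shape:
        raise ValueError("length mismatch between predictions and y")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; R is undefined")
    out = {
        "MAE": float(np.mean(np.abs(predictions - y))),
        "MSE": float(np.mean((predictions - y) ** 2)),
    }
    if np.ptp(predictions) == 0:
        out["R"] = float("nan")
        out["R_p"] = float("nan")
    else:
        r, p = stats.pearsonr(predictions, y)
        out["R"] = float(r)
        out["R_p"] = float(p)
    return out


def cv_metrics(run: CvRun, y: np.ndarray) -> dict:
    """Run-level metrics; repeated k-fold averages metrics over repeats."""
    if run.scheme.kind == "loocv":
        return metrics(run.predictions, y)
    per_rep = [metrics(run.predictions[r], y) for r in range(run.predictions.shape[0])]
    return {k: float(np.mean([m[k] for m in per_rep])) for k in ("R", "R_p", "MAE", "MSE")}


# ---------------------------------------------------------------------------
# Contributions


def edge_contributions(run: CvRun) -> np.ndarray:
    """Fraction of folds in which each edge was selected, in [0, 1]."""
    counts = np.zeros(run.n_edges)
    for fr in run.folds:
        counts += fr.mask
    return counts / run.n_folds


def roi_contributions(edge_contribs: np.ndarray, pair_index: np.ndarray,
                      n_rois: int) -> pd.Series:
    """Min-max-normalized per-ROI sums of incident edge contributions.

    Only ROIs incident to at least one selected edge are included.  When
    all included ROIs tie (min == max), the tied nonzero value maps to 1.0.
    """
    edge_contribs = np.asarray(edge_contribs, dtype=float)
    if not np.any(edge_contribs > 0):
        raise ValueError("all edge contributions are zero")
    raw = np.zeros(n_rois)
    sel = edge_contribs > 0
    np.add.at(raw, pair_index[sel, 0] - 1, edge_contribs[sel])
    np.add.at(raw, pair_index[sel, 1] - 1, edge_contribs[sel])
    incident = raw > 0
    vals = raw[incident]
    lo, hi = vals.min(), vals.max()
    norm = np.ones_like(vals) if hi == lo else (vals - lo) / (hi - lo)
    index = pd.Index(np.flatnonzero(incident) + 1, name="roi_index")
    return pd.Series(norm, index=index, name="contribution")


def _division_frame(edge_contribs, signs, edge_ann: pd.DataFrame, scheme: str):
    """Rows of (division, signed weight * contribution) for one scheme."""
    c = np.asarray(edge_contribs, dtype=float)
    s = np.asarray(signs)
    sel = c > 0
    idx = np.flatnonzero(sel)
    ann = edge_ann.iloc[idx]
    pos = s[idx] >= 0
    if scheme == "intra_inter":
        div = np.where(ann["intra_network"].to_numpy(), "intra-network", "inter-network")
        return pd.DataFrame({"division": div, "contribution": c[idx], "positive": pos}), \
            ["intra-network", "inter-network"]
    if scheme == "hemisphere":
        return pd.DataFrame({"division": ann["hemisphere_class"].to_numpy(),
                             "contribution": c[idx], "positive": pos}), \
            list(features.HEMISPHERE_CLASSES)
    if scheme == "network":
        end1, end2 = ann["network1"].to_numpy(), ann["network2"].to_numpy()
        order = list(features.NETWORKS)
    elif scheme == "lobe":
        end1 = ann["lobe1"].map(features.lobe_division).to_numpy()
        end2 = ann["lobe2"].map(features.lobe_division).to_numpy()
        order = list(features.LOBE_DIVISIONS)
    else:
        raise ValueError(f"unknown division scheme {scheme!r}; "
                         f"expected one of {DIVISION_SCHEMES}")
    # Endpoint-keyed: half the contribution to each end's division (full
    # weight when both ends share the division).
    half = pd.DataFrame({
        "division": np.concatenate([end1, end2]),
        "contribution": np.concatenate([c[idx] / 2, c[idx] / 2]),
        "positive": np.concatenate([pos, pos]),
    })
    return half, order


def division_summary(edge_contribs, signs, edge_ann: pd.DataFrame,
                     scheme: str) -> pd.DataFrame:
    """Percentage contribution shares per division, split by correlation sign.

    ``signs`` is the per-edge sign of the full-sample correlation with the
    observed scores (a descriptive quantity, not a cross-validated one).
    Shares sum to 100 and positive + negative sub-shares equal each
    division's share.
    """
    frame, order = _division_frame(edge_contribs, signs, edge_ann, scheme)
    total = frame["contribution"].sum()
    if total == 0:
        raise ValueError("no positive edge contributions to summarize")
    rows = []
    for div in order:
        sub = frame[frame["division"] == div]
        share = 100 * sub["contribution"].sum() / total
        pos = 100 * sub.loc[sub["positive"], "contribution"].sum() / total
        rows.append({"division": div, "share_pct": share,
                     "positive_pct": pos, "negative_pct": share - pos})
    return pd.DataFrame(rows)


def all_division_summaries(edge_contribs, signs, edge_ann) -> dict:
    return {scheme: division_summary(edge_contribs, signs, edge_ann, scheme)
            for scheme in DIVISION_SCHEMES}


# ---------------------------------------------------------------------------
# Report tables


def report_tables(run: CvRun, X: np.ndarray, y: np.ndarray,
                  annotation: pd.DataFrame):
    """Per-edge and per-ROI report tables for all edges ever selected.

    The per-edge table carries ROI names, networks, lobes, hemisphere
    class, the full-sample correlation r with the observed scores (labeled
    as such: it is recomputed on all subjects, not averaged over folds) and
    the fold contribution, sorted positive sign first, then contribution
    descending.  The per-ROI table carries min-max-normalized ROI
    contributions sorted descending.  Output is deterministic for a fixed
    run.
    """
    n_rois = len(annotation)
    pair_index = features.canonical_pairs(n_rois)
    edge_ann = features.annotate_edges(pair_index, annotation)
    contribs = edge_contributions(run)
    full_r = score_edges(X, y).r

    sel = np.flatnonzero(contribs > 0)
    edges = edge_ann.iloc[sel].copy()
    edges["full_sample_r"] = full_r[sel]
    edges["contribution"] = contribs[sel]
    edges["sign"] = np.where(edges["full_sample_r"] >= 0, "positive", "negative")
    edges = edges.sort_values(
        by=["sign", "contribution", "edge_id"],
        ascending=[False, False, True],  # 'positive' > 'negative' lexically
    ).reset_index(drop=True)
    edge_cols = ["edge_id", "roi1", "name1", "lobe1", "network1",
                 "roi2", "name2", "lobe2", "network2",
                 "full_sample_r", "contribution", "sign",
                 "intra_network", "hemisphere_class"]
    edges = edges[edge_cols]

    roi_c = roi_contributions(contribs, pair_index, n_rois)
    rois = annotation.set_index("roi_index").loc[roi_c.index,
                                                 ["name", "hemisphere", "lobe", "network"]]
    rois = rois.assign(contribution=roi_c.values).reset_index()
    rois = rois.sort_values(by=["contribution", "roi_index"],
                            ascending=[False, True]).reset_index(drop=True)
    return edges, rois


def fold_selection_table(run: CvRun, full_r: np.ndarray | None = None) -> pd.DataFrame:
    """Long-format per-fold selected-edge list (fold, edge_id, [r])."""
    rows = []
    for fr in run.folds:
        for e in np.flatnonzero(fr.mask):
            rows.append({"fold": fr.fold, "repeat": fr.repeat, "edge_id": int(e)})
    df = pd.DataFrame(rows, columns=["fold", "repeat", "edge_id"])
    if full_r is not None and len(df):
        df["full_sample_r"] = np.asarray(full_r)[df["edge_id"].to_numpy()]
    return df


def audit_no_leakage(run: CvRun, X: np.ndarray, y: np.ndarray) -> bool:
    """Recompute every fold's mask from its stored training ids; must match."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    for fr in run.folds:
        scores = score_edges(X[fr.train_idx], y[fr.train_idx])
        if not np.array_equal(select_edges(scores, fr.threshold), fr.mask):
            return False
    return True
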