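"""Connectome edge features from ROI time series.

Per subject, the pipeline averages voxel signals within each region of
interest (ROI), correlates every ROI pair (Pearson), variance-stabilizes the
correlations with Fisher's r-to-z transform, and vectorizes the upper
triangle of the symmetric z matrix into a canonical edge vector.  For the
116-region AAL parcellation this yields 116*115/2 = 6670 edge features per
subject.

The canonical edge order is row-major over the strict upper triangle with
ROIs in ascending atlas order: (1,2), (1,3), ..., (1,n), (2,3), ...  The
order is fixed so that edge vectors are comparable across subjects and
serializable with a stable pair index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: |r| is clipped to this bound before arctanh so that degenerate, perfectly
#: correlated inputs map to a large finite z instead of +/-inf.
FISHER_CLIP = 1.0 - 1e-7

#: The six functional networks used to annotate ROIs.
NETWORKS = ("DMN", "EAN", "SMN", "Visual", "SBN", "Cerebel")

#: Coarse lobe divisions used for reporting; the annotation's fine-grained
#: lobe labels map onto these (prefrontal counts as Frontal, cerebellar
#: hemispheres and vermis together form Cerebellum).
LOBE_DIVISIONS = ("Frontal", "Temporal", "Parietal", "Occipital", "Insula", "Cerebellum")

HEMISPHERE_CLASSES = ("inter-hemispheric", "LH", "RH", "cerebellar")


class DegenerateSeriesError(ValueError):
    """A ROI time series has zero variance; correlations are undefined."""


def n_edges(n_rois: int) -> int:
    """Number of distinct ROI pairs, n*(n-1)/2."""
    return n_rois * (n_rois - 1) // 2


def canonical_pairs(n_rois: int) -> np.ndarray:
    """Canonical (i, j) ROI pairs, 1-based, i < j, row-major upper triangle.

    Returns an (n_edges, 2) integer array.
    """
    iu = np.triu_indices(n_rois, k=1)
    return np.column_stack(iu).astype(np.int64) + 1


def edge_id(i: int, j: int, n_rois: int) -> int:
    """Canonical 0-based edge index of the 1-based ROI pair (i, j), i < j."""
    if not (1 <= i < j <= n_rois):
        raise ValueError(f"need 1 <= i < j <= {n_rois}, got ({i}, {j})")
    i0, j0 = i - 1, j - 1
    return i0 * n_rois - i0 * (i0 + 1) // 2 + (j0 - i0 - 1)


def roi_mean_timeseries(volume4d: np.ndarray, labels: np.ndarray, n_rois: int) -> np.ndarray:
    """Average voxel signals within each labeled ROI.

    Parameters
    ----------
    volume4d : (x, y, z, t) array of voxel time series.
    labels : (x, y, z) integer array; voxels labeled k belong to ROI k,
        label 0 is background.
    n_rois : number of ROIs; every label 1..n_rois must be present.

    Returns
    -------
    (t, n_rois) array; column k-1 is the mean series of ROI k.
    """
    volume4d = np.asarray(volume4d)
    labels = np.asarray(labels)
    if volume4d.ndim != 4:
        raise ValueError(f"volume4d must be 4-D, got shape {volume4d.shape}")
    if labels.shape != volume4d.shape[:3]:
        raise ValueError(
            f"label shape {labels.shape} does not match volume {volume4d.shape[:3]}"
        )
    flat_labels = labels.reshape(-1)
    flat = volume4d.reshape(-1, volume4d.shape[3])
    missing = [k for k in range(1, n_rois + 1) if not np.any(flat_labels == k)]
    if missing:
        raise ValueError(f"ROIs with zero voxels: {missing}")
    out = np.empty((volume4d.shape[3], n_rois), dtype=float)
    for k in range(1, n_rois + 1):
        out[:, k - 1] = flat[flat_labels == k].mean(axis=0)
    return out


def pearson_matrix(timeseries: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix between ROI time series (columns).

    Requires at least 3 timepoints and no zero-variance column; a constant
    ROI series is a hard error naming the offending 1-based ROI indices.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError(f"timeseries must be 2-D (timepoints x ROIs), got {ts.shape}")
    if ts.shape[0] < 3:
        raise ValueError(f"need >= 3 timepoints, got {ts.shape[0]}")
    sd = ts.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise DegenerateSeriesError(
            f"zero-variance ROI series (1-based indices): {(dead + 1).tolist()}"
        )
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(r):
    """Fisher r-to-z transform, z = arctanh(r), with |r| clipped to 1 - 1e-7.

    Strictly increasing and odd; clipping keeps degenerate perfectly
    correlated inputs finite (logged when triggered).
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    if np.any(np.abs(r) > FISHER_CLIP):
        log.info("fisher_z: clipped %d value(s) with |r| > %g",
                 int(np.sum(np.abs(r) > FISHER_CLIP)), FISHER_CLIP)
    out = np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))
    return out if out.ndim else float(out)


@dataclass
class EdgeVector:
    """One subject's Fisher-z edge features with the canonical pair index."""

    subject_id: str
    z: np.ndarray
    pair_index: np.ndarray  # (n_edges, 2), 1-based ROI pairs

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape[0] != self.pair_index.shape[0]:
            raise ValueError("z and pair_index lengths differ")
        if not np.all(np.isfinite(self.z)):
            raise ValueError(f"non-finite edge values for subject {self.subject_id}")


def vectorize_upper(matrix: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Extract the strict upper triangle of a symmetric matrix in canonical order.

    The operation is invertible given the pair index (see ``unvectorize``).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix must be square, got {m.shape}")
    if not np.allclose(m, m.T, atol=atol, rtol=0):
        raise ValueError("matrix is not symmetric within tolerance")
    return m[np.triu_indices(m.shape[0], k=1)]


def unvectorize(values: np.ndarray, n_rois: int, diagonal: float = 0.0) -> np.ndarray:
    """Rebuild the symmetric matrix from a canonical upper-triangle vector."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] != n_edges(n_rois):
        raise ValueError(f"expected {n_edges(n_rois)} values, got {values.shape[0]}")
    m = np.zeros((n_rois, n_rois))
    iu = np.triu_indices(n_rois, k=1)
    m[iu] = values
    m = m + m.T
    np.fill_diagonal(m, diagonal)
    return m


def subject_edge_vector(timeseries: np.ndarray) -> np.ndarray:
    """Time series -> Pearson matrix -> canonical edge vector -> Fisher z.

    Vectorizing before the transform keeps the (clipped) unit diagonal out
    of the z-scores; off-diagonal entries are unaffected by the order.
    """
    return fisher_z(vectorize_upper(pearson_matrix(timeseries)))


def cohort_edge_matrix(timeseries_list) -> np.ndarray:
    """Stack per-subject edge vectors into a (subjects x edges) matrix."""
    return np.vstack([subject_edge_vector(ts) for ts in timeseries_list])


# ---------------------------------------------------------------------------
# ROI annotation and per-edge metadata


def load_annotation(path=None) -> pd.DataFrame:
    """Load and validate an ROI annotation table.

    Columns: roi_index (1..n, one row each), name, hemisphere (L/R/none),
    lobe, network (one of the six functional networks).  With no path, the
    packaged AAL-116 annotation is used; its six-network assignment is a
    best-effort reconstruction and can be overridden by supplying a CSV.
    """
    if path is None:
        with resources.files("connsev.data").joinpath("aal116_annotation.csv").open() as fh:
            ann = pd.read_csv(fh)
    else:
        ann = pd.read_csv(path)
    required = ["roi_index", "name", "hemisphere", "lobe", "network"]
    missing = [c for c in required if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    n = len(ann)
    idx = ann["roi_index"].to_numpy()
    if len(np.unique(idx)) != n or set(idx) != set(range(1, n + 1)):
        raise ValueError("roi_index must be exactly 1..n with one row per ROI")
    bad_net = sorted(set(ann["network"]) - set(NETWORKS))
    if bad_net:
        raise ValueError(f"unknown networks {bad_net}; expected one of {NETWORKS}")
    bad_hemi = sorted(set(ann["hemisphere"]) - {"L", "R", "none"})
    if bad_hemi:
        raise ValueError(f"unknown hemisphere labels {bad_hemi}")
    none_rows = ann[ann["hemisphere"] == "none"]
    if not none_rows.empty and not (none_rows["lobe"] == "Vermis").all():
        raise ValueError("hemisphere 'none' is reserved for vermis regions")
    return ann.sort_values("roi_index").reset_index(drop=True)


def lobe_division(lobe: str) -> str:
    """Map a fine-grained lobe label onto one of the six reporting lobes."""
    if lobe == "prefrontal":
        return "Frontal"
    if lobe in ("Cerebellum", "Vermis"):
        return "Cerebellum"
    if lobe not in LOBE_DIVISIONS:
        raise ValueError(f"unknown lobe label: {lobe!r}")
    return lobe


def annotate_edges(pair_index: np.ndarray, annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-edge metadata derived from the ROI annotation.

    Returns a DataFrame aligned with the canonical edge order, with the
    names/networks/lobes at both ends, an intra-network flag (both ends in
    the same functional network), and a hemisphere class:

    - ``cerebellar`` if either end is a cerebellum or vermis region,
    - ``inter-hemispheric`` if the ends lie in opposite hemispheres,
    - ``LH`` / ``RH`` otherwise.
    """
    ann = annotation.set_index("roi_index")
    missing = sorted(set(np.unique(pair_index)) - set(ann.index))
    if missing:
        raise ValueError(f"annotation missing ROI indices: {missing}")
    i, j = pair_index[:, 0], pair_index[:, 1]

    def col(name, side):
        return ann[name].loc[side].to_numpy()

    net1, net2 = col("network", i), col("network", j)
    hemi1, hemi2 = col("hemisphere", i), col("hemisphere", j)
    lobe1, lobe2 = col("lobe", i), col("lobe", j)
    cerebellar = (net1 == "Cerebel") | (net2 == "Cerebel")
    inter_h = (hemi1 != hemi2) & ~cerebellar
    hemi_class = np.where(
        cerebellar, "cerebellar",
        np.where(inter_h, "inter-hemispheric", np.where(hemi1 == "L", "LH", "RH")),
    )
    return pd.DataFrame({
        "edge_id": np.arange(len(i)),
        "roi1": i,
        "roi2": j,
        "name1": col("name", i),
        "name2": col("name", j),
        "network1": net1,
        "network2": net2,
        "lobe1": lobe1,
        "lobe2": lobe2,
        "intra_network": net1 == net2,
        "hemisphere_class": hemi_class,
    })


def write_edge_matrix(path, X: np.ndarray, subject_ids, annotation=None) -> None:
    """Write a subjects x edges matrix as TSV with ROIi__ROIj column names."""
    n_r = int(round((1 + np.sqrt(1 + 8 * X.shape[1])) / 2))
    if n_edges(n_r) != X.shape[1]:
        raise ValueError(f"{X.shape[1]} columns is not a triangular number")
    pairs = canonical_pairs(n_r)
    cols = [f"ROI{i}__ROI{j}" for i, j in pairs]
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "subject_id", list(subject_ids))
    df.to_csv(path, sep="\t", index=False)


def read_edge_matrix(path):
    """Read a TSV written by ``write_edge_matrix``; returns (ids, X, pairs)."""
    df = pd.read_csv(path, sep="\t")
    ids = df["subject_id"].astype(str).tolist()
    X = df.drop(columns="subject_id").to_numpy(dtype=float)
    n_r = int(round((1 + np.sqrt(1 + 8 * X.shape[1])) / 2))
    return ids, X, canonical_pairs(n_r)


def write_pair_index(path, pair_index: np.ndarray) -> None:
    pd.DataFrame(pair_index, columns=["roi1", "roi2"]).assign(
        edge_id=np.arange(len(pair_index))
    )[["edge_id", "roi1", "roi2"]].to_csv(path, index=False)
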