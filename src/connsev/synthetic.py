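"""Synthetic cohorts with planted connectivity-severity structure.

The generator emulates the statistical structure the analysis assumes: each
subject has an integer severity score s (uniform on 1..10 by default, the
scale of calibrated severity scores), and a small set of ROI-disjoint
"planted" edges whose Pearson correlation varies linearly with s,

    r(s) = base_correlation + severity_slope * (s - s_mid),

where s_mid is the midpoint of the severity range.  The target correlation
is realized exactly by a shared-latent construction: for a planted edge
(i, j) with target r,

    x_i = sqrt(|r|) * g + sqrt(1 - |r|) * e_i
    x_j = sign(r) * sqrt(|r|) * g + sqrt(1 - |r|) * e_j

with g, e_i, e_j independent standard normal series, so both channels keep
unit variance and corr(x_i, x_j) = r.  All non-planted ROIs are independent
standard normal noise.

Default effect size
-------------------
``DEFAULT_SEVERITY_SLOPE`` is chosen so that, at the default 200 timepoints,
the population correlation between a planted edge's Fisher-z value and the
severity score is about 0.33.  Edge-level severity correlations reported for
this kind of analysis concentrate in the 0.23-0.33 band, and planted edges
emulate the *selected* (i.e. detectable) end of that band: with severity
uniform on 1..10 (sd 2.87) and sampling noise sd 1/sqrt(T-3) on z, a slope
of 0.0085 per severity unit gives corr(z, s) ~ 0.33, which a p < 0.0023
filter at n ~ 150 recovers with high power.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import features
from .calibration import CalibrationTable, synthetic_calibration_table

DEFAULT_SEVERITY_SLOPE = 0.0085
DEFAULT_BASE_CORRELATION = 0.1

SITES = ("NYU", "UCLA_1", "USM")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``severity_slope`` may be a single float (applied to every planted edge)
    or a sequence with one slope per planted edge; the sign of each slope is
    the planted sign of that edge.  ``noise_sd`` adds independent
    measurement noise to every channel; series are rescaled to keep unit
    variance, which attenuates planted correlations by 1/(1 + noise_sd**2).
    """

    n_subjects: int
    n_rois: int = 116
    n_timepoints: int = 200
    planted_edges: tuple = ()
    base_correlation: float = DEFAULT_BASE_CORRELATION
    severity_slope: object = DEFAULT_SEVERITY_SLOPE
    noise_sd: float = 0.0
    severity_range: tuple = (1, 10)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "planted_edges",
                           tuple((int(i), int(j)) for i, j in self.planted_edges))
        if np.ndim(self.severity_slope) > 0:
            object.__setattr__(self, "severity_slope",
                               tuple(float(s) for s in self.severity_slope))

    @property
    def slopes(self) -> np.ndarray:
        """Per-edge slope array (broadcast if a scalar was given)."""
        if np.ndim(self.severity_slope) == 0:
            return np.full(len(self.planted_edges), float(self.severity_slope))
        return np.asarray(self.severity_slope, dtype=float)

    @property
    def severity_midpoint(self) -> float:
        lo, hi = self.severity_range
        return (lo + hi) / 2.0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_timepoints < 30:
            raise ValueError(f"n_timepoints must be >= 30, got {self.n_timepoints}")
        lo, hi = self.severity_range
        if not (lo < hi):
            raise ValueError("severity_range must be an increasing integer interval")
        used = set()
        for (i, j) in self.planted_edges:
            if not (1 <= i < j <= self.n_rois):
                raise ValueError(f"planted edge ({i}, {j}) is not 1-based with i < j <= n_rois")
            if i in used or j in used:
                raise ValueError(f"planted edges must be ROI-disjoint; ROI reused in ({i}, {j})")
            used.update((i, j))
        slopes = self.slopes
        if len(self.planted_edges) and slopes.shape[0] != len(self.planted_edges):
            raise ValueError("severity_slope sequence length must match planted_edges")
        max_dev = max(abs(lo - self.severity_midpoint), abs(hi - self.severity_midpoint))
        if len(self.planted_edges):
            worst = np.abs(self.base_correlation) + np.abs(slopes) * max_dev
            if np.any(worst > 0.95):
                raise ValueError(
                    f"target |r| reaches {worst.max():.3f} > 0.95 at extreme severity; "
                    "reduce base_correlation or severity_slope"
                )


@dataclass
class SubjectRecord:
    """One synthetic subject: ROI time series plus phenotype fields."""

    subject_id: str
    timeseries: np.ndarray  # (timepoints, n_rois)
    severity: int


@dataclass
class GroundTruth:
    """What was planted: true severities, canonical edge ids, signs."""

    spec: CohortSpec
    true_scores: np.ndarray
    planted_edge_ids: np.ndarray
    planted_signs: np.ndarray


def generate_cohort(spec: CohortSpec):
    """Generate a cohort of ROI time series with planted severity structure.

    Returns ``(subjects, truth)``; reproducible bit-for-bit given
    ``spec.seed``.  Specs whose target |r(s)| would reach 1 are rejected.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.severity_range
    severities = rng.integers(lo, hi + 1, size=spec.n_subjects)
    slopes = spec.slopes
    s_mid = spec.severity_midpoint
    T, R = spec.n_timepoints, spec.n_rois

    subjects = []
    for k, s in enumerate(severities):
        X = rng.standard_normal((T, R))
        for (i, j), slope in zip(spec.planted_edges, slopes):
            r = spec.base_correlation + slope * (s - s_mid)
            if abs(r) >= 1:
                raise ValueError(f"target |r| >= 1 for edge ({i}, {j}) at severity {s}")
            rho = abs(r)
            g = rng.standard_normal(T)
            X[:, i - 1] = np.sqrt(rho) * g + np.sqrt(1 - rho) * X[:, i - 1]
            X[:, j - 1] = np.sign(r) * np.sqrt(rho) * g + np.sqrt(1 - rho) * X[:, j - 1]
        if spec.noise_sd > 0:
            X = (X + spec.noise_sd * rng.standard_normal((T, R))) / np.sqrt(1 + spec.noise_sd**2)
        subjects.append(SubjectRecord(f"sub-{k + 1:04d}", X, int(s)))

    edge_ids = np.array(
        [features.edge_id(i, j, spec.n_rois) for i, j in spec.planted_edges], dtype=int
    )
    signs = np.sign(slopes).astype(int)
    truth = GroundTruth(spec, severities.astype(int), edge_ids, signs)
    return subjects, truth


def default_planted_edges():
    """Ten ROI-disjoint pairs within a 116-ROI atlas, used by demos."""
    return ((1, 5), (7, 12), (17, 23), (31, 40), (47, 57),
            (66, 70), (73, 79), (82, 86), (90, 107), (100, 112))


def default_planted_slopes(n_edges: int = 10, magnitude: float = DEFAULT_SEVERITY_SLOPE):
    """Half positive, half negative slopes of the default magnitude."""
    half = n_edges // 2
    return tuple([magnitude] * (n_edges - half) + [-magnitude] * half)


def study_spec(n_subjects: int = 150, seed: int = 0, n_timepoints: int = 200) -> CohortSpec:
    """The default study-scale cohort: 116 ROIs, 10 mixed-sign planted edges."""
    edges = default_planted_edges()
    return CohortSpec(
        n_subjects=n_subjects,
        n_timepoints=n_timepoints,
        planted_edges=edges,
        severity_slope=default_planted_slopes(len(edges)),
        seed=seed,
    )


def null_spec(n_subjects: int = 100, seed: int = 0, n_timepoints: int = 200) -> CohortSpec:
    """Zero-slope cohort: planted edges exist but carry no severity signal."""
    edges = default_planted_edges()
    return CohortSpec(
        n_subjects=n_subjects,
        n_timepoints=n_timepoints,
        planted_edges=edges,
        severity_slope=tuple([0.0] * len(edges)),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Phenotypes


def generate_phenotypes(
    n_subjects: int,
    seed: int,
    scores=None,
    table: CalibrationTable | None = None,
) -> pd.DataFrame:
    """Generate a phenotype table (subject_id, ados_total, module, age, site).

    With ``scores`` given (one severity per subject), module, age and ADOS
    total are drawn from a calibration-table cell that maps back to exactly
    that score, so scoring the returned table recovers ``scores``; otherwise
    ADOS totals are drawn from a plausible 0-28 distribution.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    table = table if table is not None else synthetic_calibration_table()
    df = table.frame
    rows = []
    for k in range(n_subjects):
        if scores is not None:
            cell = df[df["css"] == int(scores[k])]
            if cell.empty:
                raise ValueError(f"no calibration row with css={scores[k]}")
            row = cell.iloc[rng.integers(len(cell))]
            ados = int(rng.integers(row["raw_min"], row["raw_max"] + 1))
        else:
            row = df.iloc[rng.integers(len(df))]
            ados = int(np.clip(np.round(rng.normal(11.7, 3.9)), row["raw_min"], row["raw_max"]))
        age = float(np.round(rng.uniform(row["age_min"], row["age_max"]), 1))
        rows.append({
            "subject_id": f"sub-{k + 1:04d}",
            "ados_total": ados,
            "module": int(row["module"]),
            "age": age,
            "site": SITES[rng.integers(len(SITES))],
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Labeled-volume fixture for the ROI-averaging test path


def generate_labeled_volume(
    n_rois: int,
    voxels_per_roi: int,
    timeseries: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Build a (4-D volume, integer label volume) pair from ROI series.

    Every voxel labeled k carries ROI k's series plus independent Gaussian
    noise; one background column of zeros carries label 0.  ROI-mean
    extraction recovers ``timeseries`` exactly when ``noise_sd`` is 0 and
    converges to it as ``voxels_per_roi`` grows.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[1] != n_rois:
        raise ValueError(f"timeseries must have {n_rois} columns, got {ts.shape}")
    if voxels_per_roi < 1:
        raise ValueError("voxels_per_roi must be >= 1")
    rng = np.random.default_rng(seed)
    T = ts.shape[0]
    vol = np.zeros((n_rois, voxels_per_roi + 1, 1, T))
    labels = np.zeros((n_rois, voxels_per_roi + 1, 1), dtype=np.int16)
    for k in range(n_rois):
        noise = noise_sd * rng.standard_normal((voxels_per_roi, T)) if noise_sd > 0 else 0.0
        vol[k, :voxels_per_roi, 0, :] = ts[:, k][None, :] + noise
        labels[k, :voxels_per_roi, 0] = k + 1
    return vol, labels


# ---------------------------------------------------------------------------
# Serialization


def write_cohort(outdir, subjects, truth: GroundTruth) -> None:
    """Write per-subject TSV time series and the ground truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = [str(k + 1) for k in range(truth.spec.n_rois)]
    for sub in subjects:
        pd.DataFrame(sub.timeseries, columns=header).to_csv(
            outdir / f"{sub.subject_id}.tsv", sep="\t", index=False
        )
    write_ground_truth(outdir / "ground_truth.json", truth)


def write_ground_truth(path, truth: GroundTruth) -> None:
    payload = {
        "spec": asdict(truth.spec),
        "true_scores": truth.true_scores.tolist(),
        "planted_edge_ids": truth.planted_edge_ids.tolist(),
        "planted_signs": truth.planted_signs.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    spec_d = dict(payload["spec"])
    spec_d["planted_edges"] = tuple(tuple(e) for e in spec_d["planted_edges"])
    if isinstance(spec_d["severity_slope"], list):
        spec_d["severity_slope"] = tuple(spec_d["severity_slope"])
    spec_d["severity_range"] = tuple(spec_d["severity_range"])
    return GroundTruth(
        CohortSpec(**spec_d),
        np.asarray(payload["true_scores"], dtype=int),
        np.asarray(payload["planted_edge_ids"], dtype=int),
        np.asarray(payload["planted_signs"], dtype=int),
    )


def read_cohort_timeseries(indir):
    """Read per-subject TSVs from a directory; returns (ids, list of arrays)."""
    indir = Path(indir)
    paths = sorted(p for p in indir.glob("*.tsv"))
    ids = [p.stem for p in paths]
    series = [pd.read_csv(p, sep="\t").to_numpy(dtype=float) for p in paths]
    return ids, series


def write_nifti_pair(path4d, path_labels, vol4d, labels) -> None:
    """Write the labeled-volume fixture as a NIfTI pair."""
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(vol4d, dtype=np.float32), np.eye(4)), str(path4d))
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16), np.eye(4)), str(path_labels))


def read_nifti_pair(path4d, path_labels):
    import nibabel as nib

    vol = np.asarray(nib.load(str(path4d)).dataobj, dtype=float)
    labels = np.asarray(nib.load(str(path_labels)).dataobj).astype(int)
    return vol, labels
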