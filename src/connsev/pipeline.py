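"""End-to-end orchestration: scores -> features -> CV -> reports.

A single declarative config (YAML or dict) drives the whole pipeline:
severity scoring (calibration lookup or precomputed scores), edge-feature
extraction (time-series directory, NIfTI pair, or a precomputed edge
matrix), cross-validation with fold-wise selection, metrics, and the
contribution reports.  Every random draw flows from the master seed, the
effective config is echoed into a run manifest together with SHA-256
hashes of all outputs, and rerunning the same config reproduces the
outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, calibration, evaluation, features, selection, svr, synthetic

log = logging.getLogger(__name__)

INPUT_MODES = ("demo", "timeseries", "nifti", "edges")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class ValidationReport:
    fatals: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatals


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration; exactly one input mode."""

    output_dir: str = "connsev_run"
    input_mode: str = "demo"
    # input paths (mode-dependent)
    timeseries_dir: str | None = None
    nifti_4d: str | None = None
    nifti_labels: str | None = None
    edges_tsv: str | None = None
    annotation_path: str | None = None   # None -> packaged AAL-116
    phenotype_path: str | None = None
    calibration_path: str | None = None  # None -> packaged synthetic table
    scores_path: str | None = None       # precomputed subject_id,css CSV
    # demo-mode cohort size
    demo_n_subjects: int = 150
    demo_n_timepoints: int = 200
    demo_n_rois: int = 116
    # selection
    threshold: float | None = selection.DEFAULT_THRESHOLD
    threshold_search: str | None = None  # None | 'stage1' | 'stage2'
    # SVR
    svr_c: float = 1.0
    svr_epsilon: float = 0.1
    # CV
    cv_kind: str = "loocv"
    cv_k: int = 10
    cv_repeats: int = 10
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Check path existence, subject alignment and table integrity.

    Returns a report distinguishing fatals from warnings; never raises.
    """
    rep = ValidationReport()
    if config.input_mode not in INPUT_MODES:
        rep.fatals.append(f"unknown input_mode {config.input_mode!r}")
        return rep
    mode_paths = {
        "timeseries": [("timeseries_dir", config.timeseries_dir)],
        "nifti": [("nifti_4d", config.nifti_4d), ("nifti_labels", config.nifti_labels)],
        "edges": [("edges_tsv", config.edges_tsv)],
        "demo": [],
    }[config.input_mode]
    for name, p in mode_paths:
        if p is None:
            rep.fatals.append(f"input_mode {config.input_mode!r} requires {name}")
        elif not Path(p).exists():
            rep.fatals.append(f"{name} does not exist: {p}")

    try:
        ann = features.load_annotation(config.annotation_path)
        if config.annotation_path is None and len(ann) != 116:
            rep.fatals.append("packaged annotation must have 116 rows")
    except (ValueError, FileNotFoundError) as exc:
        rep.fatals.append(f"annotation: {exc}")
        ann = None

    if config.scores_path is not None:
        if not Path(config.scores_path).exists():
            rep.fatals.append(f"scores_path does not exist: {config.scores_path}")
    elif config.input_mode != "demo":
        if config.phenotype_path is None:
            rep.fatals.append("need phenotype_path (or scores_path) outside demo mode")
        elif not Path(config.phenotype_path).exists():
            rep.fatals.append(f"phenotype_path does not exist: {config.phenotype_path}")
    if config.calibration_path is not None:
        try:
            calibration.load_calibration_table(config.calibration_path)
        except (calibration.CalibrationError, FileNotFoundError) as exc:
            rep.fatals.append(f"calibration table: {exc}")

    # Subject alignment between time series and phenotypes.
    if (config.input_mode == "timeseries" and config.timeseries_dir
            and Path(config.timeseries_dir).is_dir()
            and config.phenotype_path and Path(config.phenotype_path).exists()):
        ts_ids = {p.stem for p in Path(config.timeseries_dir).glob("*.tsv")}
        pheno = pd.read_csv(config.phenotype_path)
        if "subject_id" in pheno.columns:
            for sid in pheno["subject_id"].astype(str):
                if sid not in ts_ids:
                    rep.fatals.append(f"subject {sid} in phenotypes but no time series file")
            extra = ts_ids - set(pheno["subject_id"].astype(str))
            if extra:
                rep.warnings.append(
                    f"{len(extra)} time-series file(s) without phenotype rows: "
                    f"{sorted(extra)[:5]}"
                )
        else:
            rep.fatals.append("phenotype table has no subject_id column")

    if config.threshold is None and config.threshold_search is None:
        rep.fatals.append("set either threshold or threshold_search")
    if config.threshold_search not in (None, "stage1", "stage2"):
        rep.fatals.append(f"unknown threshold_search {config.threshold_search!r}")
    if config.cv_kind not in ("loocv", "kfold"):
        rep.fatals.append(f"unknown cv_kind {config.cv_kind!r}")
    return rep


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_scores(config: PipelineConfig, outdir: Path, demo=None):
    """Observed severity scores per subject (subject_id -> css)."""
    if config.scores_path is not None:
        df = pd.read_csv(config.scores_path)
        return df["subject_id"].astype(str).tolist(), df["css"].to_numpy(float), []
    table = (calibration.load_calibration_table(config.calibration_path)
             if config.calibration_path is not None
             else calibration.synthetic_calibration_table())
    if config.input_mode == "demo":
        pheno = demo["phenotypes"]
    else:
        pheno = pd.read_csv(config.phenotype_path)
    scores, exclusions = calibration.score_cohort(pheno, table)
    scores.to_csv(outdir / "scores.csv", index=False)
    if exclusions:
        log.warning("excluded %d uncalibratable subject(s)", len(exclusions))
    return scores["subject_id"].tolist(), scores["css"].to_numpy(float), exclusions


def _stage_features(config: PipelineConfig, ids, outdir: Path, demo=None):
    """Subjects x edges Fisher-z matrix aligned with the score order."""
    if config.input_mode == "edges":
        e_ids, X, _ = features.read_edge_matrix(config.edges_tsv)
        order = {sid: k for k, sid in enumerate(e_ids)}
        missing = [sid for sid in ids if sid not in order]
        if missing:
            raise ValueError(f"edge matrix missing subjects: {missing[:5]}")
        return X[[order[sid] for sid in ids]]
    if config.input_mode == "demo":
        series = {s.subject_id: s.timeseries for s in demo["subjects"]}
        X = features.cohort_edge_matrix([series[sid] for sid in ids])
    elif config.input_mode == "timeseries":
        ts_ids, series = synthetic.read_cohort_timeseries(config.timeseries_dir)
        lookup = dict(zip(ts_ids, series))
        X = features.cohort_edge_matrix([lookup[sid] for sid in ids])
    else:  # nifti
        vol, labels = synthetic.read_nifti_pair(config.nifti_4d, config.nifti_labels)
        n_rois = int(labels.max())
        ts = features.roi_mean_timeseries(vol, labels, n_rois)
        X = features.subject_edge_vector(ts)[None, :]
        if len(ids) != 1:
            raise ValueError("nifti mode handles a single subject volume")
    features.write_edge_matrix(outdir / "edge_matrix.tsv", X, ids)
    n_rois = int(round((1 + np.sqrt(1 + 8 * X.shape[1])) / 2))
    features.write_pair_index(outdir / "pair_index.csv", features.canonical_pairs(n_rois))
    # analyze exactly what was serialized, so a rerun from the written edge
    # matrix reproduces this run bit for bit
    return features.read_edge_matrix(outdir / "edge_matrix.tsv")[1]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write artifacts + manifest; returns the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    report = validate_inputs(config)
    if not report.ok:
        raise PipelineError("validate", "; ".join(report.fatals))
    for w in report.warnings:
        log.warning(w)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = features.load_annotation(config.annotation_path)

    demo = None
    if config.input_mode == "demo":
        spec = synthetic.study_spec(config.demo_n_subjects, seed=config.seed,
                                    n_timepoints=config.demo_n_timepoints)
        if config.demo_n_rois != spec.n_rois:
            raise PipelineError("simulate", "demo mode uses the 116-ROI atlas")
        subjects, truth = synthetic.generate_cohort(spec)
        pheno = synthetic.generate_phenotypes(
            spec.n_subjects, seed=config.seed + 1, scores=truth.true_scores
        )
        pheno.to_csv(outdir / "phenotypes.csv", index=False)
        synthetic.write_ground_truth(outdir / "ground_truth.json", truth)
        demo = {"subjects": subjects, "truth": truth, "phenotypes": pheno}

    try:
        ids, y, exclusions = _stage_scores(config, outdir, demo)
    except Exception as exc:
        raise PipelineError("scores", str(exc)) from exc
    if len(ids) < 10:
        raise PipelineError("scores", f"only {len(ids)} calibratable subjects")

    try:
        X = _stage_features(config, ids, outdir, demo)
    except Exception as exc:
        raise PipelineError("features", str(exc)) from exc
    if X.shape[1] != features.n_edges(len(annotation)):
        raise PipelineError(
            "features",
            f"{X.shape[1]} edges does not match the {len(annotation)}-ROI annotation",
        )

    scheme = (evaluation.CvScheme("loocv") if config.cv_kind == "loocv"
              else evaluation.CvScheme("kfold", k=config.cv_k,
                                       repeats=config.cv_repeats, seed=config.seed))
    svr_config = svr.SvrConfig(C=config.svr_c, epsilon=config.svr_epsilon)

    try:
        search = None
        if config.threshold_search == "stage2":
            search = selection.stage2_threshold_search(X, y, cv_scheme=scheme,
                                                       svr_config=svr_config)
            threshold = search.chosen
        elif config.threshold_search == "stage1":
            search = selection.stage1_threshold_search(X, y, svr_config=svr_config)
            threshold = search.chosen
        else:
            threshold = float(config.threshold)
        run = evaluation.run_cv(X, y, scheme=scheme, threshold=threshold,
                                svr_config=svr_config)
    except Exception as exc:
        raise PipelineError("cv", str(exc)) from exc

    m = evaluation.cv_metrics(run, y)
    contribs = evaluation.edge_contributions(run)
    full_r = selection.score_edges(X, y).r
    signs = np.sign(full_r)
    pair_index = features.canonical_pairs(len(annotation))
    edge_ann = features.annotate_edges(pair_index, annotation)

    # predictions
    if scheme.kind == "loocv":
        pred_df = pd.DataFrame({"subject_id": ids, "observed": y,
                                "estimated": run.predictions})
    else:
        rows = []
        for rep in range(run.predictions.shape[0]):
            for k, sid in enumerate(ids):
                rows.append({"subject_id": sid, "repeat": rep, "observed": y[k],
                             "estimated": run.predictions[rep, k]})
        pred_df = pd.DataFrame(rows)
    pred_df.to_csv(outdir / "predictions.csv", index=False, float_format="%.6f")

    (outdir / "metrics.json").write_text(json.dumps(m, indent=2))
    edges_df, rois_df = evaluation.report_tables(run, X, y, annotation)
    edges_df.to_csv(outdir / "edges.csv", index=False, float_format="%.6f")
    rois_df.to_csv(outdir / "rois.csv", index=False, float_format="%.6f")
    for scheme_name, df in evaluation.all_division_summaries(contribs, signs,
                                                             edge_ann).items():
        df.to_csv(outdir / f"divisions_{scheme_name}.csv", index=False,
                  float_format="%.6f")
    evaluation.fold_selection_table(run, full_r).to_csv(
        outdir / "selected_edges_per_fold.csv", index=False, float_format="%.6f")

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "seed": config.seed,
        "n_subjects": len(ids),
        "n_edges": int(X.shape[1]),
        "threshold": threshold,
        "threshold_search": None if search is None else {
            "stage": search.stage, "criterion": search.criterion_name,
            "chosen": search.chosen,
        },
        "per_fold_selected_counts": [int(fr.mask.sum()) for fr in run.folds],
        "excluded_subjects": [sid for sid, _ in exclusions],
        "metrics": m,
        "outputs": {},
    }
    for p in sorted(outdir.glob("*")):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("run complete: R=%.3f MAE=%.3f, %d folds", m["R"], m["MAE"], run.n_folds)
    return manifest
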