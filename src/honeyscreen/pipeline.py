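"""End-to-end scenario processing: runs -> feature matrices -> reports.

This is the orchestration layer the command-line interface, the
examples and the acceptance analyses share. Each sample is processed
independently (render or read, detect peaks, bucketize, TIC-normalize)
and only then assembled into labeled matrices — so adding one new
sample to a stored matrix never requires reprocessing old ones, which
is the routine-laboratory requirement the fixed-grid scheme exists for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bucketing import BucketGrid, EmptyRunError, FeatureVector, build_grid, bucketize, normalize_tic
from .cohort import CohortDesign, iter_runs
from .fusion import AnalysisMatrix, SampleLabel, assemble_matrix, split_by_honey
from .models import (
    ADULTERATED,
    PURE,
    ModelReport,
    RfConfig,
    class_weights,
    evaluate_regression,
    pca_scores,
    predict_classes,
    train_classifier,
    train_regressor,
)
from .peaks import PeakParams, detect_all
from .spectra_io import CANONICAL_WINDOWS, LcmsRun

__all__ = [
    "default_grid",
    "process_run",
    "ScenarioData",
    "process_scenario",
    "ScenarioReport",
    "analyze_scenario",
]


def default_grid(design: CohortDesign, mode: str, fragments: bool = False) -> BucketGrid:
    """The mode's fixed bucket grid (20 s x 2 Da) from the design's spans."""
    layers: list = [(1, None)]
    if fragments:
        layers += [(2, w) for w in CANONICAL_WINDOWS]
    return build_grid(
        mz_range=design.mz_range,
        mz_width=2.0,
        rt_range=design.rt_span[mode],
        rt_width=20.0,
        layers=layers,
    )


def process_run(
    run: LcmsRun, grid: BucketGrid, params: PeakParams = PeakParams(), normalize: bool = True
) -> FeatureVector:
    """One run -> detected peaks -> bucket vector (TIC-normalized by default)."""
    peaks = detect_all(run, params)
    fv = bucketize(peaks, grid)
    return normalize_tic(fv) if normalize else fv


@dataclass
class ScenarioData:
    """Processed matrices of one syrup scenario."""

    syrup: str
    matrices: dict[str, AnalysisMatrix]  # per-mode blocks plus "fused"
    dropped: list[str] = field(default_factory=list)  # signal-free samples

    def matrix(self, variant: str = "fused") -> AnalysisMatrix:
        return self.matrices[variant]


def process_scenario(
    design: CohortDesign,
    syrup: str,
    peak_params: PeakParams = PeakParams(),
    fragments: bool = False,
    noise: bool = True,
) -> ScenarioData:
    """Simulate and process one syrup scenario into analysis matrices.

    Every sample is rendered in both modes, peak-detected and
    bucketized independently; samples with a signal-free block are
    dropped (and listed), mirroring how an injection failure is handled
    in a real cohort. Produces one matrix per mode and the low-level
    fused matrix (blocks normalized, then concatenated mode-major).
    """
    grids = {mode: default_grid(design, mode, fragments) for mode in design.modes}
    per_sample: dict[str, dict[str, FeatureVector]] = {}
    labels: dict[str, SampleLabel] = {}
    dropped: list[str] = []
    for row, run in iter_runs(design, syrup, noise=noise):
        sid = row["sample_id"]
        if sid in dropped:
            continue
        try:
            fv = process_run(run, grids[run.mode], peak_params)
        except EmptyRunError:
            dropped.append(sid)
            per_sample.pop(sid, None)
            continue
        per_sample.setdefault(sid, {})[run.mode] = fv
        labels[sid] = SampleLabel(
            honey_id=row["honey_id"],
            syrup=row["syrup"],
            proportion=row["proportion_pct"],
            device_id=row["device_id"],
        )
    complete = {
        sid: blocks for sid, blocks in per_sample.items() if len(blocks) == len(design.modes)
    }
    matrices = {
        mode: assemble_matrix(complete, labels, order=[mode]) for mode in design.modes
    }
    matrices["fused"] = assemble_matrix(complete, labels, order=list(design.modes))
    return ScenarioData(syrup=syrup, matrices=matrices, dropped=dropped)


@dataclass
class ScenarioReport:
    """Classification, regression and PCA summaries of one scenario."""

    syrup: str
    variant: str
    n_train: int
    n_test: int
    test_honeys: list[str]
    classification: ModelReport
    regression: ModelReport
    pca: pd.DataFrame | None = None
    pca_explained: np.ndarray | None = None
    silhouette_device: float | None = None
    silhouette_proportion: float | None = None

    def to_dict(self) -> dict:
        c, r = self.classification, self.regression
        return {
            "syrup": self.syrup,
            "variant": self.variant,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "test_honeys": list(self.test_honeys),
            "classification": {
                "oob_error_pct": c.oob_error,
                "test_accuracy_pct": c.test_accuracy,
                "per_level_correct": {
                    f"{k:g}": list(v) for k, v in (c.per_level_confusion or {}).items()
                },
            },
            "regression": {
                "r_squared": r.r_squared,
                "r_squared_ss": r.r_squared_ss,
                "rmse_pct": r.rmse,
                "per_level_mae_pct": {f"{k:g}": v for k, v in (r.per_level_mae or {}).items()},
            },
            "pca": {
                "explained_variance_ratio": None
                if self.pca_explained is None
                else [float(x) for x in self.pca_explained],
                "silhouette_device": self.silhouette_device,
                "silhouette_proportion": self.silhouette_proportion,
            },
        }


def analyze_scenario(
    data: ScenarioData,
    variant: str = "fused",
    n_test_honeys: int = 9,
    split_seed: int = 0,
    rf: RfConfig = RfConfig(),
    with_pca: bool = True,
) -> ScenarioReport:
    """Honey-level split, forest training and evaluation for one scenario.

    Classification: class-weighted forest of pure vs adulterated, OOB
    error on the training honeys, accuracy and per-level tally on the
    held-out honeys. Regression: syrup proportion (percent v/v) with
    R^2 (squared Pearson), RMSE and per-level MAE on the test set. PCA
    (on the full matrix) adds device/proportion silhouettes on the
    first two components.
    """
    mat = data.matrix(variant)
    train_ids, test_ids = split_by_honey(mat.labels, n_test_honeys, seed=split_seed)
    train, test = mat.subset(train_ids), mat.subset(test_ids)

    y_train = np.where(train.labels["proportion_pct"] > 0, ADULTERATED, PURE)
    clf, clf_report = train_classifier(train.X, y_train, cfg=rf)
    if len(test_ids):
        y_pred, tally = predict_classes(clf, test.X, test.labels["proportion_pct"])
        y_true = np.where(test.labels["proportion_pct"] > 0, ADULTERATED, PURE)
        clf_report.test_accuracy = 100.0 * float(np.mean(y_pred == y_true))
        clf_report.per_level_confusion = tally

    reg = train_regressor(train.X, train.labels["proportion_pct"], cfg=rf)
    reg_report = (
        evaluate_regression(reg, test.X, test.labels["proportion_pct"])
        if len(test_ids)
        else ModelReport()
    )

    scores = explained = sil_dev = sil_prop = None
    if with_pca:
        from sklearn.metrics import silhouette_score

        scores, explained = pca_scores(mat.X, n_components=2)
        if mat.labels["device_id"].nunique() > 1:
            sil_dev = float(silhouette_score(scores.values, mat.labels["device_id"]))
        if mat.labels["proportion_pct"].nunique() > 1:
            sil_prop = float(silhouette_score(scores.values, mat.labels["proportion_pct"]))
        scores = scores.assign(
            device=mat.labels["device_id"], proportion=mat.labels["proportion_pct"]
        )

    return ScenarioReport(
        syrup=data.syrup,
        variant=variant,
        n_train=len(train_ids),
        n_test=len(test_ids),
        test_honeys=sorted(test.labels["honey_id"].unique()) if len(test_ids) else [],
        classification=clf_report,
        regression=reg_report,
        pca=scores,
        pca_explained=explained,
        silhouette_device=sil_dev,
        silhouette_proportion=sil_prop,
    )
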