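"""ROC calibration of the QF threshold and quality-gated classification.

Two experiments:

* ``roc_quality`` sweeps the QF decision threshold from 0 to the dataset
  maximum against the reviewer-based ground truth (qS >= 7 is "high
  quality") and reports sensitivity/specificity per threshold, the AUC and
  the Youden-optimal operating point.

* ``train_gated_classifier`` measures how a quality gate changes tissue
  classification (normal vs cancer): measurements with QF above the gate
  are kept, SNV spectra are the features, an L1-regularized linear SVM
  selects informative bins, and a linear SVM (C grid-searched inside the
  training folds) is scored by patient-grouped cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import SelectFromModel
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedGroupKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .io import read_manifest, read_response, read_spectrum
from .preprocess import RollingBallConfig, preprocess_pipeline
from .quality import QfConfig, compute_qf
from .spectra import QualityRecord, SpectrumValidationError

__all__ = [
    "RocCurve",
    "ClassificationReport",
    "QualityDataset",
    "process_dataset",
    "roc_quality",
    "train_gated_classifier",
    "compare_gating",
    "DEFAULT_C_GRID",
]

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
QS_HIGH_QUALITY = 7


@dataclass(frozen=True, eq=False)
class RocCurve:
    """QF-threshold ROC: sensitivity/specificity per threshold, AUC, optimum."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_threshold: float
    optimal_sensitivity: float
    optimal_specificity: float

    @property
    def optimal_point(self) -> tuple[float, float, float]:
        return (self.optimal_threshold, self.optimal_sensitivity, self.optimal_specificity)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        })


@dataclass(frozen=True, eq=False)
class ClassificationReport:
    """Cross-validated tissue-classification metrics under a QF gate."""

    qf_gate: float
    n_used: int
    fold_accuracy: np.ndarray
    fold_sensitivity: np.ndarray
    fold_specificity: np.ndarray
    fold_balanced_accuracy: np.ndarray

    @property
    def accuracy(self) -> float:
        return float(self.fold_accuracy.mean())

    @property
    def sensitivity(self) -> float:
        return float(self.fold_sensitivity.mean())

    @property
    def specificity(self) -> float:
        return float(self.fold_specificity.mean())

    @property
    def balanced_accuracy(self) -> float:
        return float(self.fold_balanced_accuracy.mean())

    def fold_std(self, metric: str = "accuracy") -> float:
        arr = getattr(self, f"fold_{metric}")
        return float(arr.std(ddof=1)) if arr.size > 1 else 0.0

    def summary(self) -> dict[str, float]:
        return {
            "qf_gate": self.qf_gate,
            "n_used": self.n_used,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "accuracy_fold_std": self.fold_std("accuracy"),
            "sensitivity_fold_std": self.fold_std("sensitivity"),
            "specificity_fold_std": self.fold_std("specificity"),
        }


@dataclass(eq=False)
class QualityDataset:
    """A fully preprocessed dataset: QF values, qS labels and SNV features."""

    records: list[QualityRecord]
    features: np.ndarray           # SNV spectra, one row per measurement
    qf: np.ndarray
    qs: np.ndarray
    pathology: np.ndarray
    patient_id: np.ndarray
    measurement_id: np.ndarray

    def __len__(self) -> int:
        return len(self.records)


def process_dataset(
    dataset_dir: str | Path,
    rb_cfg: RollingBallConfig | None = None,
    qf_cfg: QfConfig | None = None,
) -> QualityDataset:
    """Preprocess every manifest entry of an on-disk dataset and compute QF."""
    dataset_dir = Path(dataset_dir)
    manifest = read_manifest(dataset_dir / "manifest.tsv")
    dark = read_spectrum(dataset_dir / "dark.tsv")
    response = read_response(dataset_dir / "response.tsv")
    qf_cfg = qf_cfg or QfConfig()
    records: list[QualityRecord] = []
    rows = []
    for row in manifest.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = dataset_dir / p
        raw = read_spectrum(p)
        decomposed, processed = preprocess_pipeline(raw, dark, response, rb_cfg)
        qf = compute_qf(decomposed, qf_cfg)
        qs = int(row.qs) if hasattr(row, "qs") and pd.notna(row.qs) else None
        pathology = row.pathology if hasattr(row, "pathology") and pd.notna(row.pathology) else None
        records.append(QualityRecord(str(row.measurement_id), qf, qs, pathology))
        rows.append((processed.intensity, qf, qs if qs is not None else -1,
                     pathology or "", getattr(row, "patient_id", ""), str(row.measurement_id)))
    features = np.vstack([r[0] for r in rows])
    return QualityDataset(
        records=records,
        features=features,
        qf=np.array([r[1] for r in rows]),
        qs=np.array([r[2] for r in rows]),
        pathology=np.array([r[3] for r in rows]),
        patient_id=np.array([str(r[4]) for r in rows]),
        measurement_id=np.array([r[5] for r in rows]),
    )


def roc_quality(
    records: Sequence[QualityRecord],
    qs_threshold: int = QS_HIGH_QUALITY,
) -> RocCurve:
    """ROC of the QF against reviewer quality (qS >= qs_threshold = high).

    Thresholds sweep 0 and every distinct QF value up to the dataset
    maximum; a spectrum is called high quality when QF strictly exceeds
    the threshold.  The optimal point maximizes Youden's J = sensitivity +
    specificity - 1, ties broken toward higher specificity.
    """
    qf = np.array([r.qf for r in records], dtype=float)
    qs = np.array([r.qs for r in records])
    if any(r.qs is None for r in records):
        raise SpectrumValidationError("every record needs a qS score for ROC calibration")
    truth = qs >= qs_threshold
    if truth.all() or not truth.any():
        raise SpectrumValidationError("ROC needs both high- and low-quality spectra")
    thresholds = np.unique(np.concatenate([[0.0], np.unique(qf)]))
    pred = qf[None, :] > thresholds[:, None]
    sens = (pred & truth).sum(axis=1) / truth.sum()
    spec = (~pred & ~truth).sum(axis=1) / (~truth).sum()
    auc = float(roc_auc_score(truth, qf))
    j = sens + spec - 1.0
    best = np.flatnonzero(j == j.max())[-1]  # last index = largest threshold = highest specificity
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        optimal_threshold=float(thresholds[best]),
        optimal_sensitivity=float(sens[best]),
        optimal_specificity=float(spec[best]),
    )


def _binary_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float, float]:
    tp = np.sum(y_pred & y_true)
    tn = np.sum(~y_pred & ~y_true)
    fp = np.sum(y_pred & ~y_true)
    fn = np.sum(~y_pred & y_true)
    acc = (tp + tn) / y_true.size
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    bal = np.nanmean([sens, spec])
    return float(acc), float(sens), float(spec), float(bal)


def _make_pipeline(c_select: float = 0.1) -> Pipeline:
    selector = SelectFromModel(
        LinearSVC(penalty="l1", dual=False, C=c_select, max_iter=5000), threshold=1e-8
    )
    clf = LinearSVC(dual=False, max_iter=5000)
    return Pipeline([
        ("scale", StandardScaler()),
        ("select", selector),
        ("clf", clf),
    ])


def train_gated_classifier(
    dataset: QualityDataset | str | Path,
    qf_gate: float = 0.0,
    folds: int = 5,
    seed: int = 0,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
) -> ClassificationReport:
    """Cross-validated normal-vs-cancer classification under a QF gate.

    Measurements with QF strictly above the gate (and a normal/cancer
    label — infiltrated tissue is excluded) feed a pipeline of L1-based
    feature selection and a linear SVM whose C is grid-searched on the
    training folds; folds are grouped by patient so co-located spectra
    never straddle a train/test split.
    """
    if not isinstance(dataset, QualityDataset):
        dataset = process_dataset(dataset)
    keep = (dataset.qf > qf_gate) & np.isin(dataset.pathology, ["normal", "cancer"])
    n_used = int(keep.sum())
    y = dataset.pathology[keep] == "cancer"
    if n_used < 2 * folds or len(np.unique(y)) < 2:
        raise SpectrumValidationError(
            f"gate {qf_gate} leaves {n_used} usable measurements "
            f"({np.sum(y)} cancer): too few for {folds}-fold cross-validation"
        )
    X = dataset.features[keep]
    group_idx = dataset.patient_id[keep]
    # stratified patient-grouped folds: no patient straddles a split and the
    # cancer:normal balance is kept comparable across folds
    outer = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs, senss, specs, bals = [], [], [], []
    for train, test in outer.split(X, y, groups=group_idx):
        inner_groups = group_idx[train]
        n_inner = min(3, len(np.unique(inner_groups)))
        search = GridSearchCV(
            _make_pipeline(),
            {"clf__C": list(c_grid), "select__estimator__C": [0.1, 1.0]},
            cv=StratifiedGroupKFold(n_splits=n_inner, shuffle=True, random_state=seed),
            scoring="accuracy", n_jobs=1,
        )
        search.fit(X[train], y[train], groups=inner_groups)
        y_pred = search.predict(X[test]).astype(bool)
        acc, sens, spec, bal = _binary_metrics(y[test], y_pred)
        accs.append(acc)
        senss.append(sens)
        specs.append(spec)
        bals.append(bal)
    return ClassificationReport(
        qf_gate=float(qf_gate),
        n_used=n_used,
        fold_accuracy=np.array(accs),
        fold_sensitivity=np.array(senss),
        fold_specificity=np.array(specs),
        fold_balanced_accuracy=np.array(bals),
    )


def compare_gating(
    dataset: QualityDataset | str | Path,
    gates: Sequence[float],
    seeds: Sequence[int] = (0,),
    folds: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classification metrics and across-fold variability per QF gate.

    Returns ``(summary, detail)``: one summary row per gate (means over
    seeds of the fold-mean metrics and of the across-fold standard
    deviations) and one detail row per (gate, seed).
    """
    if len(gates) < 1:
        raise SpectrumValidationError("need at least one gate")
    if not isinstance(dataset, QualityDataset):
        dataset = process_dataset(dataset)
    if max(gates) >= dataset.qf.max():
        raise SpectrumValidationError(
            f"gate {max(gates)} is at or above the dataset QF maximum {dataset.qf.max():.1f}: empty gate"
        )
    detail_rows = []
    for gate in gates:
        for seed in seeds:
            rep = train_gated_classifier(dataset, qf_gate=gate, folds=folds, seed=seed)
            row = rep.summary()
            row["seed"] = seed
            detail_rows.append(row)
    detail = pd.DataFrame(detail_rows)
    summary = (
        detail.groupby("qf_gate")
        .agg({
            "n_used": "mean",
            "accuracy": "mean",
            "sensitivity": "mean",
            "specificity": "mean",
            "accuracy_fold_std": "mean",
            "sensitivity_fold_std": "mean",
            "specificity_fold_std": "mean",
        })
        .reset_index()
    )
    return summary, detail
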