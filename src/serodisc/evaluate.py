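"""Patient-grouped evaluation: 70/30 splits, replicate-consensus patient
predictions, sensitivity/specificity/accuracy over repeated splits, and
pooled ROC analysis with constrained operating points.

All splitting is by patient ID so that the nine replicate spectra of a
patient never straddle the train/test boundary, and the EMSC reference is
always computed from training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .dataset import POSITIVE_LABEL, SpectralDataset
from .errors import DegenerateDataError, StratificationError
from .learners import ModelSpec, fit_model, smote, tune_cv
from .preprocess import PreprocessConfig, run_preprocess

MOD = 2**31  # all derived seeds stay below 2^31


@dataclass(frozen=True)
class SplitPlan:
    """One patient-grouped train/test partition."""

    repeat_index: int
    train_patients: tuple
    test_patients: tuple
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_patients) & set(self.test_patients):
            raise ValueError("train and test patient sets overlap")


@dataclass
class PatientPrediction:
    patient_id: str
    true_label: int
    votes: list
    consensus_label: int
    mean_score: float


@dataclass
class ROCCurve:
    """Empirical ROC: thresholds with (sensitivity, specificity) pairs."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


@dataclass
class OperatingPoints:
    """Constrained operating points inside {sens >= floor, spec >= floor}:
    A = max sensitivity, B = max specificity, C = most balanced."""

    floor: float
    empty: bool
    max_sensitivity: Optional[tuple] = None
    max_specificity: Optional[tuple] = None
    balanced: Optional[tuple] = None


@dataclass
class RepeatSummary:
    """Per-repeat metrics plus aggregates and pooled patient scores."""

    per_repeat: pd.DataFrame
    aggregate: dict
    pooled: pd.DataFrame = field(repr=False)
    models: list = field(default_factory=list, repr=False)
    feature_axis: Optional[np.ndarray] = None
    tuned: list = field(default_factory=list)


def split_by_patient(ds: SpectralDataset, train_frac: float = 0.7,
                     seed: int = 0, repeat_index: int = 0) -> SplitPlan:
    """Stratified patient-level split; per class the train count is the
    nearest integer to ``train_frac * n_class`` (half rounds up)."""
    labels = ds.patient_labels()
    rng = np.random.default_rng(int(seed) % MOD)
    train, test = [], []
    for cls in sorted(labels.unique()):
        ids = labels.index[labels == cls].to_numpy()
        if ids.size < 2:
            raise StratificationError(
                f"class {cls} has {ids.size} patient(s); cannot stratify"
            )
        perm = rng.permutation(ids)
        n_train = int(np.floor(train_frac * ids.size + 0.5))
        n_train = min(max(n_train, 1), ids.size - 1)
        train.extend(perm[:n_train])
        test.extend(perm[n_train:])
    return SplitPlan(repeat_index, tuple(sorted(train)), tuple(sorted(test)),
                     int(seed) % MOD)


def consensus(votes, mean_score: Optional[float] = None,
              threshold: float = 0.5) -> int:
    """Majority label of the replicate votes (odd count => no tie).

    Even counts can tie; a ``mean_score`` fallback resolves the tie at
    ``threshold``, otherwise the tie raises."""
    votes = np.asarray(votes, dtype=int)
    pos = int(votes.sum())
    neg = votes.size - pos
    if pos == neg:
        if mean_score is None:
            raise DegenerateDataError(
                f"tied consensus among {votes.size} votes and no score fallback"
            )
        return int(mean_score >= threshold)
    return int(pos > neg)


def metrics(preds) -> tuple:
    """(sensitivity, specificity, accuracy) at patient level,
    cancer = positive."""
    truth = np.array([p.true_label for p in preds], dtype=int)
    pred = np.array([p.consensus_label for p in preds], dtype=int)
    if np.unique(truth).size < 2:
        raise DegenerateDataError("metrics need both classes in the truth")
    tp = int(np.sum((truth == 1) & (pred == 1)))
    fn = int(np.sum((truth == 1) & (pred == 0)))
    tn = int(np.sum((truth == 0) & (pred == 0)))
    fp = int(np.sum((truth == 0) & (pred == 1)))
    return tp / (tp + fn), tn / (tn + fp), (tp + tn) / truth.size


def _predict_patients(model, ds_test: SpectralDataset) -> list:
    """Score every test spectrum, then reduce to per-patient consensus
    label and mean score."""
    scores = model.score(ds_test.matrix)
    votes = (scores >= model.threshold).astype(int)
    preds = []
    meta = ds_test.meta
    for pid in ds_test.patients:
        rows = np.flatnonzero((meta["patient_id"] == pid).to_numpy())
        v = votes[rows]
        ms = float(scores[rows].mean())
        preds.append(PatientPrediction(
            patient_id=pid,
            true_label=int(meta.iloc[rows[0]]["class"] == POSITIVE_LABEL),
            votes=list(map(int, v)),
            consensus_label=consensus(v, mean_score=ms,
                                      threshold=model.threshold),
            mean_score=ms,
        ))
    return preds


def evaluate_split(ds: SpectralDataset, plan: SplitPlan, spec: ModelSpec,
                   prep_cfg: PreprocessConfig, sampling: str = "none",
                   seed: int = 0, tune: bool = True, folds: int = 5):
    """Run one repeat: preprocess with a training-only EMSC reference,
    optionally SMOTE the training features, tune (or reuse) hyperparameters,
    refit on all training data, and score the test patients.

    Returns (patient predictions, fitted model, tuned spec, feature axis).
    """
    ds.require_two_classes()
    train_rows = ds.rows_for_patients(plan.train_patients)
    train_mask = np.zeros(ds.n_spectra, dtype=bool)
    train_mask[train_rows] = True

    prepped = run_preprocess(ds, prep_cfg, train_mask=train_mask)
    Xtr = prepped.matrix[train_mask]
    ytr = prepped.y[train_mask]
    groups = prepped.meta["patient_id"].to_numpy()[train_mask]

    if hasattr(spec, "build"):
        # any object exposing build(X, y, seed) -> FittedModel-like works;
        # the engine itself is family-agnostic
        model = spec.build(Xtr, ytr, seed)
        preds = _predict_patients(model, prepped.take_rows(np.flatnonzero(~train_mask)))
        return preds, model, spec, prepped.axis

    if tune and spec.tuned is None:
        spec = tune_cv(Xtr, ytr, spec, folds=folds, seed=seed, groups=groups,
                       sampling=sampling)
    elif spec.tuned is None:
        grid = spec.resolved_grid(Xtr.shape[1])
        (param, values), = grid.items()
        spec = ModelSpec(spec.family, spec.grid,
                         {param: values[len(values) // 2]}, spec.n_trees)

    if sampling == "smote":
        Xtr, ytr = smote(Xtr, ytr, seed=seed)
    elif sampling != "none":
        raise ValueError(f"unknown sampling {sampling!r}")

    model = fit_model(spec, Xtr, ytr, seed=seed)
    test_rows = ~train_mask
    preds = _predict_patients(model, prepped.take_rows(np.flatnonzero(test_rows)))
    return preds, model, spec, prepped.axis


def run_repeats(ds: SpectralDataset, model_spec: ModelSpec,
                prep_cfg: PreprocessConfig, n_repeats: int = 51,
                sampling: str = "none", base_seed: int = 0,
                train_frac: float = 0.7, tune: bool = True,
                folds: int = 5, keep_models: bool = False) -> RepeatSummary:
    """The study loop: ``n_repeats`` independent patient-grouped splits,
    each fully re-preprocessed, tuned, fitted and scored; metrics are
    aggregated as mean +/- SD over repeats.  Repeat r uses seed
    ``(base_seed + r) mod 2^31`` so any repeat is reproducible alone."""
    rows, pooled, models, tuned_list = [], [], [], []
    feature_axis = None
    for r in range(1, n_repeats + 1):
        seed_r = (int(base_seed) + r) % MOD
        plan = split_by_patient(ds, train_frac, seed=seed_r, repeat_index=r)
        preds, model, tuned_spec, feature_axis = evaluate_split(
            ds, plan, model_spec, prep_cfg, sampling=sampling,
            seed=seed_r, tune=tune, folds=folds,
        )
        sens, spec_, acc = metrics(preds)
        scores = np.array([p.mean_score for p in preds])
        truth = np.array([p.true_label for p in preds])
        auc_r = roc_from_scores(scores, truth).auc
        rows.append({"repeat": r, "sensitivity": sens, "specificity": spec_,
                     "accuracy": acc, "auc": auc_r})
        for p in preds:
            pooled.append({"repeat": r, "patient_id": p.patient_id,
                           "true_label": p.true_label,
                           "mean_score": p.mean_score,
                           "consensus_label": p.consensus_label})
        tuned_list.append(getattr(tuned_spec, "tuned", None))
        if keep_models:
            models.append(model)
    per_repeat = pd.DataFrame(rows)
    aggregate = {}
    for m in ("sensitivity", "specificity", "accuracy", "auc"):
        aggregate[f"{m}_mean"] = float(per_repeat[m].mean())
        aggregate[f"{m}_sd"] = float(per_repeat[m].std(ddof=1)) if n_repeats > 1 else 0.0
    return RepeatSummary(per_repeat, aggregate, pd.DataFrame(pooled),
                         models, feature_axis, tuned_list)


def roc_from_scores(scores, labels) -> ROCCurve:
    """Empirical ROC over continuous scores; AUC by the trapezoid rule.

    Tied scores collapse to a single threshold step, so the AUC equals the
    pairwise concordance P(s_case > s_ctrl) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise DegenerateDataError("ROC needs both classes among the scores")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thr, sensitivity=tpr, specificity=1 - fpr,
                    auc=auc)


def pooled_roc(summary: RepeatSummary) -> ROCCurve:
    """ROC over patient mean scores pooled across repeats (each patient
    contributes once per test appearance)."""
    pooled = summary.pooled
    return roc_from_scores(pooled["mean_score"].to_numpy(),
                           pooled["true_label"].to_numpy())


def operating_points(roc: ROCCurve, floor: float = 0.60) -> OperatingPoints:
    """Operating points within {sens >= floor and spec >= floor}; boundary
    points are admitted.  A: max sensitivity; B: max specificity;
    C: argmin |sens - spec| (ties toward larger sens + spec)."""
    if not 0 < floor < 1:
        raise ValueError("floor must be inside (0, 1)")
    sens, spec = roc.sensitivity, roc.specificity
    ok = np.flatnonzero((sens >= floor) & (spec >= floor))
    if ok.size == 0:
        return OperatingPoints(floor=floor, empty=True)
    pts = list(zip(sens[ok], spec[ok]))
    a = max(pts, key=lambda p: (p[0], p[1]))
    b = max(pts, key=lambda p: (p[1], p[0]))
    c = min(pts, key=lambda p: (abs(p[0] - p[1]), -(p[0] + p[1])))
    return OperatingPoints(floor=floor, empty=False, max_sensitivity=a,
                           max_specificity=b, balanced=c)
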