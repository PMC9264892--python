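"""Statistical validation and model interpretation.

* Permutation-null test: per iteration, a fresh patient-grouped split; one
  model trained on the true labels (observed) and one on labels permuted
  across patients (all nine replicate spectra of a patient keep a common
  permuted label).  The p-value is the add-one exceedance estimator

      p = (1 + #{null_i >= mean(observed)}) / (n_iter + 1)

  so it can never be exactly zero; a run with zero exceedances reports the
  floor 1/(n_iter+1) and is flagged ``at_floor``.  Note that referencing the
  *mean* of the observed accuracies makes this estimator conservative under
  the null (see docs/methods.md); it is the convention implemented here.

* Gini profile: random-forest mean-decrease-in-impurity importances
  averaged over repeats, mapped to binned-wavenumber centers, with a
  top-k table (ties ranked by ascending wavenumber).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .dataset import NEGATIVE_LABEL, POSITIVE_LABEL, SpectralDataset
from .errors import IntegrityError
from .evaluate import (MOD, OperatingPoints, ROCCurve, RepeatSummary,
                       evaluate_split, metrics, split_by_patient)
from .learners import ModelSpec
from .preprocess import PreprocessConfig

log = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    observed_acc: np.ndarray
    null_acc: np.ndarray
    p_value: float
    n_iter: int
    at_floor: bool

    def __str__(self) -> str:  # "p < 1/(n_iter+1)" when no null exceeds
        if self.at_floor:
            return f"p < {1.0 / (self.n_iter + 1):.3g}"
        return f"p = {self.p_value:.4g}"


@dataclass
class GiniProfile:
    """Mean per-bin RF importance with bin-center wavenumbers (cm^-1)."""

    wavenumbers: np.ndarray
    importance: np.ndarray
    top_k: pd.DataFrame


def _permute_patient_labels(ds: SpectralDataset, rng) -> np.ndarray:
    """Per-spectrum 0/1 labels after permuting class labels across
    patients; class counts are preserved exactly (a permutation, not a
    resample)."""
    labels = ds.patient_labels()
    permuted = pd.Series(rng.permutation(labels.to_numpy()),
                         index=labels.index)
    assert permuted.sum() == labels.sum()  # counts preserved by construction
    return permuted.loc[ds.meta["patient_id"]].to_numpy()


def permutation_test(ds: SpectralDataset, prep_cfg: PreprocessConfig,
                     model_spec: Optional[ModelSpec] = None,
                     n_iter: int = 1000, sampling: str = "none",
                     base_seed: int = 0, train_frac: float = 0.7,
                     retune_each_iter: bool = False) -> PermutationResult:
    """Observed-vs-null accuracy distributions over ``n_iter`` iterations.

    Defaults to PLS-DA.  Hyperparameters are tuned once on an initial
    split and reused across iterations unless ``retune_each_iter``.
    """
    if n_iter < 10:
        raise ValueError("n_iter must be >= 10 for a meaningful null")
    if model_spec is None:
        model_spec = ModelSpec("plsda")

    tuned_spec = model_spec
    if getattr(model_spec, "tuned", "stub") is None and not retune_each_iter:
        plan0 = split_by_patient(ds, train_frac, seed=base_seed % MOD)
        _, _, tuned_spec, _ = evaluate_split(
            ds, plan0, model_spec, prep_cfg, sampling=sampling,
            seed=base_seed % MOD, tune=True,
        )

    observed = np.empty(n_iter)
    null = np.empty(n_iter)
    for i in range(n_iter):
        seed_i = (int(base_seed) + 7919 * (i + 1)) % MOD
        rng = np.random.default_rng(seed_i)
        plan = split_by_patient(ds, train_frac, seed=seed_i, repeat_index=i + 1)
        spec_i = model_spec if retune_each_iter else tuned_spec
        if retune_each_iter:
            preds, _, _, _ = evaluate_split(
                ds, plan, spec_i, prep_cfg, sampling=sampling, seed=seed_i,
                tune=True,
            )
            observed[i] = metrics(preds)[2]
            ds_perm = _with_labels(ds, _permute_patient_labels(ds, rng))
            preds_n, _, _, _ = evaluate_split(
                ds_perm, plan, spec_i, prep_cfg, sampling=sampling,
                seed=seed_i, tune=True,
            )
            null[i] = metrics(preds_n)[2]
        else:
            # preprocessing is label-independent, so the observed and null
            # models of one iteration share the same features
            observed[i], null[i] = _one_iteration(
                ds, plan, spec_i, prep_cfg, sampling, seed_i, rng,
            )

    exceed = int(np.sum(null >= observed.mean()))
    p = (1 + exceed) / (n_iter + 1)
    return PermutationResult(observed, null, p, n_iter, at_floor=exceed == 0)


def _one_iteration(ds, plan, spec, prep_cfg, sampling, seed, rng):
    """Observed and null patient-consensus test accuracies for one split."""
    from .evaluate import _predict_patients
    from .learners import fit_model, smote
    from .preprocess import run_preprocess

    train_mask = np.zeros(ds.n_spectra, dtype=bool)
    train_mask[ds.rows_for_patients(plan.train_patients)] = True
    prepped = run_preprocess(ds, prep_cfg, train_mask=train_mask)
    test_idx = np.flatnonzero(~train_mask)
    ds_test = prepped.take_rows(test_idx)

    accs = []
    y_true = prepped.y
    y_perm = _permute_patient_labels(ds, rng)
    for y_row in (y_true, y_perm):
        Xtr, ytr = prepped.matrix[train_mask], y_row[train_mask]
        if sampling == "smote":
            Xtr, ytr = smote(Xtr, ytr, seed=seed)
        if hasattr(spec, "build"):
            model = spec.build(Xtr, ytr, seed)
        else:
            model = fit_model(spec, Xtr, ytr, seed=seed)
        scores = model.score(ds_test.matrix)
        votes = (scores >= model.threshold).astype(int)
        correct = 0
        pids = ds_test.meta["patient_id"].to_numpy()
        truth_rows = y_row[test_idx]
        for pid in np.unique(pids):
            rows = np.flatnonzero(pids == pid)
            v = votes[rows]
            lab = consensus_votes(v, float(scores[rows].mean()),
                                  model.threshold)
            correct += int(lab == truth_rows[rows[0]])
        accs.append(correct / np.unique(pids).size)
    return accs[0], accs[1]


def consensus_votes(v, mean_score, threshold):
    pos = int(v.sum())
    if 2 * pos == v.size:
        return int(mean_score >= threshold)
    return int(2 * pos > v.size)


def _with_labels(ds: SpectralDataset, y_per_row: np.ndarray) -> SpectralDataset:
    meta = ds.meta.copy()
    meta["class"] = np.where(y_per_row == 1, POSITIVE_LABEL, NEGATIVE_LABEL)
    return SpectralDataset(ds.matrix, ds.axis.copy(), meta)


def gini_profile(summary_or_importances, feature_axis: np.ndarray,
                 top_k: int = 15, normalize: bool = False) -> GiniProfile:
    """Average RF importances over repeats and rank the top wavenumbers.

    Accepts a :class:`RepeatSummary` with kept RF models or a list of
    per-repeat importance vectors.  Ties in importance are ranked by
    ascending wavenumber.
    """
    if isinstance(summary_or_importances, RepeatSummary):
        imps = [m.feature_importances_ for m in summary_or_importances.models
                if m.feature_importances_ is not None]
    else:
        imps = [np.asarray(v, dtype=float) for v in summary_or_importances]
    if not imps:
        raise ValueError("no random-forest importances available")
    lengths = {len(v) for v in imps}
    if len(lengths) != 1:
        raise IntegrityError(f"mismatched feature counts across repeats: {lengths}")
    feature_axis = np.asarray(feature_axis, dtype=float)
    if feature_axis.size != lengths.pop():
        raise IntegrityError("feature axis does not match importance length")

    mean_imp = np.mean(imps, axis=0)
    if normalize:
        mean_imp = mean_imp / mean_imp.sum()
    order = np.lexsort((feature_axis, -mean_imp))  # ties -> ascending cm^-1
    k = min(top_k, mean_imp.size)
    table = pd.DataFrame({
        "rank": np.arange(1, k + 1),
        "wavenumber": feature_axis[order[:k]],
        "importance": mean_imp[order[:k]],
    })
    return GiniProfile(feature_axis, mean_imp, table)


def render_reports(outdir, summary: Optional[RepeatSummary] = None,
                   roc: Optional[ROCCurve] = None,
                   points: Optional[OperatingPoints] = None,
                   perm: Optional[PermutationResult] = None,
                   gini: Optional[GiniProfile] = None,
                   prepped: Optional[SpectralDataset] = None) -> list:
    """Write the run's figures and metric table with deterministic names.

    Produces: ``roc_curve.png``, ``permutation_hist.png``,
    ``gini_importance.png``, ``mean_spectra.png`` and ``metrics.csv``
    (only for the inputs provided); returns the written paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    if summary is not None:
        path = outdir / "metrics.csv"
        agg = pd.DataFrame([summary.aggregate])
        agg.to_csv(path, index=False, float_format="%.10g")
        written.append(path)

    if roc is not None:
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.plot(1 - roc.specificity, roc.sensitivity, color="navy")
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
        if points is not None and not points.empty:
            lo = points.floor
            ax.add_patch(plt.Rectangle((0, lo), 1 - lo, 1 - lo,
                                       alpha=0.15, color="tab:blue"))
            for name, pt in (("A", points.max_sensitivity),
                             ("B", points.max_specificity),
                             ("C", points.balanced)):
                ax.plot(1 - pt[1], pt[0], "o", color="orange")
                ax.annotate(name, (1 - pt[1], pt[0]),
                            textcoords="offset points", xytext=(5, -10))
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"Pooled ROC (AUC = {roc.auc:.3f})")
        path = outdir / "roc_curve.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    if perm is not None and perm.n_iter > 0:
        fig, ax = plt.subplots(figsize=(6, 4))
        bins = np.linspace(0, 1, 41)
        ax.hist(perm.null_acc, bins=bins, alpha=0.6, color="tab:red",
                label="null (permuted labels)")
        ax.hist(perm.observed_acc, bins=bins, alpha=0.6, color="tab:blue",
                label="observed (true labels)")
        ax.set_xlabel("patient-level test accuracy")
        ax.set_ylabel("count")
        ax.set_title(f"Permutation test ({perm})")
        ax.legend()
        path = outdir / "permutation_hist.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    elif perm is not None:
        log.info("empty permutation result; histogram skipped")

    if gini is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(gini.wavenumbers, gini.importance, color="tab:green")
        ax.invert_xaxis()
        ax.set_xlabel("wavenumber (cm$^{-1}$)")
        ax.set_ylabel("mean Gini importance")
        ax.set_title("Random-forest importance profile")
        path = outdir / "gini_importance.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    if prepped is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        y = prepped.y
        for val, name, color in ((1, "cancer", "black"), (0, "control", "red")):
            rows = prepped.matrix[y == val]
            if rows.size:
                ax.plot(prepped.axis, rows.mean(axis=0), color=color,
                        label=f"mean {name}")
        ax.invert_xaxis()
        ax.set_xlabel("wavenumber (cm$^{-1}$)")
        ax.set_ylabel("processed absorbance")
        ax.legend()
        path = outdir / "mean_spectra.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    return written
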