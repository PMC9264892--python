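"""YAML-driven run configuration and the end-to-end pipeline driver.

``run_all`` executes simulate -> preprocess -> evaluate -> permutation test
-> reports for every configured model family and writes a JSON manifest
with all seeds, configs and output checksums, so re-running the same
config reproduces every numeric output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .dataset import SpectralDataset
from .evaluate import operating_points, pooled_roc, run_repeats
from .iohub import read_wide_csv, write_wide_csv
from .learners import ModelSpec
from .preprocess import PreprocessConfig
from .synthspec import CohortConfig, make_axis, simulate_cohort
from .validate import gini_profile, permutation_test, render_reports

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One reproducible run: cohort source, preprocessing, model list,
    repeat/permutation counts and the base seed everything derives from."""

    cohort: object  # CohortConfig or path to a wide CSV
    prep: PreprocessConfig = field(default_factory=PreprocessConfig)
    models: list = field(default_factory=lambda: ["rf", "plsda", "svm_linear"])
    n_repeats: int = 51
    sampling: str = "none"
    perm_iters: int = 1000
    base_seed: int = 0
    outdir: str = "results"
    axis_high: float = 4000.0
    axis_low: float = 450.0
    axis_spacing: float = 2.0
    tune: bool = True
    roc_floor: float = 0.60

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = raw.pop("cohort", None)
        if cohort is None:
            raise ValueError(f"{path}: config needs a 'cohort' section or path")
        if isinstance(cohort, dict):
            cohort = CohortConfig(**cohort)
        else:
            cohort = str(cohort)
            if not Path(cohort).exists():
                raise FileNotFoundError(f"cohort data path not found: {cohort}")
        prep = PreprocessConfig(**raw.pop("prep", {}))
        return cls(cohort=cohort, prep=prep, **raw)


def load_cohort(cfg: RunConfig) -> SpectralDataset:
    if isinstance(cfg.cohort, CohortConfig):
        axis = make_axis(cfg.axis_high, cfg.axis_low, cfg.axis_spacing)
        return simulate_cohort(cfg.cohort, axis)
    return read_wide_csv(cfg.cohort)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to
    ``outdir/manifest.json``)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ds = load_cohort(cfg)
    cohort_csv = outdir / "cohort.csv"
    write_wide_csv(ds, cohort_csv)
    log.info("cohort: %d spectra, %d patients", ds.n_spectra, len(ds.patients))

    summaries = {}
    gini = None
    metric_rows = []
    for fam in cfg.models:
        spec = ModelSpec(fam)
        summary = run_repeats(
            ds, spec, cfg.prep, n_repeats=cfg.n_repeats,
            sampling=cfg.sampling, base_seed=cfg.base_seed,
            tune=cfg.tune, keep_models=(fam == "rf"),
        )
        summary.per_repeat.to_csv(outdir / f"metrics_{fam}_per_repeat.csv",
                                  index=False, float_format="%.10g")
        roc = pooled_roc(summary)
        pts = operating_points(roc, cfg.roc_floor)
        row = {"model": fam, **summary.aggregate, "pooled_auc": roc.auc}
        metric_rows.append(row)
        summaries[fam] = (summary, roc, pts)
        if fam == "rf":
            gini = gini_profile(summary, summary.feature_axis)
            gini.top_k.to_csv(outdir / "gini_top15.csv", index=False,
                              float_format="%.10g")
        pd.DataFrame(
            [{"point": n, "sensitivity": p[0], "specificity": p[1]}
             for n, p in (("max_sensitivity", pts.max_sensitivity),
                          ("max_specificity", pts.max_specificity),
                          ("balanced", pts.balanced))
             if p is not None]
        ).to_csv(outdir / f"operating_points_{fam}.csv", index=False,
                 float_format="%.10g")
        log.info("%s: accuracy %.3f +/- %.3f, pooled AUC %.3f", fam,
                 row["accuracy_mean"], row["accuracy_sd"], roc.auc)

    metrics_csv = outdir / "metrics_summary.csv"
    pd.DataFrame(metric_rows).to_csv(metrics_csv, index=False,
                                     float_format="%.10g")

    perm = permutation_test(
        ds, cfg.prep, ModelSpec("plsda"), n_iter=cfg.perm_iters,
        sampling=cfg.sampling, base_seed=cfg.base_seed,
    )
    pd.DataFrame({"observed_acc": perm.observed_acc,
                  "null_acc": perm.null_acc}).to_csv(
        outdir / "permutation_accuracies.csv", index=False,
        float_format="%.10g")

    # figures from the best-AUC model's pooled ROC; mean-spectra overlay
    # from the whole cohort preprocessed with an all-rows reference
    from .preprocess import run_preprocess

    best = max(metric_rows, key=lambda r: r["pooled_auc"])["model"]
    summary, roc, pts = summaries[best]
    render_reports(outdir, summary=summary, roc=roc, points=pts, perm=perm,
                   gini=gini, prepped=run_preprocess(ds, cfg.prep))

    manifest = {
        "version": __version__,
        "base_seed": cfg.base_seed,
        "n_repeats": cfg.n_repeats,
        "perm_iters": cfg.perm_iters,
        "sampling": cfg.sampling,
        "models": list(cfg.models),
        "prep": _prep_dict(cfg.prep),
        "cohort": asdict(cfg.cohort) if isinstance(cfg.cohort, CohortConfig)
                  else str(cfg.cohort),
        "permutation_p": perm.p_value,
        "permutation_at_floor": perm.at_floor,
        "metrics": metric_rows,
        "checksums": {
            p.name: _sha256(p) for p in sorted(outdir.glob("*.csv"))
        },
    }
    # tuples inside cohort config are not JSON-native
    if isinstance(manifest["cohort"], dict):
        for key in ("effect_bands", "base_bands"):
            manifest["cohort"][key] = [list(astuple_band(b)) for b in
                                       manifest["cohort"][key]]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return manifest


def _prep_dict(prep: PreprocessConfig) -> dict:
    d = asdict(prep)
    if not isinstance(d["emsc_reference"], str):
        d["emsc_reference"] = "supplied-spectrum"
    return d


def astuple_band(b) -> tuple:
    if isinstance(b, dict):
        return (b["center"], b["width"], b["amplitude"])
    return (b.center, b.width, b.amplitude) if hasattr(b, "center") else tuple(b)
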