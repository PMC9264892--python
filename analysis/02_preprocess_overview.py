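#!/usr/bin/env python
"""Preprocess design A and summarize what each stage does to the data.

Reads results/data/cohortA.csv (run 01 first), applies the chain
EMSC -> fingerprint crop (1800-1000/cm) -> vector normalization ->
binning x8, reports the dimensionality after each stage, and writes the
processed features plus a mean-spectra overlay figure to results/prep/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from serodisc import (PreprocessConfig, bin_spectra, crop_region,
                      emsc_correct, read_wide_csv, vector_normalize,
                      write_wide_csv)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ds = read_wide_csv(ROOT / "data" / "cohortA.csv")
    out = ROOT / "prep"
    out.mkdir(parents=True, exist_ok=True)
    print(f"raw: {ds.n_spectra} x {ds.n_points}")

    cfg = PreprocessConfig()
    stage = emsc_correct(ds, ds.matrix.mean(axis=0), cfg.emsc_order)
    print(f"after EMSC (order {cfg.emsc_order}): {stage.n_points} points")
    stage = crop_region(stage, cfg.crop_high, cfg.crop_low)
    print(f"after crop ({cfg.crop_low:g}-{cfg.crop_high:g}/cm): "
          f"{stage.n_points} points")
    stage = vector_normalize(stage)
    stage = bin_spectra(stage, cfg.bin_factor)
    print(f"after vector normalization + binning x{cfg.bin_factor}: "
          f"{stage.n_points} features")

    write_wide_csv(stage, out / "cohortA_preprocessed.csv")

    fig, ax = plt.subplots(figsize=(7, 4))
    y = stage.y
    for val, name, color in ((1, "cancer", "black"), (0, "control", "red")):
        ax.plot(stage.axis, stage.matrix[y == val].mean(axis=0), color=color,
                label=f"mean {name} (n={int((y == val).sum())} spectra)")
    ax.invert_xaxis()
    ax.set_xlabel("wavenumber (cm$^{-1}$)")
    ax.set_ylabel("processed absorbance")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "mean_spectra.png", dpi=120)
    print(f"wrote {out / 'cohortA_preprocessed.csv'} and mean_spectra.png")


if __name__ == "__main__":
    main()
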