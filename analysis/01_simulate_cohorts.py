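#!/usr/bin/env python
"""Generate the three synthetic serum cohort designs.

Design A: balanced cancer vs healthy controls, strong spectral effect.
Design B: balanced cancer vs symptomatic controls, moderate effect.
Design C: imbalanced cancer vs symptomatic controls, moderate effect.

Desk-scale sizes (half of design A's full 100/100) keep the downstream
scripts interactive; every cohort keeps the 3 biological x 3 technical
replicate structure (9 spectra per patient).  Writes wide CSVs under
results/data/.
"""

from pathlib import Path

from serodisc import CohortConfig, make_axis, simulate_cohort, write_wide_csv

OUT = Path(__file__).resolve().parents[1] / "results" / "data"

DESIGNS = {
    "cohortA": CohortConfig(n_cases=50, n_controls=50, effect_size=4.0,
                            seed=1001),
    "cohortB": CohortConfig(n_cases=35, n_controls=35, effect_size=1.5,
                            seed=1002),
    "cohortC": CohortConfig(n_cases=50, n_controls=18, effect_size=1.5,
                            seed=1003),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    axis = make_axis(4000.0, 450.0, 2.0)
    for name, cfg in DESIGNS.items():
        ds = simulate_cohort(cfg, axis)
        path = write_wide_csv(ds, OUT / f"{name}.csv")
        print(f"{name}: {ds.n_spectra} spectra "
              f"({cfg.n_cases} cancer / {cfg.n_controls} control patients, "
              f"9 replicates each, {ds.n_points} points) -> {path.name}")


if __name__ == "__main__":
    main()
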