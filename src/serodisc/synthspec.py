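"""Synthetic serum-like ATR-FTIR cohort generator.

Emulates the structure of a dried-serum infrared study: each patient
contributes 3 biological x 3 technical replicate spectra; a case/control
class difference is planted as additive amplitude shifts on a small set of
Gaussian bands (amide II flanks ~1570 and ~1500 cm^-1, phosphate ~1270,
carbohydrate ~1050); each spectrum carries multiplicative scatter, an
additive polynomial baseline, and white technical noise:

    y = b * (base + z*effect + patient_dev + bio_dev) + baseline + noise

with z = 1 for cancer, 0 for control, and b = exp(N(0, scatter_sd)).
Scatter is applied before the baseline so that EMSC's model (reference
scale plus polynomial) is exactly the right inverse.

Reproducibility: one RNG stream per cohort derived from ``cfg.seed``, with
per-patient sub-streams keyed by patient counter, so the same seed always
yields a bit-identical cohort and any patient subset is reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import NEGATIVE_LABEL, POSITIVE_LABEL, SpectralDataset


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band: center (cm^-1), width sigma (cm^-1),
    amplitude (absorbance)."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be non-negative")


# Base serum band library: amide A, CH stretch, amide I, amide II,
# PO2- asymmetric stretch, carbohydrate C-O bands.
DEFAULT_BASE_BANDS = (
    BandSpec(3300.0, 90.0, 0.45),
    BandSpec(2960.0, 30.0, 0.12),
    BandSpec(1650.0, 28.0, 1.00),
    BandSpec(1545.0, 24.0, 0.72),
    BandSpec(1450.0, 20.0, 0.25),
    BandSpec(1400.0, 18.0, 0.20),
    BandSpec(1240.0, 25.0, 0.18),
    BandSpec(1100.0, 22.0, 0.14),
    BandSpec(1040.0, 18.0, 0.16),
)

# Class-difference bands: amide II flanks plus phosphate/carbohydrate bands.
DEFAULT_EFFECT_BANDS = (
    BandSpec(1570.0, 12.0, 0.020),
    BandSpec(1500.0, 12.0, 0.020),
    BandSpec(1270.0, 14.0, 0.010),
    BandSpec(1050.0, 14.0, 0.010),
)

# Qualitative effect-size regimes used throughout the analyses, in units
# of the between-patient marker SD: weak is barely detectable, moderate
# mirrors the harder symptomatic-control contrast, strong is a clearly
# detectable difference (patient-level Bayes accuracy ~ Phi(2) ~ 0.98).
EFFECT_WEAK = 0.5
EFFECT_MODERATE = 1.5
EFFECT_STRONG = 4.0


@dataclass
class CohortConfig:
    """Design of one synthetic cohort.

    ``effect_size`` multiplies the amplitudes of ``effect_bands`` and is
    added to case spectra only; 0 gives exchangeable classes (a null
    cohort).  Every patient additionally carries a marker factor
    ``m ~ N(0, marker_sd)`` on the same effect-band shape, modelling
    biological heterogeneity of the discriminant bands within class, so the
    patient-level separation is governed by ``effect_size / marker_sd``.
    Noise scales are absorbance RMS per point: ``patient_sd`` for the
    smooth between-patient deviation, ``bio_sd`` for the per-biological-
    replicate deviation, ``tech_sd`` for white per-point noise.
    ``scatter_sd`` is the log-scale SD of the multiplicative factor and
    ``baseline_order``/``baseline_sd`` control the random polynomial drift.
    """

    n_cases: int = 100
    n_controls: int = 100
    n_bio: int = 3
    n_tech: int = 3
    effect_size: float = EFFECT_MODERATE
    effect_bands: tuple = DEFAULT_EFFECT_BANDS
    base_bands: tuple = DEFAULT_BASE_BANDS
    marker_sd: float = 1.0
    patient_sd: float = 0.02
    bio_sd: float = 0.008
    tech_sd: float = 0.004
    scatter_sd: float = 0.10
    baseline_order: int = 2
    baseline_sd: float = 0.03
    smooth_sigma_cm: float = 32.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_bio", "n_tech"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("marker_sd", "patient_sd", "bio_sd", "tech_sd",
                     "scatter_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.effect_bands = tuple(
            b if isinstance(b, BandSpec) else BandSpec(*b) for b in self.effect_bands
        )
        self.base_bands = tuple(
            b if isinstance(b, BandSpec) else BandSpec(*b) for b in self.base_bands
        )


def make_axis(high: float = 4000.0, low: float = 450.0, spacing: float = 2.0) -> np.ndarray:
    """Strictly decreasing wavenumber grid from ``high`` to ``low``.

    When the span is not divisible by ``spacing`` the grid stops at the
    last point >= ``low`` and a warning is emitted.
    """
    if high <= low:
        raise ValueError(f"need high > low, got {high} <= {low}")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    ratio = (high - low) / spacing
    if abs(ratio - round(ratio)) > 1e-9:
        n = int(np.floor(ratio)) + 1
        axis = high - spacing * np.arange(n)
        warnings.warn(
            f"span {high}-{low} not divisible by spacing {spacing}; "
            f"grid ends at {axis[-1]:g} cm^-1",
            stacklevel=2,
        )
        return axis
    return high - spacing * np.arange(int(round(ratio)) + 1)


def base_serum_spectrum(axis: np.ndarray, bands=DEFAULT_BASE_BANDS) -> np.ndarray:
    """Sum of Gaussian bands evaluated on ``axis`` (non-negative)."""
    bands = list(bands)
    if not bands:
        raise ValueError("band list must be non-empty")
    out = np.zeros_like(np.asarray(axis, dtype=float))
    for b in bands:
        out += b.amplitude * np.exp(-0.5 * ((axis - b.center) / b.width) ** 2)
    return out


def _smooth_noise(rng, axis, sd, sigma_cm):
    """Smooth correlated noise: white noise convolved with a Gaussian
    kernel, rescaled to RMS ``sd``.  Models broad biochemical variation."""
    if sd == 0:
        return np.zeros_like(axis)
    spacing = abs(axis[0] - axis[1])
    sigma_pts = max(sigma_cm / spacing, 1e-9)
    half = int(np.ceil(4 * sigma_pts))
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma_pts) ** 2)
    kernel /= kernel.sum()
    white = rng.standard_normal(axis.size + 2 * half)
    smooth = np.convolve(white, kernel, mode="valid")
    rms = np.sqrt(np.mean(smooth**2))
    return sd * smooth / max(rms, 1e-300)


def simulate_cohort(cfg: CohortConfig, axis: np.ndarray | None = None) -> SpectralDataset:
    """Generate one cohort as a :class:`SpectralDataset`.

    Rows are ordered case patients first, then controls; within a patient,
    biological replicate is the outer loop, technical the inner.
    """
    if axis is None:
        axis = make_axis()
    axis = np.asarray(axis, dtype=float)
    base = base_serum_spectrum(axis, cfg.base_bands)
    effect_shape = (base_serum_spectrum(axis, cfg.effect_bands)
                    if cfg.effect_bands else np.zeros_like(axis))

    # polynomial basis on the axis rescaled to [-1, 1]
    t = 2 * (axis - axis.min()) / (axis.max() - axis.min()) - 1
    poly_basis = np.vstack([t**k for k in range(cfg.baseline_order + 1)])

    n_patients = cfg.n_cases + cfg.n_controls
    rows, recs = [], []
    for p in range(n_patients):
        is_case = p < cfg.n_cases
        pid = f"{'case' if is_case else 'ctrl'}_{p:04d}"
        label = POSITIVE_LABEL if is_case else NEGATIVE_LABEL
        rng = np.random.default_rng([cfg.seed, p])
        marker = rng.normal(0.0, cfg.marker_sd)
        patient_dev = _smooth_noise(rng, axis, cfg.patient_sd, cfg.smooth_sigma_cm)
        z = cfg.effect_size if is_case else 0.0
        clean_core = base + (z + marker) * effect_shape + patient_dev
        for b in range(1, cfg.n_bio + 1):
            bio_dev = _smooth_noise(rng, axis, cfg.bio_sd, cfg.smooth_sigma_cm)
            for tch in range(1, cfg.n_tech + 1):
                scatter = np.exp(rng.normal(0.0, cfg.scatter_sd))
                coeffs = rng.normal(0.0, cfg.baseline_sd, size=cfg.baseline_order + 1)
                baseline = coeffs @ poly_basis
                noise = rng.normal(0.0, cfg.tech_sd, size=axis.size)
                rows.append(scatter * (clean_core + bio_dev) + baseline + noise)
                recs.append((pid, label, b, tch))
    meta = pd.DataFrame(recs, columns=["patient_id", "class", "bio_rep", "tech_rep"])
    return SpectralDataset(np.vstack(rows), axis, meta)
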