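"""Spectral preprocessing chain: EMSC -> fingerprint crop -> vector
normalization -> binning.

The stages run in exactly that order (``run_preprocess`` enforces it).  EMSC
(extended multiplicative signal correction) fits each spectrum x against a
reference r and a polynomial baseline,

    x  ~=  b * r  +  sum_k c_k P_k(t),      t = axis rescaled to [-1, 1]

with P_k Legendre polynomials (P_0 = 1 carries the additive offset), and
returns (x - baseline) / b.  Because the generator applies multiplicative
scatter before its additive baseline, EMSC is the exact model inverse for
synthetic data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.polynomial import legendre

from .dataset import SpectralDataset
from .errors import DegenerateDataError, RangeError

log = logging.getLogger(__name__)

#: sentinel for "use the mean of the training rows as EMSC reference"
MEAN_OF_TRAINING = "mean-of-training"


@dataclass
class PreprocessConfig:
    """Preprocessing knobs.

    ``emsc_reference`` is either :data:`MEAN_OF_TRAINING` (default; the
    reference is computed from rows flagged as training only, then applied
    to every row) or an explicit reference spectrum on the raw axis.
    ``normalization``: ``"vector"`` (per-spectrum mean-centering then unit
    L2), ``"l2"`` (unit L2 without centering) or ``"none"``.
    """

    emsc_order: int = 2
    emsc_reference: object = MEAN_OF_TRAINING
    crop_high: float = 1800.0
    crop_low: float = 1000.0
    normalization: str = "vector"
    bin_factor: int = 8

    def __post_init__(self) -> None:
        if self.crop_high <= self.crop_low:
            raise ValueError("crop_high must exceed crop_low")
        if self.bin_factor < 1:
            raise ValueError("bin_factor must be >= 1")
        if self.emsc_order < 0:
            raise ValueError("emsc_order must be >= 0")
        if self.normalization not in ("vector", "l2", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


def emsc_correct(
    ds: SpectralDataset,
    reference: np.ndarray,
    order: int = 2,
    return_diagnostics: bool = False,
):
    """EMSC-correct every spectrum of ``ds`` against ``reference``.

    Returns the corrected dataset; with ``return_diagnostics=True`` also a
    dict with the fitted offset ``a`` (the P_0 coefficient), scale ``b``
    and polynomial coefficients ``c`` per row.
    """
    coef, poly = _emsc_fit(ds, reference, order)
    b = coef[0]
    baseline = (poly @ coef[1:]).T  # (n_spectra, n_points)
    corrected = (ds.matrix - baseline) / b[:, None]
    out = ds.with_matrix(corrected)
    if return_diagnostics:
        return out, {"a": coef[1].copy(), "b": b.copy(), "c": coef[1:].T.copy()}
    return out


def _emsc_fit(ds: SpectralDataset, reference: np.ndarray, order: int):
    """Least-squares EMSC coefficients for every row (shared helper).

    Returns (coef, poly): coef has shape (order+2, n_spectra) with the
    reference scale b in row 0 and Legendre coefficients after it; poly is
    the (n_points, order+1) Legendre design block."""
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (ds.n_points,):
        raise ValueError("reference must live on the dataset axis")
    if np.allclose(reference, 0.0):
        raise DegenerateDataError("EMSC reference is identically zero")

    lo, hi = ds.axis.min(), ds.axis.max()
    t = 2 * (ds.axis - lo) / (hi - lo) - 1
    poly = legendre.legvander(t, order)  # (n_points, order+1), P_0..P_order
    design = np.column_stack([reference, poly])

    # normal equations: the design is tiny (order+2 columns) and Legendre
    # columns keep it well conditioned; guard against collinearity
    gram = design.T @ design
    if np.linalg.cond(gram) > 1e12:
        raise np.linalg.LinAlgError("collinear EMSC design matrix")
    coef = np.linalg.solve(gram, design.T @ ds.matrix.T)
    b = coef[0]
    small = np.flatnonzero(np.abs(b) < 1e-8)
    if small.size:
        raise DegenerateDataError(
            f"EMSC scale factor below 1e-8 for row {int(small[0])}"
        )
    return coef, poly


def crop_region(ds: SpectralDataset, high: float = 1800.0, low: float = 1000.0) -> SpectralDataset:
    """Keep points with low <= wavenumber <= high (inclusive), order kept."""
    mask = (ds.axis >= low) & (ds.axis <= high)
    if not mask.any():
        raise RangeError(
            f"crop [{low}, {high}] does not overlap axis "
            f"[{ds.axis.min():g}, {ds.axis.max():g}]"
        )
    return ds.with_matrix(ds.matrix[:, mask], ds.axis[mask])


def vector_normalize(ds: SpectralDataset, center: bool = True) -> SpectralDataset:
    """Per-spectrum mean-centering (optional) and unit-L2 scaling."""
    m = ds.matrix
    if center:
        m = m - m.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(m, axis=1)
    bad = np.flatnonzero(norms < 1e-300)
    if bad.size:
        raise DegenerateDataError(
            f"zero-variance spectrum at row {int(bad[0])} cannot be normalized"
        )
    return ds.with_matrix(m / norms[:, None])


def bin_spectra(ds: SpectralDataset, factor: int = 8) -> SpectralDataset:
    """Average consecutive non-overlapping blocks of ``factor`` points.

    Both intensities and wavenumbers are block-averaged; a trailing
    remainder shorter than ``factor`` is dropped (logged).
    """
    if factor < 1:
        raise ValueError("bin factor must be >= 1")
    if factor > ds.n_points:
        raise RangeError(f"bin factor {factor} exceeds {ds.n_points} points")
    if factor == 1:
        return ds.with_matrix(ds.matrix.copy())
    n_bins = ds.n_points // factor
    dropped = ds.n_points - n_bins * factor
    if dropped:
        log.warning("binning drops %d trailing point(s)", dropped)
    keep = n_bins * factor
    matrix = ds.matrix[:, :keep].reshape(ds.n_spectra, n_bins, factor).mean(axis=2)
    axis = ds.axis[:keep].reshape(n_bins, factor).mean(axis=1)
    return ds.with_matrix(matrix, axis)


def run_preprocess(
    ds: SpectralDataset,
    cfg: PreprocessConfig,
    train_mask: Optional[np.ndarray] = None,
) -> SpectralDataset:
    """Apply EMSC -> crop -> normalization -> binning, in that order.

    With the ``mean-of-training`` reference policy, the EMSC reference is
    the mean of the rows where ``train_mask`` is True (all rows when no
    mask is given), so test rows never influence the correction.
    """
    if isinstance(cfg.emsc_reference, str):
        if cfg.emsc_reference != MEAN_OF_TRAINING:
            raise ValueError(f"unknown reference policy {cfg.emsc_reference!r}")
        if train_mask is None:
            reference = ds.matrix.mean(axis=0)
        else:
            train_mask = np.asarray(train_mask, dtype=bool)
            if not train_mask.any():
                raise ValueError("train_mask selects no rows for the reference")
            reference = ds.matrix[train_mask].mean(axis=0)
    else:
        reference = np.asarray(cfg.emsc_reference, dtype=float)

    # EMSC is fitted on the full axis, but the correction is pointwise
    # given the coefficients, so it is materialized only on the crop
    # window (identical to correct-then-crop, without the wasted columns)
    coef, poly = _emsc_fit(ds, reference, cfg.emsc_order)
    mask = (ds.axis >= cfg.crop_low) & (ds.axis <= cfg.crop_high)
    if not mask.any():
        raise RangeError(
            f"crop [{cfg.crop_low}, {cfg.crop_high}] does not overlap axis"
        )
    baseline = (poly[mask] @ coef[1:]).T
    corrected = (ds.matrix[:, mask] - baseline) / coef[0][:, None]
    out = ds.with_matrix(corrected, ds.axis[mask])
    if cfg.normalization == "vector":
        out = vector_normalize(out, center=True)
    elif cfg.normalization == "l2":
        out = vector_normalize(out, center=False)
    out = bin_spectra(out, cfg.bin_factor)
    return out
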