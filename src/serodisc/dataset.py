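"""In-memory containers for ATR-FTIR spectral cohorts.

A cohort is stored wide: one row per acquired spectrum, one column per
wavenumber, with per-row metadata identifying the patient, the class
(``cancer`` is always the positive class, ``control`` the negative), and the
biological / technical replicate indices.  Wavenumbers are kept high->low
(4000 -> 450 cm^-1), the direction IR spectra are conventionally displayed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, IntegrityError

#: canonical metadata column order for wide tables
META_COLUMNS = ["patient_id", "class", "bio_rep", "tech_rep"]

#: serialized class labels, mapped internally to 1 (positive) / 0 (negative)
POSITIVE_LABEL = "cancer"
NEGATIVE_LABEL = "control"


@dataclass
class Spectrum:
    """A single absorbance spectrum plus its acquisition metadata."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    patient_id: str = ""
    class_label: str = ""
    bio_rep: int = 1
    tech_rep: int = 1

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise IntegrityError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.size != self.intensities.size:
            raise IntegrityError(
                f"axis length {self.wavenumbers.size} != "
                f"intensity length {self.intensities.size}"
            )
        if self.wavenumbers.size < 2:
            raise IntegrityError("a spectrum needs at least 2 points")
        if not np.all(np.diff(self.wavenumbers) < 0):
            # store high->low; flip an ascending axis rather than reject it
            if np.all(np.diff(self.wavenumbers) > 0):
                self.wavenumbers = self.wavenumbers[::-1].copy()
                self.intensities = self.intensities[::-1].copy()
            else:
                raise IntegrityError("wavenumber axis must be strictly monotone")
        if not np.all(np.isfinite(self.intensities)):
            raise DegenerateDataError("non-finite intensity values")

    def __len__(self) -> int:
        return int(self.wavenumbers.size)


@dataclass
class SpectralDataset:
    """A cohort of spectra sharing one wavenumber axis.

    Parameters
    ----------
    matrix : (n_spectra, n_points) absorbance values.
    axis : shared wavenumber grid in cm^-1, strictly decreasing.
    meta : per-row DataFrame with columns ``patient_id``, ``class``,
        ``bio_rep``, ``tech_rep``.
    """

    matrix: np.ndarray
    axis: np.ndarray
    meta: pd.DataFrame = field(repr=False)
    #: set True when the meta came unchanged from an already-validated
    #: dataset (derived stages); skips the O(n log n) integrity checks
    trusted_meta: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.matrix.ndim != 2:
            raise IntegrityError("matrix must be 2-D (spectra x points)")
        if self.axis.ndim != 1 or self.axis.size != self.matrix.shape[1]:
            raise IntegrityError("axis length must match matrix columns")
        if not np.all(np.diff(self.axis) < 0):
            raise IntegrityError("wavenumber axis must be strictly decreasing")
        if len(self.meta) != self.matrix.shape[0]:
            raise IntegrityError("meta rows must match matrix rows")
        if not np.all(np.isfinite(self.matrix)):
            raise DegenerateDataError("non-finite intensities in matrix")
        if self.trusted_meta:
            return
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise IntegrityError(f"meta missing columns {missing}")
        self.meta = self.meta.reset_index(drop=True)
        key = self.meta[["patient_id", "bio_rep", "tech_rep"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise IntegrityError(
                "duplicate (patient, bio_rep, tech_rep) triple: "
                f"{tuple(dup)}"
            )
        counts = self.meta.groupby("patient_id").size()
        if counts.nunique() > 1:
            raise IntegrityError(
                "unequal replicate counts per patient: "
                f"{dict(counts[counts != counts.iloc[0]])}"
            )

    # -- basic views ------------------------------------------------------

    @property
    def n_spectra(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_points(self) -> int:
        return int(self.matrix.shape[1])

    @property
    def patients(self) -> np.ndarray:
        """Unique patient ids in first-appearance order."""
        return self.meta["patient_id"].unique()

    @property
    def replicates_per_patient(self) -> int:
        return int(self.meta.groupby("patient_id").size().iloc[0])

    @property
    def y(self) -> np.ndarray:
        """Per-spectrum 0/1 labels (1 = cancer / positive)."""
        return (self.meta["class"].to_numpy() == POSITIVE_LABEL).astype(int)

    def patient_labels(self) -> pd.Series:
        """0/1 label per patient, indexed by patient_id."""
        lab = self.meta.drop_duplicates("patient_id").set_index("patient_id")["class"]
        return (lab == POSITIVE_LABEL).astype(int)

    # -- subsetting -------------------------------------------------------

    def take_rows(self, idx: np.ndarray) -> "SpectralDataset":
        return SpectralDataset(
            self.matrix[idx], self.axis.copy(),
            self.meta.iloc[idx].reset_index(drop=True),
            trusted_meta=True,
        )

    def rows_for_patients(self, patient_ids) -> np.ndarray:
        """Row indices of all spectra belonging to the given patients."""
        wanted = set(patient_ids)
        mask = self.meta["patient_id"].isin(wanted).to_numpy()
        return np.flatnonzero(mask)

    def with_matrix(self, matrix: np.ndarray, axis: np.ndarray | None = None) -> "SpectralDataset":
        """Same cohort metadata with transformed intensities (and axis)."""
        return SpectralDataset(
            matrix,
            self.axis.copy() if axis is None else np.asarray(axis, dtype=float),
            self.meta,
            trusted_meta=True,
        )

    def require_two_classes(self) -> None:
        if self.meta["class"].nunique() < 2:
            raise DegenerateDataError(
                "classification requires at least two distinct class labels"
            )

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, SpectralDataset):
            return NotImplemented
        return (
            np.allclose(self.axis, other.axis, atol=1e-9)
            and np.allclose(self.matrix, other.matrix, atol=1e-9)
            and self.meta[META_COLUMNS].equals(other.meta[META_COLUMNS])
        )
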