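"""Core in-memory containers shared across the pipeline.

The unit of every intersubject computation is a :class:`SubjectEnsemble`:
N aligned 4D BOLD images on a common grid, mask, TR and volume count.
Stimulus information travels as a :class:`Regressor` on the TR grid, and
every voxelwise result is a :class:`StatMap` carrying its statistic kind,
degrees of freedom and provenance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError

__all__ = [
    "RatingTrace",
    "Regressor",
    "BoldImage",
    "SubjectEnsemble",
    "PhaseField",
    "SimilarityField",
    "StatMap",
    "TraitTable",
    "SecondLevelModel",
]

#: instrument score ranges (items scored 0/1): AQ-50 and the 43-item O-LIFE
#: short scales, with the two socially loaded subscales used in the
#: trait-conjunction analyses.
INSTRUMENT_RANGES = {
    "aq_total": (0, 50),
    "olife_total": (0, 43),
    "aq_social_skills": (0, 10),
    "olife_introversion": (0, 10),
}


@dataclass
class RatingTrace:
    """A continuous stimulus rating sampled on a uniform time grid."""

    times: np.ndarray  # seconds, uniformly spaced, strictly increasing
    values: np.ndarray  # rating units
    rater_id: str = "rater"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise InvalidArgumentError("times and values must be 1D and aligned")
        if len(self.times) >= 2:
            d = np.diff(self.times)
            if np.any(d <= 0) or np.ptp(d) > 1e-6:
                raise InvalidArgumentError("trace time grid must be uniform and increasing")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("trace contains missing/non-finite values")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def copy(self) -> "RatingTrace":
        return RatingTrace(self.times.copy(), self.values.copy(), self.rater_id)


@dataclass
class Regressor:
    """A stimulus-locked series on the scan's TR grid."""

    values: np.ndarray
    tr: float
    convolved: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InvalidArgumentError("regressor must be 1D")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("regressor values must be finite")
        if self.tr <= 0:
            raise InvalidArgumentError("tr must be positive")

    @property
    def n_volumes(self) -> int:
        return len(self.values)


@dataclass
class BoldImage:
    """A single subject's 4D BOLD series plus its brain mask."""

    data: np.ndarray  # (x, y, z, t)
    tr: float
    mask: np.ndarray  # (x, y, z) boolean
    subject_id: str = "sub-01"
    provenance: tuple = ()  # processing steps applied, in order

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.data.ndim != 4:
            raise InvalidArgumentError("BOLD data must be 4D (x, y, z, t)")
        if self.mask.shape != self.data.shape[:3]:
            raise InvalidArgumentError("mask shape must match the spatial grid")
        if self.tr <= 0:
            raise InvalidArgumentError("tr must be positive")
        if not np.all(np.isfinite(self.data[self.mask])):
            raise InvalidArgumentError(
                f"non-finite in-mask values in subject {self.subject_id}"
            )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid(self) -> tuple:
        return self.data.shape[:3]

    def with_data(self, data: np.ndarray, step: str | None = None) -> "BoldImage":
        prov = self.provenance + ((step,) if step else ())
        return BoldImage(data, self.tr, self.mask, self.subject_id, prov)


@dataclass
class SubjectEnsemble:
    """N aligned BOLD images: same grid, mask, TR and volume count."""

    images: list

    def __post_init__(self) -> None:
        if len(self.images) == 0:
            raise InvalidArgumentError("ensemble is empty")
        ref = self.images[0]
        for img in self.images[1:]:
            if img.grid != ref.grid:
                raise InvalidArgumentError(
                    f"subject {img.subject_id}: grid {img.grid} != {ref.grid}"
                )
            if img.n_volumes != ref.n_volumes:
                raise InvalidArgumentError(
                    f"subject {img.subject_id}: {img.n_volumes} volumes, "
                    f"expected {ref.n_volumes}"
                )
            if abs(img.tr - ref.tr) > 1e-9:
                raise InvalidArgumentError(f"subject {img.subject_id}: TR mismatch")
            if not np.array_equal(img.mask, ref.mask):
                raise InvalidArgumentError(f"subject {img.subject_id}: mask mismatch")

    @property
    def n_subjects(self) -> int:
        return len(self.images)

    @property
    def mask(self) -> np.ndarray:
        return self.images[0].mask

    @property
    def tr(self) -> float:
        return self.images[0].tr

    @property
    def n_volumes(self) -> int:
        return self.images[0].n_volumes

    def map(self, fn) -> "SubjectEnsemble":
        return SubjectEnsemble([fn(img) for img in self.images])


@dataclass
class PhaseField:
    """Per-voxel instantaneous phase (radians in (-pi, pi])."""

    data: np.ndarray  # (x, y, z, t)
    tr: float
    mask: np.ndarray
    subject_id: str = "sub-01"


@dataclass
class SimilarityField:
    """One subject's leave-one-out phase similarity series, in [-1, 1]."""

    data: np.ndarray  # (x, y, z, t)
    tr: float
    mask: np.ndarray
    subject_id: str = "sub-01"


@dataclass
class StatMap:
    """A 3D per-voxel statistic with degrees of freedom and provenance."""

    data: np.ndarray  # (x, y, z); NaN outside mask
    statistic: str  # beta | t | r | fisher_z
    mask: np.ndarray
    df: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.data.shape != self.mask.shape:
            raise InvalidArgumentError("stat map and mask shapes differ")
        if self.statistic == "t" and (self.df is None or self.df <= 0):
            raise InvalidArgumentError("t maps require df > 0")

    def in_mask(self) -> np.ndarray:
        return self.data[self.mask]


class TraitTable:
    """Per-subject questionnaire scores used as second-level covariates.

    Thin wrapper over a DataFrame indexed by subject_id; validates that
    requested columns have no missing values and sit within the
    instrument ranges.
    """

    def __init__(self, df: pd.DataFrame):
        if "subject_id" in df.columns:
            df = df.set_index("subject_id")
        self.df = df.copy()
        for col, (lo, hi) in INSTRUMENT_RANGES.items():
            if col in self.df.columns:
                v = self.df[col]
                if v.isna().any():
                    raise InvalidArgumentError(f"missing values in {col}")
                if (v < lo).any() or (v > hi).any():
                    raise InvalidArgumentError(
                        f"{col} outside instrument range [{lo}, {hi}]"
                    )

    @property
    def n_subjects(self) -> int:
        return len(self.df)

    def covariates(self, names, standardize: bool = True) -> np.ndarray:
        """Return the (n_subjects, len(names)) covariate matrix."""
        missing = [n for n in names if n not in self.df.columns]
        if missing:
            raise InvalidArgumentError(f"unknown trait columns: {missing}")
        X = self.df[list(names)].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise InvalidArgumentError("missing values in requested covariates")
        if standardize:
            sd = X.std(axis=0, ddof=1)
            if np.any(sd == 0):
                raise InvalidArgumentError("constant covariate cannot be standardized")
            X = (X - X.mean(axis=0)) / sd
        return X


@dataclass
class SecondLevelModel:
    """Specification of the group-level covariate model."""

    covariates: list  # trait column names (intercept is implicit)
    contrast: str

    def __post_init__(self) -> None:
        if self.contrast not in self.covariates:
            raise InvalidArgumentError(
                f"contrast {self.contrast!r} not among covariates {self.covariates}"
            )
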