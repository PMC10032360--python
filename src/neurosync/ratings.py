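"""Continuous stimulus ratings: rater aggregation, reliability, and the
HRF-convolved regressor on the TR grid.

A panel of raters continuously judged the presence of biological motion
in the movie stimulus.  The panel is averaged, linearly regridded onto
volume-acquisition times, and convolved with the canonical double-gamma
hemodynamic response function to form the regressor used by both the
magnitude (GLM) and synchronization (ISPS) arms.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .exceptions import (
    InsufficientCoverageError,
    InvalidArgumentError,
    InvalidStateError,
    UndefinedStatisticError,
)
from .types import RatingTrace, Regressor

__all__ = [
    "average_raters",
    "intraclass_correlation",
    "resample_to_tr",
    "hrf_convolve",
    "canonical_hrf",
]


def _check_common_grid(traces) -> None:
    if len(traces) < 2:
        raise InvalidArgumentError("need at least two rater traces")
    t0 = traces[0].times
    for tr in traces[1:]:
        if tr.times.shape != t0.shape or np.max(np.abs(tr.times - t0)) > 1e-6:
            raise InvalidArgumentError("rater traces are on different time grids")


def average_raters(traces) -> RatingTrace:
    """Pointwise arithmetic mean of rater traces sharing one time grid."""
    _check_common_grid(traces)
    values = np.mean([t.values for t in traces], axis=0)
    return RatingTrace(traces[0].times.copy(), values, rater_id="mean")


def intraclass_correlation(traces, variant: str = "icc2") -> float:
    """Inter-rater reliability of a rater panel.

    The default ``icc2`` is ICC(2,1): two-way random effects, absolute
    agreement, single rater — the standard choice when a fixed panel is
    meant to generalize to a population of raters.  ``icc3`` (two-way
    mixed, consistency) is available for sensitivity analysis.

    Computed from the timepoint x rater mean-squares decomposition:

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
        ICC(3,1) = (MSR - MSE) / (MSR + (k-1) MSE)
    """
    _check_common_grid(traces)
    X = np.column_stack([t.values for t in traces])  # (n timepoints, k raters)
    n, k = X.shape
    if n < 2:
        raise InvalidArgumentError("need at least two timepoints")
    grand = X.mean()
    ss_total = np.sum((X - grand) ** 2)
    if ss_total <= 1e-300:
        raise UndefinedStatisticError("zero total variance: ICC undefined")
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if variant == "icc2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif variant == "icc3":
        denom = msr + (k - 1) * mse
    else:
        raise InvalidArgumentError(f"unknown ICC variant {variant!r}")
    if denom == 0:
        raise UndefinedStatisticError("degenerate mean squares: ICC undefined")
    return float((msr - mse) / denom)


def resample_to_tr(
    trace: RatingTrace,
    tr: float,
    n_volumes: int,
    stimulus_onset_s: float = 0.0,
) -> Regressor:
    """Linearly interpolate a rating trace onto volume-acquisition times.

    Volume k is acquired at scanner time k*tr; the stimulus (and the
    trace's clock) starts at ``stimulus_onset_s``.  Volumes before
    stimulus onset or after its end take the nearest stimulus value
    (fixation padding).
    """
    if tr <= 0:
        raise InvalidArgumentError("tr must be positive")
    if n_volumes < 1:
        raise InvalidArgumentError("n_volumes must be positive")
    span = trace.times[-1] - trace.times[0]
    covered = (n_volumes - 1) * tr - stimulus_onset_s
    if span < covered / 2:
        raise InsufficientCoverageError(
            f"trace spans {span:.1f}s but the scan covers {covered:.1f}s of stimulus"
        )
    vol_times = np.arange(n_volumes) * tr - stimulus_onset_s
    values = np.interp(vol_times, trace.times, trace.values)  # clamps at edges
    return Regressor(values, tr=tr, convolved=False)


def canonical_hrf(
    tr: float,
    duration_s: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``tr``, unit-sum normalized.

    h(t) = Gamma(6,1).pdf(t) - Gamma(16,1).pdf(t)/6 over a 32-s kernel;
    unit-sum normalization gives the convolution a DC gain of 1.
    """
    if tr <= 0 or duration_s <= 0:
        raise InvalidArgumentError("tr and duration must be positive")
    t = np.arange(0.0, duration_s + tr / 2, tr)
    h = stats.gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    h -= undershoot_ratio * stats.gamma.pdf(
        t, undershoot_delay / undershoot_disp, scale=undershoot_disp
    )
    s = h.sum()
    if s <= 0:
        raise InvalidArgumentError("degenerate HRF kernel (increase duration)")
    return h / s


def hrf_convolve(regressor: Regressor, **hrf_kwargs) -> Regressor:
    """Convolve a raw regressor with the canonical HRF, truncated to
    the scan length."""
    if regressor.convolved:
        raise InvalidStateError("regressor is already HRF-convolved")
    kernel = canonical_hrf(regressor.tr, **hrf_kwargs)
    values = np.convolve(regressor.values, kernel)[: regressor.n_volumes]
    return Regressor(values, tr=regressor.tr, convolved=True)
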