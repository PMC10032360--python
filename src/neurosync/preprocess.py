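"""Temporal cleaning of voxel time series.

Two branches share a Savitzky-Golay detrend (240-s window by default);
the synchronization branch additionally band-pass filters to the
0.04-0.07 Hz band in which intersubject phase locking is assessed.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .exceptions import InvalidArgumentError
from .types import BoldImage

__all__ = ["savgol_window_length", "savitzky_golay_detrend", "bandpass"]


def savgol_window_length(window_s: float, tr: float) -> int:
    """Nearest odd number of samples to ``window_s`` seconds."""
    exact = window_s / tr
    lo = int(np.floor(exact))
    lo = lo if lo % 2 == 1 else lo - 1
    hi = lo + 2
    win = lo if abs(exact - lo) <= abs(hi - exact) else hi
    if win < 3:
        raise InvalidArgumentError("window too short for the sampling rate")
    return win


def savitzky_golay_detrend(
    image: BoldImage, window_s: float = 240.0, polyorder: int = 3
) -> BoldImage:
    """Subtract the per-voxel Savitzky-Golay smooth (low-frequency drift).

    Edges are handled by polynomial fits on shrinking windows
    (scipy's ``mode='interp'``), so the operation is bit-reproducible.
    """
    win = savgol_window_length(window_s, image.tr)
    if win < polyorder + 2:
        raise InvalidArgumentError("window must cover at least polyorder + 2 samples")
    if win > image.n_volumes:
        raise InvalidArgumentError(
            f"detrend window ({win} samples) longer than the series "
            f"({image.n_volumes} volumes)"
        )
    out = image.data.copy()
    vox = out[image.mask]  # (V, T)
    trend = signal.savgol_filter(vox, win, polyorder, axis=-1, mode="interp")
    out[image.mask] = vox - trend
    return image.with_data(out, step=f"sgdetrend({window_s}s,p{polyorder})")


def bandpass(
    image: BoldImage, low_hz: float = 0.04, high_hz: float = 0.07, order: int = 2
) -> BoldImage:
    """Zero-phase Butterworth band-pass of every in-mask voxel series.

    Forward-backward application (``sosfiltfilt`` with odd-reflection
    padding) squares the magnitude response and cancels the phase
    response, so band-centred oscillations pass with zero lag.
    """
    nyquist = 0.5 / image.tr
    if not (0 < low_hz < high_hz < nyquist):
        raise InvalidArgumentError(
            f"band ({low_hz}, {high_hz}) Hz outside (0, Nyquist={nyquist:.4f}) Hz"
        )
    sos = signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=1.0 / image.tr, output="sos"
    )
    out = image.data.copy()
    vox = out[image.mask]
    # demean first: the filter kills DC asymptotically but demeaning avoids
    # the edge transient a large offset would leave on a finite series
    vox = vox - vox.mean(axis=-1, keepdims=True)
    out[image.mask] = signal.sosfiltfilt(sos, vox, axis=-1)
    return image.with_data(out, step=f"bandpass({low_hz}-{high_hz}Hz,o{order})")
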