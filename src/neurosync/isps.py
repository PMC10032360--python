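"""Intersubject phase synchronization (ISPS).

Each band-limited voxel series is turned into an instantaneous phase via
the analytic signal; per subject, the leave-one-out phase similarity at
voxel v and time t is the mean circular cosine of the phase difference
with every other subject,

    sim_s(v, t) = (1 / (N-1)) * sum_{j != s} cos(phi_s - phi_j),

a bounded series in [-1, 1] that equals 1 only at perfect alignment.
Its subject mean is tied exactly to the group phase-locking value R by

    mean_s sim_s = (N R^2 - 1) / (N - 1),

which serves as the module's primary correctness oracle.  Each subject's
similarity series is then correlated with the HRF-convolved rating
regressor and Fisher z-transformed for group-level inference.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import hilbert

from .exceptions import InvalidArgumentError
from .types import BoldImage, PhaseField, Regressor, SimilarityField, StatMap

__all__ = [
    "instantaneous_phase",
    "loo_phase_similarity",
    "group_plv",
    "couple_similarity_to_regressor",
]

#: atanh clip bound for |r| = 1
_Z_EPS = 1e-12


def instantaneous_phase(image: BoldImage) -> PhaseField:
    """Phase of the analytic signal (series + i * Hilbert(series)) per voxel.

    Constant (zero-variance) series have no defined phase and are flagged
    NaN within the mask.
    """
    vox = image.data[image.mask]  # (V, T)
    phase = np.angle(hilbert(vox, axis=-1))
    dead = vox.std(axis=-1) == 0
    phase[dead] = np.nan
    out = np.full(image.data.shape, np.nan)
    out[image.mask] = phase
    return PhaseField(out, image.tr, image.mask, image.subject_id)


def _phase_stack(phases) -> np.ndarray:
    mask = phases[0].mask
    for p in phases[1:]:
        if p.data.shape != phases[0].data.shape or not np.array_equal(p.mask, mask):
            raise InvalidArgumentError("phase fields are on different grids")
    return np.stack([p.data[mask] for p in phases])  # (N, V, T)


def loo_phase_similarity(phases, form: str = "cosine"):
    """Leave-one-out phase similarity series, one field per subject.

    ``form='cosine'`` (default) is the circular-cosine similarity above.
    ``form='angular'`` is the angular-distance alternative
    1 - mean_j |wrap(phi_s - phi_j)| / pi, offered for sensitivity
    analysis; the PLV identity holds for the cosine form only.
    NaN phases propagate to the similarity at that (voxel, time).
    """
    if len(phases) < 3:
        raise InvalidArgumentError("leave-one-out similarity needs >= 3 subjects")
    P = _phase_stack(phases)
    n = P.shape[0]
    if form == "cosine":
        Zc = np.exp(1j * P)  # (N, V, T)
        S = Zc.sum(axis=0)
        sims = (np.conj(Zc) * (S[None] - Zc)).real / (n - 1)
    elif form == "angular":
        sims = np.zeros_like(P)
        for s in range(n):
            d = P - P[s][None]
            d = np.abs(np.angle(np.exp(1j * d)))  # wrapped to [0, pi]
            sims[s] = 1.0 - (d.sum(axis=0) - d[s]) / ((n - 1) * np.pi)
    else:
        raise InvalidArgumentError(f"unknown similarity form {form!r}")
    mask = phases[0].mask
    out = []
    for s, ph in enumerate(phases):
        field = np.full(ph.data.shape, np.nan)
        field[mask] = sims[s]
        out.append(SimilarityField(field, ph.tr, mask, ph.subject_id))
    return out


def group_plv(phases) -> np.ndarray:
    """Group phase-locking value R(v, t) = |mean_j exp(i phi_j)| in [0, 1].

    Returned on the full grid with NaN outside the mask.
    """
    if len(phases) < 2:
        raise InvalidArgumentError("group PLV needs >= 2 subjects")
    P = _phase_stack(phases)
    R = np.abs(np.exp(1j * P).mean(axis=0))
    out = np.full(phases[0].data.shape, np.nan)
    out[phases[0].mask] = R
    return out


def couple_similarity_to_regressor(
    similarity: SimilarityField,
    regressor: Regressor,
    edge_exclude: int = 10,
) -> StatMap:
    """Correlate each voxel's similarity series with the convolved
    regressor; Fisher z-transform the r map.

    The first and last ``edge_exclude`` samples are dropped to avoid
    Hilbert end effects.  Zero-variance similarity series give NaN;
    |r| = 1 is clipped to atanh(1 - 1e-12) with a warning.
    """
    if not regressor.convolved:
        raise InvalidArgumentError("coupling requires the HRF-convolved regressor")
    T = similarity.data.shape[-1]
    if regressor.n_volumes != T:
        raise InvalidArgumentError("regressor and similarity lengths differ")
    sl = slice(edge_exclude, T - edge_exclude if edge_exclude else T)
    x = regressor.values[sl]
    if len(x) < 3:
        raise InvalidArgumentError("too few samples after edge exclusion")
    Y = similarity.data[similarity.mask][:, sl]  # (V, T')
    xc = x - x.mean()
    yc = Y - Y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum() * (yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (yc @ xc) / denom
    r[denom == 0] = np.nan
    if np.nanmax(np.abs(r), initial=0.0) >= 1.0 - _Z_EPS:
        warnings.warn("similarity-regressor |r| at 1; Fisher z clipped", stacklevel=2)
    z = np.arctanh(np.clip(r, -1 + _Z_EPS, 1 - _Z_EPS))
    out = np.full(similarity.mask.shape, np.nan)
    out[similarity.mask] = z
    return StatMap(
        out,
        "fisher_z",
        similarity.mask,
        provenance=f"ISPS-regressor coupling, subject {similarity.subject_id}",
    )
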