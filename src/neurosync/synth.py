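"""Synthetic multi-subject BOLD ensembles with planted ground truth.

The generator emulates the statistical structure the two analysis arms
assume: a slow bounded rating trace judged by a small rater panel with
moderate agreement, integer trait scores with realistic inter-trait
correlations, and brain regions in which BOLD amplitude and/or
intersubject phase synchrony co-vary (positively or negatively) with the
rating.

Four signed archetypes span the quadrants of the activity/synchrony
overlay:

``AMP+SYNC+``  amplitude rises with the rating AND subjects' band-limited
               phases align when the rating is high (convergent positive).
``AMP+SYNC-``  amplitude rises while phases scatter (the shared
               oscillation's weight falls) as the rating rises.
``AMP-SYNC+``  amplitude falls with the rating; phases align when it is
               high.
``AMP-SYNC-``  amplitude falls and phases scatter (convergent negative).

Synchrony is produced by mixing one shared band-limited (0.04-0.07 Hz)
oscillation per region with a subject-specific band-limited series; the
shared weight tracks the min-max-normalized convolved rating (reversed
for SYNC-).  Trait effects scale a subject's amplitude beta or shared
mixing weight by (1 + sign * magnitude * z(trait)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .exceptions import InvalidArgumentError
from .ratings import hrf_convolve, intraclass_correlation
from .types import BoldImage, RatingTrace, Regressor, SubjectEnsemble, TraitTable

__all__ = [
    "RegionSpec",
    "TraitEffect",
    "SimulationConfig",
    "GroundTruth",
    "ARCHETYPE_CODES",
    "default_region_layout",
    "generate_rating_trace",
    "generate_rater_panel",
    "estimate_panel_icc",
    "calibrate_rater_noise",
    "generate_trait_table",
    "generate_ensemble",
]

#: integer codes shared with the inference quadrant legend
ARCHETYPE_CODES = {
    "null": 0,
    "AMP+SYNC+": 1,
    "AMP+SYNC-": 2,
    "AMP-SYNC+": 3,
    "AMP-SYNC-": 4,
}

#: target marginal means (Table-style descriptives) for trait binning:
#: binomial success probabilities = mean / n_items
_TRAIT_MARGINALS = {
    "aq_total": (50, 16.8 / 50),
    "olife_total": (43, 11.2 / 43),
    "aq_social_skills": (10, 3.1 / 10),
    "olife_introversion": (10, 2.2 / 10),
}


@dataclass(frozen=True)
class RegionSpec:
    """A cuboid region with a signed archetype and effect sizes.

    ``amp_effect`` is the amplitude beta in noise-SD units (sign taken
    from the archetype); ``sync_effect`` is the amplitude of the
    band-limited oscillation that carries the synchrony effect.
    """

    label: str
    archetype: str
    box: tuple  # (x0, x1, y0, y1, z0, z1), half-open
    amp_effect: float = 0.5
    sync_effect: float = 1.0

    def slices(self):
        x0, x1, y0, y1, z0, z1 = self.box
        return (slice(x0, x1), slice(y0, y1), slice(z0, z1))


@dataclass(frozen=True)
class TraitEffect:
    """Scale a region's amplitude beta or shared synchrony weight by
    (1 + sign * magnitude * z(trait)) per subject."""

    trait: str
    region: str
    sign: int = -1
    magnitude: float = 0.4
    on: str = "amplitude"  # or "synchrony"


def default_region_layout(grid=(16, 16, 8)):
    """Four disjoint 4x4x4 archetype regions inside the default grid."""
    nx, ny, nz = grid
    if nx < 14 or ny < 14 or nz < 7:
        raise InvalidArgumentError("default layout needs a grid of at least 14x14x7")
    return (
        RegionSpec("convergent_pos", "AMP+SYNC+", (2, 6, 2, 6, 1, 5)),
        RegionSpec("amp_only_pos", "AMP+SYNC-", (10, 14, 2, 6, 1, 5)),
        RegionSpec("sync_only_pos", "AMP-SYNC+", (2, 6, 10, 14, 3, 7)),
        RegionSpec("convergent_neg", "AMP-SYNC-", (10, 14, 10, 14, 3, 7)),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic ensemble."""

    n_subjects: int = 20
    grid: tuple = (16, 16, 8)
    n_volumes: int = 460
    tr: float = 2.6
    region_specs: tuple = field(default_factory=default_region_layout)
    trait_effects: tuple = ()
    noise_sd: float = 1.0
    ar_coefficient: float = 0.3
    band: tuple = (0.04, 0.07)
    w_lo: float = 0.1  # shared-weight floor of the synchrony mixing ramp
    w_hi: float = 0.9  # shared-weight ceiling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_volumes < 2:
            raise InvalidArgumentError("need >= 1 subject and >= 2 volumes")
        if self.n_volumes * self.tr < 2.0 / self.band[0]:
            raise InvalidArgumentError(
                "series too short to resolve the synchrony band"
            )
        if not (0 <= self.ar_coefficient < 1):
            raise InvalidArgumentError("AR coefficient must be in [0, 1)")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be nonnegative")
        seen = {}
        occupied = np.zeros(self.grid, dtype=bool)
        for rs in self.region_specs:
            if rs.archetype not in ARCHETYPE_CODES or rs.archetype == "null":
                raise InvalidArgumentError(f"unknown archetype {rs.archetype!r}")
            if not np.isfinite(rs.amp_effect) or rs.amp_effect < 0:
                raise InvalidArgumentError("amp_effect must be finite and nonnegative")
            if not np.isfinite(rs.sync_effect) or rs.sync_effect < 0:
                raise InvalidArgumentError("sync_effect must be finite and nonnegative")
            if rs.label in seen:
                raise InvalidArgumentError(f"duplicate region label {rs.label!r}")
            seen[rs.label] = rs
            sl = rs.slices()
            if occupied[sl].any():
                raise InvalidArgumentError(f"region {rs.label!r} overlaps another region")
            occupied[sl] = True
        for te in self.trait_effects:
            if te.region not in seen:
                raise InvalidArgumentError(f"trait effect names unknown region {te.region!r}")
            if te.on not in ("amplitude", "synchrony"):
                raise InvalidArgumentError("trait effect 'on' must be amplitude|synchrony")
            if not np.isfinite(te.magnitude) or te.magnitude < 0:
                raise InvalidArgumentError("trait magnitude must be finite and nonnegative")


@dataclass
class GroundTruth:
    """Planted per-voxel archetype labels and trait-effect signs."""

    labels: np.ndarray  # 3D int array, codes per ARCHETYPE_CODES
    legend: dict
    trait_signs: dict  # (trait, region, on) -> sign

    def region_mask(self, code_or_name) -> np.ndarray:
        code = (
            ARCHETYPE_CODES[code_or_name]
            if isinstance(code_or_name, str)
            else code_or_name
        )
        return self.labels == code


def _smooth_bounded(n: int, dt: float, rng, cutoff_hz: float) -> np.ndarray:
    """Low-pass-filtered white noise, min-max scaled to [0, 1]."""
    x = rng.standard_normal(n + 200)
    sos = signal.butter(2, cutoff_hz, btype="lowpass", fs=1.0 / dt, output="sos")
    x = signal.sosfiltfilt(sos, x)[100:-100]
    lo, hi = x.min(), x.max()
    if hi - lo == 0:
        return np.full(n, 0.5)
    return (x - lo) / (hi - lo)


def generate_rating_trace(
    duration_s: float, dt: float, seed: int, cutoff_hz: float = 0.02
) -> RatingTrace:
    """A slow bounded rating trace in [0, 1], sampled every ``dt`` seconds.

    The trace is low-pass-filtered Gaussian noise (0.02 Hz cutoff by
    default), mimicking the slow envelope of a continuous rating of a
    movie stimulus while keeping its power below both the GLM high-pass
    band edge's complement and the synchrony band.
    """
    if duration_s <= 0 or dt <= 0:
        raise InvalidArgumentError("duration and dt must be positive")
    n = int(round(duration_s / dt))
    if n < 2:
        raise InvalidArgumentError("duration too short for the sampling interval")
    rng = np.random.default_rng(seed)
    values = _smooth_bounded(n, dt, rng, cutoff_hz)
    return RatingTrace(np.arange(n) * dt, values, rater_id="truth")


def generate_rater_panel(
    trace: RatingTrace,
    n_raters: int = 5,
    rater_noise_sd: float = 0.15,
    seed: int = 0,
    cutoff_hz: float = 0.05,
):
    """Per-rater traces = shared trace + smooth rater noise, clipped to [0, 1].

    Rater noise is itself low-pass filtered (raters drift slowly, they do
    not jitter sample to sample), so expected agreement falls smoothly as
    ``rater_noise_sd`` grows.
    """
    if n_raters < 2:
        raise InvalidArgumentError("a rater panel needs at least 2 raters")
    if rater_noise_sd < 0:
        raise InvalidArgumentError("rater_noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    panel = []
    for i in range(n_raters):
        if rater_noise_sd == 0:
            vals = trace.values.copy()
        else:
            noise = _smooth_bounded(len(trace.values), trace.dt, rng, cutoff_hz)
            noise = noise - noise.mean()
            s = noise.std()
            noise = noise / s * rater_noise_sd if s > 0 else noise
            vals = np.clip(trace.values + noise, 0.0, 1.0)
        panel.append(RatingTrace(trace.times.copy(), vals, rater_id=f"rater-{i + 1:02d}"))
    return panel


def estimate_panel_icc(
    trace: RatingTrace,
    n_raters: int,
    rater_noise_sd: float,
    seed: int = 0,
    n_reps: int = 20,
) -> float:
    """Monte-Carlo expected ICC(2,1) of the rater panel."""
    ss = np.random.SeedSequence((seed, 2_000_003))
    vals = []
    for child in ss.spawn(n_reps):
        panel = generate_rater_panel(
            trace, n_raters, rater_noise_sd, seed=int(child.generate_state(1)[0] % 2**31)
        )
        vals.append(intraclass_correlation(panel))
    return float(np.mean(vals))


def calibrate_rater_noise(
    trace: RatingTrace,
    n_raters: int = 5,
    target_icc: float = 0.57,
    seed: int = 0,
    tol: float = 0.01,
    n_reps: int = 20,
    max_iter: int = 40,
) -> float:
    """Bisection on ``rater_noise_sd`` so the expected panel ICC(2,1)
    hits ``target_icc`` (expected ICC is monotone non-increasing in the
    noise level)."""
    lo, hi = 1e-4, 5.0
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        icc = estimate_panel_icc(trace, n_raters, mid, seed=seed, n_reps=n_reps)
        if abs(icc - target_icc) < tol:
            return float(mid)
        if icc > target_icc:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def _latent_correlation(target_total: float, target_social: float) -> np.ndarray:
    """Latent Gaussian correlation among
    (aq_total, olife_total, aq_social_skills, olife_introversion)."""
    part_whole = 0.6  # total vs own subscale
    cross = 0.6 * target_total  # total vs the other instrument's subscale
    C = np.array(
        [
            [1.0, target_total, part_whole, cross],
            [target_total, 1.0, cross, part_whole],
            [part_whole, cross, 1.0, target_social],
            [cross, part_whole, target_social, 1.0],
        ]
    )
    return C


def generate_trait_table(
    n_subjects: int,
    target_corr_total: float = 0.305,
    target_corr_social: float = 0.528,
    seed: int = 0,
) -> TraitTable:
    """Integer AQ / O-LIFE totals and social subscales via a latent
    Gaussian copula binned onto binomial marginals.

    Marginal means approximate published descriptives (AQ 16.8/50,
    O-LIFE 11.2/43, social skills 3.1/10, introvertive anhedonia 2.2/10).
    """
    if abs(target_corr_total) >= 1 or abs(target_corr_social) >= 1:
        raise InvalidArgumentError("|target correlations| must be < 1")
    C = _latent_correlation(target_corr_total, target_corr_social)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as err:
        raise InvalidArgumentError(
            "infeasible correlation targets (latent matrix not positive definite)"
        ) from err
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_subjects, 4)) @ L.T
    U = stats.norm.cdf(Z)
    cols = {}
    for j, (name, (n_items, p)) in enumerate(_TRAIT_MARGINALS.items()):
        cols[name] = stats.binom.ppf(U[:, j], n_items, p).astype(int)
    df = pd.DataFrame(cols, index=[f"sub-{i + 1:02d}" for i in range(n_subjects)])
    df.index.name = "subject_id"
    return TraitTable(df)


def _ar1(rng, shape, ar: float, sd: float, burn: int = 50) -> np.ndarray:
    """Stationary AR(1) noise with marginal SD ``sd`` along the last axis."""
    if sd == 0:
        return np.zeros(shape)
    T = shape[-1]
    e = rng.standard_normal(shape[:-1] + (T + burn,))
    x = signal.lfilter([1.0], [1.0, -ar], e, axis=-1)[..., burn:]
    return x * (sd * np.sqrt(1.0 - ar**2))


def _band_limited(rng, n: int, tr: float, band, burn: int = 100) -> np.ndarray:
    """Unit-SD band-limited Gaussian series."""
    sos = signal.butter(2, band, btype="bandpass", fs=1.0 / tr, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n + 2 * burn))[burn:-burn]
    return (x - x.mean()) / x.std()


def generate_ensemble(
    config: SimulationConfig,
    regressor: Regressor,
    traits: TraitTable | None = None,
):
    """Generate the multi-subject ensemble and its ground truth.

    ``regressor`` is the rating regressor on the TR grid (convolved with
    the HRF internally if it is not already).  When ``config`` plants
    trait effects, ``traits`` must hold one row per subject.
    """
    if regressor.n_volumes != config.n_volumes:
        raise InvalidArgumentError(
            f"regressor has {regressor.n_volumes} samples, "
            f"config expects {config.n_volumes}"
        )
    if config.trait_effects and traits is None:
        raise InvalidArgumentError("trait effects planted but no trait table given")
    if traits is not None and traits.n_subjects != config.n_subjects:
        raise InvalidArgumentError(
            f"{traits.n_subjects} trait rows for {config.n_subjects} subjects"
        )
    conv = regressor if regressor.convolved else hrf_convolve(regressor)
    c = conv.values
    c_hat = (c - c.mean()) / c.std()  # unit-SD amplitude carrier
    rng_m = c.max() - c.min()
    m = (c - c.min()) / rng_m if rng_m > 0 else np.full_like(c, 0.5)

    # standardized trait columns for planted modulations
    zcols = {}
    for te in config.trait_effects:
        if te.trait not in zcols:
            zcols[te.trait] = traits.covariates([te.trait], standardize=True)[:, 0]

    root = np.random.SeedSequence((config.seed, 1_000_003))
    ens_rng = np.random.default_rng(root.spawn(1)[0])
    subj_seeds = root.spawn(config.n_subjects)

    # one shared oscillation per region per ensemble
    shared = {
        rs.label: _band_limited(ens_rng, config.n_volumes, config.tr, config.band)
        for rs in config.region_specs
    }

    labels = np.zeros(config.grid, dtype=np.int16)
    for rs in config.region_specs:
        labels[rs.slices()] = ARCHETYPE_CODES[rs.archetype]
    trait_signs = {
        (te.trait, te.region, te.on): te.sign for te in config.trait_effects
    }
    truth = GroundTruth(labels, {v: k for k, v in ARCHETYPE_CODES.items()}, trait_signs)

    mask = np.ones(config.grid, dtype=bool)
    w_lo, w_hi = config.w_lo, config.w_hi
    images = []
    for s_idx, seed_s in enumerate(subj_seeds):
        rng = np.random.default_rng(seed_s)
        data = _ar1(
            rng, config.grid + (config.n_volumes,), config.ar_coefficient, config.noise_sd
        )
        for rs in config.region_specs:
            amp_sign = 1.0 if rs.archetype.startswith("AMP+") else -1.0
            sync_pos = rs.archetype.endswith("SYNC+")
            beta = amp_sign * rs.amp_effect
            w_gain = 1.0
            for te in config.trait_effects:
                if te.region != rs.label:
                    continue
                factor = 1.0 + te.sign * te.magnitude * zcols[te.trait][s_idx]
                if te.on == "amplitude":
                    beta *= factor
                else:
                    w_gain *= factor
            series = beta * c_hat
            if rs.sync_effect > 0:
                ramp = m if sync_pos else 1.0 - m
                w = np.clip((w_lo + (w_hi - w_lo) * ramp) * w_gain, 0.0, 1.0)
                eta = _band_limited(rng, config.n_volumes, config.tr, config.band)
                series = series + rs.sync_effect * (
                    w * shared[rs.label] + (1.0 - w) * eta
                )
            data[rs.slices()] += series
        images.append(
            BoldImage(
                data,
                config.tr,
                mask,
                subject_id=f"sub-{s_idx + 1:02d}",
                provenance=("synthetic",),
            )
        )
    return SubjectEnsemble(images), truth
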