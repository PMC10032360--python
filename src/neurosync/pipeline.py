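"""End-to-end orchestration of the two analysis arms.

The magnitude (GLM) arm: detrend -> first-level OLS per subject ->
group one-sample t and trait regressions -> permutation cluster
correction.  The synchronization (ISPS) arm: detrend -> band-pass ->
instantaneous phase -> leave-one-out phase similarity -> per-subject
coupling with the regressor -> the same group stages.  Both arms are
pure functions of (inputs, parameters, seed).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as nio
from .exceptions import InvalidArgumentError
from .glm import build_design, fit_first_level, second_level_one_sample, second_level_regression
from .inference import permutation_correct, quadrant_overlay
from .isps import couple_similarity_to_regressor, instantaneous_phase, loo_phase_similarity
from .preprocess import bandpass, savitzky_golay_detrend
from .ratings import average_raters, hrf_convolve, intraclass_correlation, resample_to_tr
from .types import Regressor, SecondLevelModel, SubjectEnsemble, TraitTable

logger = logging.getLogger("neurosync")

__all__ = ["AnalysisParams", "RunConfig", "prepare_regressor", "run_glm_arm",
           "run_isps_arm", "run_both_arms", "report"]


@dataclass
class AnalysisParams:
    """Every analysis number in a run traces back to one of these fields."""

    tr: float = 2.6
    n_volumes: int = 460
    onset_s: float = 0.0
    detrend_window_s: float = 240.0
    detrend_polyorder: int = 3
    band: tuple = (0.04, 0.07)
    hp_cutoff_s: float = 128.0
    similarity: str = "cosine"
    edge_exclude: int = 10
    voxel_p: float = 0.001
    n_perm: int = 500
    alpha: float = 0.05
    cluster_stat: str = "mass"
    connectivity: int = 26
    covariates: tuple = ()
    contrasts: tuple = ()  # subset of covariates to test
    seed: int = 0

    def validate(self) -> None:
        nyquist = 0.5 / self.tr
        if not (0 < self.band[0] < self.band[1] < nyquist):
            raise InvalidArgumentError(
                f"band {self.band} outside (0, Nyquist={nyquist:.4f}) Hz"
            )
        if not (0 < self.voxel_p < 1):
            raise InvalidArgumentError("voxel_p must be in (0, 1)")
        for c in self.contrasts:
            if c not in self.covariates:
                raise InvalidArgumentError(f"contrast {c!r} not among covariates")


@dataclass
class RunConfig:
    """Paths plus parameters for a disk-based run."""

    ensemble_dir: str
    ratings_path: str
    out_dir: str
    traits_path: str | None = None
    params: AnalysisParams = field(default_factory=AnalysisParams)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = nio.load_yaml(path)
        params = AnalysisParams(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.get("params", {}).items()
        })
        return cls(
            ensemble_dir=raw["ensemble_dir"],
            ratings_path=raw["ratings_path"],
            out_dir=raw["out_dir"],
            traits_path=raw.get("traits_path"),
            params=params,
        )

    def validate(self) -> None:
        self.params.validate()
        for p in (self.ensemble_dir, self.ratings_path, self.traits_path):
            if p is not None and not Path(p).exists():
                raise InvalidArgumentError(f"path does not exist: {p}")


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def _done(name: str, t0: float) -> None:
    logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)


def prepare_regressor(traces, params: AnalysisParams):
    """Average the rater panel, regrid to the TR grid, convolve with the
    HRF. Returns (convolved regressor, panel ICC or None)."""
    icc = None
    if len(traces) >= 2:
        icc = intraclass_correlation(traces)
        mean_trace = average_raters(traces)
    else:
        mean_trace = traces[0]
    raw = resample_to_tr(mean_trace, params.tr, params.n_volumes, params.onset_s)
    return hrf_convolve(raw), icc


def _group_stage(maps, traits, params: AnalysisParams, arm: str):
    """Shared second-level machinery: one-sample t + permutation cluster
    tables for both tails, plus one trait-regression table per contrast."""
    out = {}
    out["group_t"] = second_level_one_sample(maps)
    for tail in ("positive", "negative"):
        out[f"clusters_{tail}"] = permutation_correct(
            maps,
            n_perm=params.n_perm,
            voxel_p=params.voxel_p,
            seed=params.seed,
            tail=tail,
            alpha=params.alpha,
            connectivity=params.connectivity,
            cluster_stat=params.cluster_stat,
        )
    if traits is not None and params.covariates:
        out["trait_t"] = {}
        out["trait_clusters"] = {}
        for contrast in params.contrasts:
            model = SecondLevelModel(list(params.covariates), contrast)
            out["trait_t"][contrast] = second_level_regression(
                maps, traits, params.covariates, contrast
            )
            out["trait_clusters"][contrast] = {
                tail: permutation_correct(
                    maps,
                    model=model,
                    traits=traits,
                    n_perm=params.n_perm,
                    voxel_p=params.voxel_p,
                    seed=params.seed,
                    tail=tail,
                    alpha=params.alpha,
                    connectivity=params.connectivity,
                    cluster_stat=params.cluster_stat,
                    fdr=True,
                )
                for tail in ("positive", "negative")
            }
    logger.info("%s arm: group stages complete", arm)
    return out


def run_glm_arm(
    ensemble: SubjectEnsemble,
    regressor: Regressor,
    traits: TraitTable | None = None,
    params: AnalysisParams | None = None,
) -> dict:
    """Magnitude arm: detrend, first-level OLS, group inference."""
    params = params or AnalysisParams(tr=ensemble.tr, n_volumes=ensemble.n_volumes)
    params.validate()
    t0 = _stage("glm:detrend")
    detrended = ensemble.map(
        lambda im: savitzky_golay_detrend(im, params.detrend_window_s, params.detrend_polyorder)
    )
    _done("glm:detrend", t0)
    design = build_design(regressor, params.hp_cutoff_s)
    t0 = _stage("glm:first-level")
    betas, tmaps = [], []
    for img in detrended.images:
        b, t = fit_first_level(img, design)
        betas.append(b)
        tmaps.append(t)
    _done("glm:first-level", t0)
    out = {"beta_maps": betas, "t_maps": tmaps, "design": design}
    out.update(_group_stage(betas, traits, params, arm="glm"))
    return out


def run_isps_arm(
    ensemble: SubjectEnsemble,
    regressor: Regressor,
    traits: TraitTable | None = None,
    params: AnalysisParams | None = None,
) -> dict:
    """Synchronization arm: band-limited phase, leave-one-out similarity,
    coupling to the regressor, group inference."""
    params = params or AnalysisParams(tr=ensemble.tr, n_volumes=ensemble.n_volumes)
    params.validate()
    t0 = _stage("isps:preprocess")
    cleaned = ensemble.map(
        lambda im: bandpass(
            savitzky_golay_detrend(im, params.detrend_window_s, params.detrend_polyorder),
            params.band[0],
            params.band[1],
        )
    )
    _done("isps:preprocess", t0)
    t0 = _stage("isps:phase-similarity")
    phases = [instantaneous_phase(im) for im in cleaned.images]
    sims = loo_phase_similarity(phases, form=params.similarity)
    _done("isps:phase-similarity", t0)
    t0 = _stage("isps:coupling")
    zmaps = [
        couple_similarity_to_regressor(s, regressor, edge_exclude=params.edge_exclude)
        for s in sims
    ]
    _done("isps:coupling", t0)
    out = {"similarity_fields": sims, "coupling_maps": zmaps}
    out.update(_group_stage(zmaps, traits, params, arm="isps"))
    return out


def run_both_arms(
    ensemble: SubjectEnsemble,
    regressor: Regressor,
    traits: TraitTable | None = None,
    params: AnalysisParams | None = None,
) -> dict:
    """Both arms plus the quadrant overlay of their cluster results."""
    glm_res = run_glm_arm(ensemble, regressor, traits, params)
    isps_res = run_isps_arm(ensemble, regressor, traits, params)
    alpha = (params or AnalysisParams()).alpha
    quadrant = quadrant_overlay(
        glm_res["clusters_positive"],
        glm_res["clusters_negative"],
        isps_res["clusters_positive"],
        isps_res["clusters_negative"],
        alpha=alpha,
    )
    return {"glm": glm_res, "isps": isps_res, "quadrant": quadrant}


def run_from_config(config: RunConfig) -> dict:
    """Disk-based run: load inputs, run both arms, write all artifacts."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ensemble = nio.load_ensemble(config.ensemble_dir)
    traces = nio.load_traces(config.ratings_path)
    params = config.params
    params.tr = ensemble.tr
    params.n_volumes = ensemble.n_volumes
    regressor, icc = prepare_regressor(traces, params)
    traits = nio.load_traits(config.traits_path) if config.traits_path else None

    results = run_both_arms(ensemble, regressor, traits, params)

    for arm in ("glm", "isps"):
        res = results[arm]
        maps = res["beta_maps"] if arm == "glm" else res["coupling_maps"]
        suffix = "beta" if arm == "glm" else "ispsz"
        for m, img in zip(maps, ensemble.images):
            nio.save_statmap(out / f"{img.subject_id}_{suffix}.nii.gz", m)
        nio.save_statmap(out / f"{arm}_group_t.nii.gz", res["group_t"])
        for tail in ("positive", "negative"):
            nio.save_cluster_table(out / f"{arm}_clusters_{tail}.tsv", res[f"clusters_{tail}"])
        for contrast, tails in res.get("trait_clusters", {}).items():
            for tail, cr in tails.items():
                nio.save_cluster_table(out / f"{arm}_trait_{contrast}_{tail}.tsv", cr)
    nio.save_quadrant_map(out / "quadrant.nii.gz", results["quadrant"])
    manifest = {"params": asdict(params), "panel_icc": icc,
                "n_subjects": ensemble.n_subjects}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    text = report(results, params, panel_icc=icc)
    (out / "report.txt").write_text(text)
    return results


def _table_lines(name: str, cr) -> list:
    lines = [f"  {name}:"]
    if len(cr.table) == 0:
        lines.append("    no suprathreshold clusters")
        return lines
    for _, row in cr.table.iterrows():
        lines.append(
            f"    cluster {int(row['label'])}: k={int(row['size'])}, "
            f"peak t={row['peak_stat']:.2f} at "
            f"({int(row['peak_x'])},{int(row['peak_y'])},{int(row['peak_z'])}), "
            f"p_unc={row['p_uncorrected']:.4f}, p_fwe={row['p_corrected']:.4f}"
        )
    return lines


def report(results: dict, params: AnalysisParams, panel_icc=None) -> str:
    """Human-readable run summary: cluster tables, quadrant counts,
    trait-association signs, and every parameter/seed used."""
    lines = ["# Two-arm naturalistic fMRI analysis report", ""]
    lines.append(f"parameters: {asdict(params)}")
    if panel_icc is not None:
        lines.append(f"rater panel ICC(2,1): {panel_icc:.3f}")
    lines.append("")
    for arm in ("glm", "isps"):
        if arm not in results:
            lines.append(f"## {arm.upper()} arm: MISSING (arm did not run)")
            continue
        res = results[arm]
        lines.append(f"## {arm.upper()} arm")
        for tail in ("positive", "negative"):
            lines.extend(_table_lines(f"{tail} clusters", res[f"clusters_{tail}"]))
        for contrast, tails in res.get("trait_clusters", {}).items():
            for tail, cr in tails.items():
                lines.extend(_table_lines(f"trait {contrast} ({tail})", cr))
        if "trait_t" in res:
            for contrast, tmap in res["trait_t"].items():
                vals = tmap.in_mask()
                vals = vals[np.isfinite(vals)]
                sign = "negative" if np.nanmedian(vals) < 0 else "positive"
                lines.append(
                    f"  trait {contrast}: median voxel t {np.nanmedian(vals):+.2f} ({sign})"
                )
        lines.append("")
    if "quadrant" in results:
        lines.append("## Quadrant overlay (both-arm conjunction)")
        for name, count in results["quadrant"].counts().items():
            lines.append(f"  {name}: {count} voxels")
    return "\n".join(lines)
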