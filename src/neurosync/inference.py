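"""Cluster formation, permutation-based family-wise error control, and
the quadrant overlay of GLM and ISPS results.

Voxels passing an uncorrected threshold (p < 0.001 by default) are
grouped into connected components (26-connectivity by default).  Family
-wise control uses the nonparametric max-statistic permutation test:
sign-flipping of subject maps for the one-sample model, whole-row
permutation of the trait covariates for the regression model.  The
permutation statistic is the cluster mass (sum of |t| over the cluster)
by default; cluster extent is available via ``cluster_stat='size'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InvalidArgumentError, ResolutionError
from .types import SecondLevelModel, StatMap, TraitTable

__all__ = [
    "ClusterResult",
    "QuadrantMap",
    "form_clusters",
    "permutation_correct",
    "quadrant_overlay",
    "QUADRANT_LEGEND",
]

QUADRANT_LEGEND = {
    0: "none",
    1: "GLM+ISPS+",
    2: "GLM+ISPS-",
    3: "GLM-ISPS+",
    4: "GLM-ISPS-",
}

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ClusterResult:
    """A cluster table plus the labelled 3D component array."""

    table: pd.DataFrame  # label, size, peak_{x,y,z}, peak_stat, p_uncorrected, p_corrected
    labels: np.ndarray  # 3D int, 0 = background
    tail: str
    voxel_threshold: float

    def significant_mask(self, alpha: float = 0.05) -> np.ndarray:
        """Union of clusters with corrected p <= alpha (all clusters when
        no permutation p values are attached)."""
        if len(self.table) == 0:
            return np.zeros(self.labels.shape, dtype=bool)
        pc = self.table["p_corrected"]
        keep = self.table["label"] if pc.isna().all() else self.table.loc[pc <= alpha, "label"]
        return np.isin(self.labels, list(keep))


@dataclass
class QuadrantMap:
    """Sign-pair overlay of GLM and ISPS suprathreshold membership."""

    labels: np.ndarray  # 3D int codes per QUADRANT_LEGEND
    legend: dict = field(default_factory=lambda: dict(QUADRANT_LEGEND))

    def counts(self) -> dict:
        return {
            name: int((self.labels == code).sum())
            for code, name in self.legend.items()
            if code != 0
        }


def _suprathreshold(statmap: StatMap, voxel_p: float, tail: str):
    if not (0 < voxel_p < 1):
        raise InvalidArgumentError("voxel_p must be in (0, 1)")
    if statmap.df is None:
        raise InvalidArgumentError("cluster forming requires a statistic with df")
    if tail == "positive":
        thr = stats.t.ppf(1 - voxel_p, statmap.df)
        supra = statmap.data > thr
    elif tail == "negative":
        thr = stats.t.ppf(1 - voxel_p, statmap.df)
        supra = statmap.data < -thr
    elif tail == "two-sided":
        thr = stats.t.ppf(1 - voxel_p / 2, statmap.df)
        supra = np.abs(statmap.data) > thr
    else:
        raise InvalidArgumentError(f"unknown tail {tail!r}")
    supra &= statmap.mask & np.isfinite(statmap.data)
    return supra, float(thr)


def _cluster_stats(supra, values, connectivity):
    """Label components; return (labels, sizes, masses) with 1-based ids."""
    labels, n = ndimage.label(supra, structure=_STRUCTURES[connectivity])
    if n == 0:
        return labels, np.array([]), np.array([])
    ids = labels[supra]
    sizes = np.bincount(ids, minlength=n + 1)[1:]
    masses = np.bincount(ids, weights=np.abs(values[supra]), minlength=n + 1)[1:]
    return labels, sizes, masses


def _peak(labels, values, cluster_id):
    """Peak voxel: highest |statistic|, ties broken by lowest linear index."""
    coords = np.flatnonzero(labels == cluster_id)
    flat = np.abs(values).ravel()[coords]
    best = coords[np.argmax(flat)]  # argmax returns the first (lowest index) max
    return np.unravel_index(best, labels.shape)


def form_clusters(
    statmap: StatMap,
    voxel_p: float = 0.001,
    tail: str = "positive",
    connectivity: int = 26,
) -> ClusterResult:
    """Threshold a t map and tabulate connected suprathreshold components.

    The table is sorted by size descending; permutation p values are NaN
    until :func:`permutation_correct` fills them in.
    """
    if connectivity not in _STRUCTURES:
        raise InvalidArgumentError("connectivity must be 6, 18 or 26")
    supra, thr = _suprathreshold(statmap, voxel_p, tail)
    labels, sizes, masses = _cluster_stats(supra, statmap.data, connectivity)
    rows = []
    for cid in range(1, len(sizes) + 1):
        px, py, pz = _peak(labels, np.nan_to_num(statmap.data), cid)
        rows.append(
            {
                "label": cid,
                "size": int(sizes[cid - 1]),
                "mass": float(masses[cid - 1]),
                "peak_x": int(px),
                "peak_y": int(py),
                "peak_z": int(pz),
                "peak_stat": float(statmap.data[px, py, pz]),
                "p_uncorrected": np.nan,
                "p_corrected": np.nan,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "label",
            "size",
            "mass",
            "peak_x",
            "peak_y",
            "peak_z",
            "peak_stat",
            "p_uncorrected",
            "p_corrected",
        ],
    )
    table = table.sort_values("size", ascending=False, kind="stable").reset_index(drop=True)
    return ClusterResult(table, labels, tail, thr)


def _one_sample_t(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    sd = D.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = D.mean(axis=0) / (sd / np.sqrt(n))
    t[sd == 0] = np.nan
    return t


def _regression_t(D, X, xtx_inv, hat, contrast_idx, df):
    betas = hat @ D  # (p, V)
    resid = D - X @ betas
    sigma2 = np.sum(resid**2, axis=0) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = betas[contrast_idx] / np.sqrt(sigma2 * xtx_inv[contrast_idx, contrast_idx])
    return t


def permutation_correct(
    maps,
    model: SecondLevelModel | None = None,
    traits: TraitTable | None = None,
    n_perm: int = 1000,
    voxel_p: float = 0.001,
    seed: int = 0,
    tail: str = "positive",
    alpha: float = 0.05,
    connectivity: int = 26,
    cluster_stat: str = "mass",
    fdr: bool = False,
) -> ClusterResult:
    """Max-statistic permutation FWE correction of second-level clusters.

    One-sample model (``model=None``): subject maps are sign-flipped,
    exchangeable under a symmetric null.  Regression model: subject rows
    are permuted relative to the covariates.  The corrected cluster p is
    (1 + #{permutation max >= observed}) / (1 + n_perm); the uncorrected
    p uses the distribution of all permutation clusters pooled, capped at
    the corrected p.  With ``fdr=True`` a Benjamini-Hochberg pass over
    the uncorrected p values adds a ``p_fdr`` column.
    """
    if n_perm < 100:
        raise InvalidArgumentError("n_perm must be at least 100")
    if 1.0 / (1 + n_perm) > alpha:
        raise ResolutionError(
            f"{n_perm} permutations cannot resolve alpha={alpha}"
        )
    if cluster_stat not in ("mass", "size"):
        raise InvalidArgumentError("cluster_stat must be 'mass' or 'size'")
    if connectivity not in _STRUCTURES:
        raise InvalidArgumentError("connectivity must be 6, 18 or 26")

    mask = maps[0].mask
    D = np.stack([m.in_mask() for m in maps])  # (N, V)
    n = D.shape[0]
    rng = np.random.default_rng(seed)

    if model is None:
        df = n - 1
        observed_t = _one_sample_t(D)

        def perm_t():
            signs = rng.choice([-1.0, 1.0], size=(n, 1))
            return _one_sample_t(signs * D)

    else:
        if traits is None:
            raise InvalidArgumentError("regression model requires a trait table")
        Z = traits.covariates(model.covariates, standardize=True)
        X = np.column_stack([np.ones(n), Z])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise InvalidArgumentError("rank-deficient covariate matrix")
        df = n - X.shape[1]
        xtx_inv = np.linalg.inv(X.T @ X)
        hat = xtx_inv @ X.T
        ci = 1 + model.covariates.index(model.contrast)
        observed_t = _regression_t(D, X, xtx_inv, hat, ci, df)

        def perm_t():
            order = rng.permutation(n)
            return _regression_t(D[order], X, xtx_inv, hat, ci, df)

    tmap = np.full(mask.shape, np.nan)
    tmap[mask] = observed_t
    observed = form_clusters(
        StatMap(tmap, "t", mask, df=df), voxel_p, tail, connectivity
    )
    if tail == "two-sided":
        thr = stats.t.ppf(1 - voxel_p / 2, df)
    else:
        thr = stats.t.ppf(1 - voxel_p, df)

    stat_col = observed.table[cluster_stat].to_numpy(dtype=float)
    max_null = np.empty(n_perm)
    pooled = []
    grid_t = np.zeros(mask.shape)
    for b in range(n_perm):
        tb = perm_t()
        grid_t[mask] = np.nan_to_num(tb)
        if tail == "positive":
            supra = grid_t > thr
        elif tail == "negative":
            supra = grid_t < -thr
        else:
            supra = np.abs(grid_t) > thr
        supra &= mask
        _, sizes, masses = _cluster_stats(supra, grid_t, connectivity)
        vals = masses if cluster_stat == "mass" else sizes.astype(float)
        max_null[b] = vals.max() if len(vals) else 0.0
        pooled.append(vals)
    pooled = np.concatenate(pooled) if pooled else np.array([])

    table = observed.table.copy()
    if len(table):
        p_corr = np.array(
            [(1 + np.sum(max_null >= s)) / (1 + n_perm) for s in stat_col]
        )
        if len(pooled):
            p_unc = np.array(
                [(1 + np.sum(pooled >= s)) / (1 + len(pooled)) for s in stat_col]
            )
        else:
            p_unc = np.full(len(stat_col), 1.0 / (1 + n_perm))
        p_unc = np.minimum(p_unc, p_corr)  # enforce corrected >= uncorrected
        table["p_uncorrected"] = p_unc
        table["p_corrected"] = p_corr
        if fdr:
            rej, p_fdr, *_ = multipletests(p_unc, alpha=alpha, method="fdr_bh")
            table["p_fdr"] = p_fdr
            table["fdr_significant"] = rej
    return ClusterResult(table, observed.labels, tail, observed.voxel_threshold)


def benjamini_hochberg(p_values, q: float = 0.05):
    """Step-up BH: returns the boolean rejection vector at level q."""
    rej, *_ = multipletests(np.asarray(p_values, dtype=float), alpha=q, method="fdr_bh")
    return rej


def quadrant_overlay(
    glm_pos: ClusterResult,
    glm_neg: ClusterResult,
    isps_pos: ClusterResult,
    isps_neg: ClusterResult,
    alpha: float = 0.05,
) -> QuadrantMap:
    """Voxelwise sign-pair overlay of the two analyses.

    A voxel is labelled only when it sits in a significant cluster of
    BOTH the GLM and the ISPS analysis; the label records the sign pair
    (convergent: ++ or --; divergent: +- or -+).  Voxels suprathreshold
    in only one analysis map to 'none'.
    """
    shape = glm_pos.labels.shape
    for cr in (glm_neg, isps_pos, isps_neg):
        if cr.labels.shape != shape:
            raise InvalidArgumentError("cluster results are on different grids")
    gp = glm_pos.significant_mask(alpha)
    gn = glm_neg.significant_mask(alpha)
    ip = isps_pos.significant_mask(alpha)
    inn = isps_neg.significant_mask(alpha)
    labels = np.zeros(shape, dtype=np.int16)
    labels[gp & ip] = 1
    labels[gp & inn] = 2
    labels[gn & ip] = 3
    labels[gn & inn] = 4
    return QuadrantMap(labels)
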