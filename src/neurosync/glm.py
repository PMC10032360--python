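"""Two-stage random-effects GLM.

First level: per-subject ordinary-least-squares regression of every
in-mask voxel series on the HRF-convolved rating regressor, with a
discrete-cosine high-pass basis (128-s cutoff by default) and an
intercept. Second level: one-sample t over subject beta maps, or a
multiple regression on standardized trait covariates in which each
trait's coefficient is adjusted for the others ("each acting as a
regressor of no interest to the other").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DesignDegenerateError, InvalidArgumentError
from .types import BoldImage, Regressor, SecondLevelModel, StatMap, TraitTable

__all__ = [
    "DesignMatrix",
    "dct_basis",
    "build_design",
    "fit_first_level",
    "second_level_one_sample",
    "second_level_regression",
]


@dataclass
class DesignMatrix:
    """First-level design: regressor of interest, DCT drift basis, intercept."""

    matrix: np.ndarray  # (n_volumes, p)
    names: list
    interest: str = "regressor"

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.names):
            raise InvalidArgumentError("column names do not match matrix width")
        if self.names.count("intercept") != 1:
            raise InvalidArgumentError("design must contain exactly one intercept")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise DesignDegenerateError("design matrix is rank deficient")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def interest_index(self) -> int:
        return self.names.index(self.interest)


def dct_basis(n_volumes: int, tr: float, hp_cutoff_s: float) -> np.ndarray:
    """SPM-style DCT-II high-pass basis.

    K = floor(2 * n * tr / cutoff) columns; column k (k = 1..K) is
    sqrt(2/n) * cos(pi * (2t + 1) * k / (2n)).
    """
    if hp_cutoff_s <= 0:
        raise InvalidArgumentError("high-pass cutoff must be positive")
    n = n_volumes
    K = int(np.floor(2.0 * n * tr / hp_cutoff_s))
    K = max(K, 1)  # the slowest basis function always fits
    t = np.arange(n)
    cols = [np.sqrt(2.0 / n) * np.cos(np.pi * (2 * t + 1) * k / (2.0 * n)) for k in range(1, K + 1)]
    return np.column_stack(cols)


def build_design(regressor: Regressor, hp_cutoff_s: float = 128.0) -> DesignMatrix:
    """Assemble [convolved regressor | DCT drift columns | intercept]."""
    if not regressor.convolved:
        raise InvalidArgumentError("first-level regressor must be HRF-convolved")
    drift = dct_basis(regressor.n_volumes, regressor.tr, hp_cutoff_s)
    X = np.column_stack(
        [regressor.values, drift, np.ones(regressor.n_volumes)]
    )
    names = ["regressor"] + [f"dct{k}" for k in range(1, drift.shape[1] + 1)] + ["intercept"]
    return DesignMatrix(X, names)


def fit_first_level(image: BoldImage, design: DesignMatrix):
    """Voxelwise OLS; returns (beta map, t map) for the regressor of interest.

    Degrees of freedom are n_volumes - rank(design).  Voxels whose series
    has zero variance get beta 0 and t NaN (flagged not-a-value, excluded
    downstream).
    """
    if image.n_volumes != design.n_volumes:
        raise InvalidArgumentError(
            f"subject {image.subject_id}: {image.n_volumes} volumes, "
            f"design expects {design.n_volumes}"
        )
    X = design.matrix
    Y = image.data[image.mask].T  # (T, V)
    p = X.shape[1]
    df = design.n_volumes - p

    xtx_inv = np.linalg.inv(X.T @ X)
    betas = xtx_inv @ X.T @ Y  # (p, V)
    resid = Y - X @ betas
    sigma2 = np.sum(resid**2, axis=0) / df
    i = design.interest_index
    se = np.sqrt(sigma2 * xtx_inv[i, i])

    beta_i = betas[i].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta_i / se
    dead = Y.var(axis=0) == 0
    beta_i[dead] = 0.0
    t[dead] = np.nan

    beta_map = np.full(image.grid, np.nan)
    t_map = np.full(image.grid, np.nan)
    beta_map[image.mask] = beta_i
    t_map[image.mask] = t
    prov = f"first-level OLS, subject {image.subject_id}"
    return (
        StatMap(beta_map, "beta", image.mask, provenance=prov),
        StatMap(t_map, "t", image.mask, df=df, provenance=prov),
    )


def _stack(maps) -> np.ndarray:
    if len(maps) < 3:
        raise InvalidArgumentError("need at least three subject maps")
    mask = maps[0].mask
    for m in maps[1:]:
        if not np.array_equal(m.mask, mask):
            raise InvalidArgumentError("subject maps are on different masks")
    return np.stack([m.in_mask() for m in maps])  # (N, V)


def second_level_one_sample(maps) -> StatMap:
    """Per-voxel one-sample t of subject values against 0 (df = N - 1)."""
    D = _stack(maps)
    n = D.shape[0]
    mean = D.mean(axis=0)
    sd = D.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[sd == 0] = np.nan
    mask = maps[0].mask
    out = np.full(mask.shape, np.nan)
    out[mask] = t
    return StatMap(
        out, "t", mask, df=n - 1, provenance=f"one-sample t over {n} subjects"
    )


def second_level_regression(
    maps,
    traits: TraitTable,
    covariate_names,
    contrast: str,
    standardize: bool = True,
    sequential_orthogonalize: bool = False,
) -> StatMap:
    """Per-voxel multiple regression of subject values on trait covariates.

    All covariates are entered jointly (plus an intercept), so each
    trait's t is adjusted for the others; this mutual-adjustment reading
    of "orthogonalized regressors" is order-invariant.  The SPM-style
    sequential Gram-Schmidt alternative (each covariate orthogonalized
    against its predecessors) is available via
    ``sequential_orthogonalize=True``.
    """
    model = SecondLevelModel(list(covariate_names), contrast)
    D = _stack(maps)
    n = D.shape[0]
    if traits.n_subjects != n:
        raise InvalidArgumentError(
            f"{n} subject maps but {traits.n_subjects} trait rows"
        )
    Z = traits.covariates(model.covariates, standardize=standardize)
    if sequential_orthogonalize:
        Q = Z.copy()
        for j in range(1, Q.shape[1]):
            prev = Q[:, :j]
            coef, *_ = np.linalg.lstsq(prev, Q[:, j], rcond=None)
            Q[:, j] = Q[:, j] - prev @ coef
        Z = Q
    X = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignDegenerateError("rank-deficient covariate matrix")
    p = X.shape[1]
    df = n - p
    if df <= 0:
        raise InvalidArgumentError("more covariates than subjects")
    xtx_inv = np.linalg.inv(X.T @ X)
    betas = xtx_inv @ X.T @ D  # (p, V); D rows are subjects
    resid = D - X @ betas
    sigma2 = np.sum(resid**2, axis=0) / df
    i = 1 + model.covariates.index(contrast)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = betas[i] / np.sqrt(sigma2 * xtx_inv[i, i])
    t[D.std(axis=0) == 0] = np.nan
    mask = maps[0].mask
    out = np.full(mask.shape, np.nan)
    out[mask] = t
    return StatMap(
        out,
        "t",
        mask,
        df=df,
        provenance=f"second-level regression, contrast {contrast} "
        f"adjusted for {[c for c in model.covariates if c != contrast]}",
    )
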