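"""Voxel-wise first-level GLM of BOLD on the alpha-power regressor.

Mass-univariate ordinary least squares with the design
``[alpha, artifact, constant]`` and one-degree-of-freedom t-contrasts on the
alpha column (positive and negative associations are separate one-sided
maps). Serial correlation is left unmodeled (no prewhitening); see the
methods note for the rationale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .regressors import Regressor


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (n_volumes, n_predictors)
    labels: list[str]
    rank: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.labels):
            raise ValueError("one label per design column required")
        if self.rank == 0:
            self.rank = int(np.linalg.matrix_rank(self.matrix))


@dataclass
class GLMFit:
    """Per-voxel OLS estimates: beta maps, residual variance, df."""

    betas: np.ndarray  # (n_predictors, x, y, z)
    sigma2: np.ndarray  # (x, y, z), NaN outside mask
    df: int
    design: DesignMatrix
    xtx_inv: np.ndarray
    mask: np.ndarray
    zero_var: np.ndarray = None  # type: ignore[assignment]

    def beta_map(self, label: str) -> np.ndarray:
        return self.betas[self.design.labels.index(label)]


@dataclass
class StatMap:
    """3D map of t statistics with its degrees of freedom."""

    values: np.ndarray
    df: int
    contrast: str = ""
    band: str = ""
    n_zero_variance: int = 0
    effect: np.ndarray | None = None  # contrast estimate (second level)


def build_design(alpha: Regressor, artifact: Regressor | None = None) -> DesignMatrix:
    """Assemble ``[alpha, artifact, constant]`` with mean-centered predictors.

    An all-zero artifact regressor is dropped with a warning; exact
    collinearity raises an error naming the offending columns.
    """
    cols = []
    labels = []
    a = alpha.values - alpha.values.mean()
    if np.allclose(a, 0):
        raise ValueError("alpha regressor is constant")
    cols.append(a)
    labels.append("alpha")
    if artifact is not None:
        if len(artifact.values) != len(alpha.values):
            raise ValueError("alpha and artifact regressors differ in length")
        if np.allclose(artifact.values, 0):
            warnings.warn("artifact regressor is all zeros; column dropped",
                          RuntimeWarning)
        else:
            cols.append(artifact.values - artifact.values.mean())
            labels.append("artifact")
    cols.append(np.ones(len(a)))
    labels.append("constant")
    X = np.column_stack(cols)
    rank = int(np.linalg.matrix_rank(X))
    if rank < X.shape[1]:
        # identify a dependent column for the message
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
                raise ValueError(
                    f"design is rank-deficient: column {labels[j]!r} is "
                    "collinear with the remaining columns"
                )
        raise ValueError("design is rank-deficient")
    return DesignMatrix(matrix=X, labels=labels, rank=rank)


def fit_glm(bold, X: DesignMatrix, mask: np.ndarray | None = None) -> GLMFit:
    """Ordinary least squares at every in-mask voxel.

    ``bold`` is a :class:`~alphabold.fmri.BOLDSeries` or a plain 4D array.
    ``df = n_volumes - rank(X)``.
    """
    data = bold.data if hasattr(bold, "data") else np.asarray(bold, dtype=float)
    n = data.shape[-1]
    if n != X.matrix.shape[0]:
        raise ValueError("number of volumes does not match design rows")
    df = n - X.rank
    if df <= 0:
        raise ValueError("non-positive degrees of freedom")
    grid = data.shape[:3]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid:
        raise ValueError("mask shape does not match BOLD grid")
    Y = data[mask].T  # (n, n_vox)
    pinv = np.linalg.pinv(X.matrix)
    B = pinv @ Y
    resid = Y - X.matrix @ B
    rss = np.sum(resid**2, axis=0)
    sigma2_vox = rss / df
    # zero-variance relative to the data scale (exact fits leave float dust)
    zero_vox = rss <= 1e-24 * np.maximum(np.sum(Y**2, axis=0), 1e-300)
    p = X.matrix.shape[1]
    betas = np.full((p,) + grid, np.nan)
    for j in range(p):
        betas[j][mask] = B[j]
    sigma2 = np.full(grid, np.nan)
    sigma2[mask] = sigma2_vox
    zero_var = np.zeros(grid, dtype=bool)
    zero_var[mask] = zero_vox
    xtx_inv = np.linalg.inv(X.matrix.T @ X.matrix)
    return GLMFit(betas=betas, sigma2=sigma2, df=df, design=X,
                  xtx_inv=xtx_inv, mask=mask, zero_var=zero_var)


def t_contrast(fit: GLMFit, c: np.ndarray, label: str = "", band: str = "") -> StatMap:
    """t map for the contrast ``c' beta``; zero-variance voxels become NaN."""
    c = np.asarray(c, dtype=float)
    if c.shape != (len(fit.design.labels),):
        raise ValueError("contrast length must equal number of predictors")
    if np.allclose(c, 0):
        raise ValueError("contrast vector is all zeros")
    cb = np.tensordot(c, fit.betas, axes=1)
    var_scale = float(c @ fit.xtx_inv @ c)
    se = np.sqrt(fit.sigma2 * var_scale)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = cb / se
    zero_var = fit.mask & fit.zero_var
    n_zero = int(np.sum(zero_var))
    if n_zero:
        t[zero_var] = np.nan
    t[~fit.mask] = np.nan
    return StatMap(values=t, df=fit.df, contrast=label, band=band,
                   n_zero_variance=n_zero)
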