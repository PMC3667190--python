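"""Voxelwise GLM with AR(1) serial-correlation handling.

First level: ordinary least squares on a design of stimulus regressors,
linear drift, constant, global mean and motion parameters; the AR(1)
coefficient is estimated from the pooled lag-1 autocorrelation of the OLS
residuals (one value per subject, pooled over voxels, in the spirit of
SPM's approximate global AR model) and the model is refit after exact
AR(1) whitening (Prais-Winsten transform, which equals generalised least
squares for a known coefficient).  Second level: voxelwise one-sample
t-tests on per-subject contrast values with cluster-extent thresholding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .isc import Cluster, threshold_clusters
from .prep import Mask, SubjectData, nuisance_design
from .stimreg import Regressor

__all__ = [
    "FirstLevelResult",
    "SecondLevelResult",
    "build_design",
    "fit_first_level",
    "second_level",
]

_RHO_CAP = 0.99


@dataclass
class FirstLevelResult:
    betas: np.ndarray  # (n_voxels, n_columns), whitened-model estimates
    column_names: list[str]
    rho_hat: float  # pooled AR(1) coefficient
    regressor_corr: float  # correlation between first two stimulus columns


@dataclass
class SecondLevelResult:
    t: np.ndarray  # (n_voxels,)
    df: int
    mask_sig: np.ndarray
    clusters: list[Cluster]


def build_design(
    data: SubjectData,
    regressors: list[Regressor],
    include_global: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix: stimulus regressors, then linear drift, constant,
    motion parameters, and optionally the global mean."""
    t_len = data.n_time
    cols, names = [], []
    for r in regressors:
        if r.values.size != t_len:
            raise ValueError("regressor length does not match data")
        v = r.values - r.values.mean()
        sd = v.std()
        cols.append(v / sd if sd > 0 else v)
        names.append(r.label)
    nuis, nuis_names = nuisance_design(data, include_global=include_global)
    X = np.column_stack(cols + [nuis])
    names = names + nuis_names
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("GLM design is rank deficient")
    return X, names


def _whitening_matrix(t_len: int, rho: float) -> np.ndarray:
    """Exact AR(1) whitening (Prais-Winsten): W y has iid errors when the
    errors of y are AR(1) with coefficient rho."""
    W = np.eye(t_len)
    W[0, 0] = np.sqrt(1.0 - rho**2)
    for i in range(1, t_len):
        W[i, i - 1] = -rho
    return W


def fit_first_level(
    data: SubjectData,
    regressors: list[Regressor],
    include_global: bool = True,
    rho: float | None = None,
) -> FirstLevelResult:
    """OLS fit, pooled AR(1) estimate from the residuals, then a
    whitened refit.  Pass ``rho`` to skip estimation and whiten with a
    known coefficient (rho = 0 reduces exactly to OLS)."""
    X, names = build_design(data, regressors, include_global=include_global)
    Y = data.bold.T  # T x V
    if rho is None:
        beta_ols, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta_ols
        num = np.sum(resid[1:] * resid[:-1])
        den = np.sum(resid**2)
        rho = 0.0 if den == 0 else float(num / den)
        if abs(rho) >= _RHO_CAP:
            warnings.warn(f"pooled AR(1) estimate {rho:.3f} capped at ±{_RHO_CAP}")
            rho = float(np.clip(rho, -_RHO_CAP, _RHO_CAP))
    W = _whitening_matrix(X.shape[0], rho)
    beta_w, *_ = np.linalg.lstsq(W @ X, W @ Y, rcond=None)
    n_stim = len(regressors)
    if n_stim >= 2:
        reg_corr = float(np.corrcoef(X[:, 0], X[:, 1])[0, 1])
    else:
        reg_corr = np.nan
    return FirstLevelResult(
        betas=beta_w.T, column_names=names, rho_hat=rho, regressor_corr=reg_corr
    )


def second_level(
    betas_per_subject: np.ndarray,
    contrast: np.ndarray,
    mask: Mask,
    alpha: float = 0.05,
    fwe_method: str = "bonferroni",
    t_fixed: float = 5.1,
    extent: int = 10,
    connectivity: int = 6,
) -> SecondLevelResult:
    """One-sample t-test across subjects on voxelwise contrast values.

    ``betas_per_subject``: (n_subjects, n_voxels, n_columns); ``contrast``
    is a vector over design columns.  Default thresholding: FWE-corrected
    p < 0.05 with a 10-voxel cluster extent.
    """
    betas = np.asarray(betas_per_subject)
    if betas.ndim != 3 or betas.shape[0] < 2:
        raise ValueError("need (n_subjects, n_voxels, n_columns) with >= 2 subjects")
    contrast = np.asarray(contrast, dtype=float)
    con = betas @ contrast  # (n_subjects, n_voxels)
    m = con.shape[0]
    mean = con.mean(axis=0)
    sd = con.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(m))
    t = np.where(np.isfinite(t), t, 0.0)
    df = m - 1
    mask_sig, clusters = threshold_clusters(
        t,
        df,
        mask,
        alpha=alpha,
        fwe_method=fwe_method,
        t_fixed=t_fixed,
        extent=extent,
        connectivity=connectivity,
    )
    return SecondLevelResult(t=t, df=df, mask_sig=mask_sig, clusters=clusters)
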