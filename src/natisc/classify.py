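"""Extrinsic/intrinsic component sorting, functional network
connectivity, and stimulus regression of IC time-courses.

A component is **extrinsic** (stimulus-driven) when its group t-map has a
positive spatial correlation above ``r_min`` (default 0.3) with the
binary ISC mask *and* more than ``overlap_min`` percent (default 50%) of
its own suprathreshold voxels fall inside the ISC mask; everything else
is intrinsic.  Functional network connectivity (FNC) then correlates —
within each subject — the time-courses of the extrinsic ICs with the
non-extrinsic ICs, Fisher-transforms the correlations and tests them
across subjects with a two-tailed one-sample t-test, Bonferroni-corrected
over the (extrinsic x non-extrinsic) pair count.  Finally each IC
time-course is regressed on the speech and non-speech stimulus
regressors (plus drift and constant), giving per-regressor betas and
partial correlations, with group-level one-sample t-tests on the betas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .gica import GroupICAModel
from .isc import ISCResult, fisher_z, threshold_clusters
from .stimreg import Regressor

__all__ = [
    "ComponentClassification",
    "FNCResult",
    "StimulusRegression",
    "sort_extrinsic",
    "fnc",
    "regress_on_stimuli",
    "classification_table",
]


@dataclass
class ComponentClassification:
    spatial_r: np.ndarray  # (k,) correlation of IC t-map with ISC mask
    overlap_pct: np.ndarray  # (k,) % of IC suprathreshold voxels in ISC mask
    is_extrinsic: np.ndarray  # (k,) bool
    ranking: np.ndarray  # component indices sorted by spatial_r descending
    ic_masks: np.ndarray  # (k, n_voxels) bool, thresholded IC maps
    r_min: float
    overlap_min: float
    fnc_result: "FNCResult | None" = field(default=None)
    regression: "StimulusRegression | None" = field(default=None)


@dataclass
class FNCResult:
    extrinsic_idx: np.ndarray  # component indices tested as extrinsic
    other_idx: np.ndarray  # retained non-extrinsic component indices
    mean_r: np.ndarray  # (nE, nO): tanh of mean Fisher z across subjects
    t: np.ndarray  # (nE, nO)
    p: np.ndarray  # (nE, nO) two-tailed
    sig: np.ndarray  # (nE, nO) bool after Bonferroni
    n_tests: int
    df: int
    alpha: float


@dataclass
class StimulusRegression:
    regressor_labels: list[str]
    betas: np.ndarray  # (n_subjects, k, n_regressors)
    partial_r: np.ndarray  # (n_subjects, k, n_regressors)
    group_t: np.ndarray  # (k, n_regressors)
    group_p: np.ndarray  # (k, n_regressors)
    mean_partial_r: np.ndarray  # (k, n_regressors)
    df: int
    labels: list[str]  # per-IC: speech / non_speech / both / neither
    regressor_corr: float  # correlation between the two stimulus regressors


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return np.nan
    return float(a @ b / denom)


def sort_extrinsic(
    model: GroupICAModel,
    isc_result: ISCResult,
    r_min: float = 0.3,
    overlap_min: float = 50.0,
    alpha: float = 0.01,
    fwe_method: str = "bonferroni",
    t_fixed: float = 5.1,
    extent: int = 20,
    connectivity: int = 6,
    thresholded_template: bool = False,
) -> ComponentClassification:
    """Classify every component against the thresholded ISC map.

    IC t-maps are thresholded with the same voxel + extent rule as the
    ISC map (on the model's own df).  ``spatial_r`` uses the
    unthresholded IC t-map against the binary ISC mask by default; with
    ``thresholded_template`` both sides are binarised.  Components whose
    thresholded map is empty have undefined overlap and are forced
    intrinsic.
    """
    isc_mask = isc_result.mask_sig
    if not isc_mask.any():
        raise ValueError("ISC mask is empty; nothing to sort against")
    k = model.order_k
    spatial_r = np.empty(k)
    overlap = np.full(k, np.nan)
    ic_masks = np.zeros((k, isc_mask.size), dtype=bool)
    template = isc_mask.astype(float)
    for c in range(k):
        tmap = model.group_tmaps[c]
        ic_mask, _ = threshold_clusters(
            tmap,
            model.tmap_df,
            model.mask,
            alpha=alpha,
            fwe_method=fwe_method,
            t_fixed=t_fixed,
            extent=extent,
            connectivity=connectivity,
        )
        ic_masks[c] = ic_mask
        side = ic_mask.astype(float) if thresholded_template else tmap
        spatial_r[c] = _pearson(side, template)
        if ic_mask.any():
            overlap[c] = 100.0 * np.sum(ic_mask & isc_mask) / np.sum(ic_mask)
    empty = ~ic_masks.any(axis=1)
    if empty.any():
        warnings.warn(
            f"components {np.flatnonzero(empty).tolist()} have empty "
            "thresholded maps; forced intrinsic"
        )
    with np.errstate(invalid="ignore"):
        is_ext = (
            model.retained
            & ~empty
            & (spatial_r > r_min)
            & (np.nan_to_num(overlap, nan=-1.0) > overlap_min)
        )
    ranking = np.argsort(-np.nan_to_num(spatial_r, nan=-np.inf))
    return ComponentClassification(
        spatial_r=spatial_r,
        overlap_pct=overlap,
        is_extrinsic=is_ext,
        ranking=ranking,
        ic_masks=ic_masks,
        r_min=r_min,
        overlap_min=overlap_min,
    )


def fnc(
    model: GroupICAModel,
    classification: ComponentClassification,
    alpha: float = 0.05,
) -> FNCResult:
    """Functional network connectivity between extrinsic and
    non-extrinsic retained ICs, Bonferroni-corrected over the pair count.
    """
    ext = np.flatnonzero(classification.is_extrinsic & model.retained)
    other = np.flatnonzero(model.retained & ~classification.is_extrinsic)
    if ext.size < 2:
        raise ValueError("need at least 2 extrinsic ICs for FNC")
    if other.size < 1:
        raise ValueError("need at least 1 non-extrinsic IC for FNC")
    m = model.n_subjects
    if m < 3:
        raise ValueError("need at least 3 subjects for FNC")
    z = np.full((m, ext.size, other.size), np.nan)
    for s in range(m):
        tcs = model.subject_timecourses[s]
        for a, ia in enumerate(ext):
            for b, ib in enumerate(other):
                ta, tb = tcs[ia], tcs[ib]
                if ta.std() == 0 or tb.std() == 0:
                    warnings.warn(
                        f"constant time-course in subject {s}; pair "
                        f"({ia},{ib}) excluded"
                    )
                    continue
                z[s, a, b] = fisher_z(np.corrcoef(ta, tb)[0, 1])
    n_valid = np.isfinite(z).sum(axis=0)
    mean_z = np.nanmean(z, axis=0)
    sd_z = np.nanstd(z, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean_z / (sd_z / np.sqrt(n_valid))
    df = m - 1
    p = 2.0 * stats.t.sf(np.abs(t), df)
    n_tests = ext.size * other.size
    sig = p < alpha / n_tests
    return FNCResult(
        extrinsic_idx=ext,
        other_idx=other,
        mean_r=np.tanh(mean_z),
        t=t,
        p=p,
        sig=sig,
        n_tests=n_tests,
        df=df,
        alpha=alpha,
    )


def regress_on_stimuli(
    model: GroupICAModel,
    regressors: list[Regressor],
    alpha: float = 0.05,
) -> StimulusRegression:
    """Multiple regression of every IC time-course on the stimulus
    regressors (plus linear drift and constant), per subject, with group
    one-sample t-tests on the betas across subjects.
    """
    if not regressors:
        raise ValueError("no regressors")
    t_len = model.subject_timecourses.shape[2]
    for r in regressors:
        if r.values.size != t_len:
            raise ValueError("regressor length must match time-course length")
    reg_mat = np.column_stack([r.values for r in regressors])
    labels = [r.label for r in regressors]
    n_reg = reg_mat.shape[1]
    if n_reg >= 2:
        rr = np.corrcoef(reg_mat.T)
        off = rr[np.triu_indices(n_reg, k=1)]
        if np.any(np.abs(off) > 0.99):
            raise ValueError("stimulus regressors are collinear")
        regressor_corr = float(rr[0, 1])
    else:
        regressor_corr = np.nan
    drift = np.linspace(-0.5, 0.5, t_len)
    X = np.column_stack([reg_mat, drift, np.ones(t_len)])
    m, k = model.n_subjects, model.order_k
    betas = np.empty((m, k, n_reg))
    partial = np.empty((m, k, n_reg))
    pinv = np.linalg.pinv(X)
    for s in range(m):
        tcs = model.subject_timecourses[s]  # k x T
        B = (pinv @ tcs.T).T  # k x p
        betas[s] = B[:, :n_reg]
        for j in range(n_reg):
            others = np.delete(X, j, axis=1)
            q, _ = np.linalg.qr(others)
            xr = X[:, j] - q @ (q.T @ X[:, j])
            yr = tcs.T - q @ (q.T @ tcs.T)  # T x k
            xn = np.linalg.norm(xr)
            yn = np.linalg.norm(yr, axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                partial[s, :, j] = (xr @ yr) / (xn * yn)
    mean_b = betas.mean(axis=0)
    sd_b = betas.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.divide(
            mean_b, sd_b / np.sqrt(m), out=np.zeros_like(mean_b), where=sd_b > 0
        )
        # zero between-subject variance: an exactly-zero effect is a zero t,
        # an exactly-repeated nonzero effect diverges
        group_t = np.where(
            sd_b > 0,
            ratio,
            np.where(np.abs(mean_b) <= 1e-12, 0.0, np.inf) * np.sign(mean_b),
        )
    df = m - 1
    group_p = 2.0 * stats.t.sf(np.abs(group_t), df)
    ic_labels = []
    for c in range(k):
        sig = group_p[c] < alpha
        if n_reg >= 2:
            if sig[0] and sig[1]:
                ic_labels.append("both")
            elif sig[0]:
                ic_labels.append(labels[0])
            elif sig[1]:
                ic_labels.append(labels[1])
            else:
                ic_labels.append("neither")
        else:
            ic_labels.append(labels[0] if sig[0] else "neither")
    return StimulusRegression(
        regressor_labels=labels,
        betas=betas,
        partial_r=partial,
        group_t=group_t,
        group_p=group_p,
        mean_partial_r=np.nanmean(partial, axis=0),
        df=df,
        labels=ic_labels,
        regressor_corr=regressor_corr,
    )


def classification_table(
    model: GroupICAModel, classification: ComponentClassification
) -> pd.DataFrame:
    """Per-IC summary table (one row per component, ranked by spatial
    correlation with the ISC mask)."""
    rows = []
    reg = classification.regression
    for rank, c in enumerate(classification.ranking):
        row = {
            "rank": rank + 1,
            "ic_id": int(c),
            "spatial_r": classification.spatial_r[c],
            "overlap_pct": classification.overlap_pct[c],
            "extrinsic": bool(classification.is_extrinsic[c]),
            "retained": bool(model.retained[c]),
            "iq": model.stability_iq[c],
        }
        if reg is not None:
            for j, lab in enumerate(reg.regressor_labels):
                row[f"beta_{lab}"] = reg.betas[:, c, j].mean()
                row[f"partial_r_{lab}"] = reg.mean_partial_r[c, j]
            row["stimulus_label"] = reg.labels[c]
        rows.append(row)
    return pd.DataFrame(rows)


def write_fnc_tsv(result: FNCResult, path: str | Path) -> None:
    df = pd.DataFrame(
        result.mean_r,
        index=[f"IC{int(i)}" for i in result.extrinsic_idx],
        columns=[f"IC{int(j)}" for j in result.other_idx],
    )
    df.to_csv(path, sep="\t")
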