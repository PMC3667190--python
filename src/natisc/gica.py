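"""Temporally concatenated group spatial ICA.

Stages:

1. **Model-order estimation** — minimum description length (MDL) on the
   eigenvalues of each subject's temporal covariance (voxels as samples);
   the cohort order is the rounded mean of per-subject optima.
2. **Two-stage PCA reduction** — subject-level PCA to k1 >= k temporal
   dimensions, temporal concatenation across subjects, then group PCA to
   k dimensions.
3. **Infomax unmixing** — natural-gradient ascent with a logistic
   nonlinearity on the whitened group data, yielding spatially
   independent component maps.
4. **Multi-run stability selection** — the ICA is repeated from random
   initialisations; components from all runs are clustered by absolute
   spatial correlation (average linkage) and each cluster is scored with
   a stability index Iq = (mean intra-cluster similarity) - (mean
   extra-cluster similarity).  The cluster centrotype is the
   representative component; clusters with Iq below threshold are not
   retained.
5. **Back-reconstruction** — subject-specific maps and time-courses from
   the aggregate unmixing and the stored two-stage PCA partitions, such
   that the subject-mean map equals the aggregate map and, for noiseless
   data of exact rank, the product of time-courses and maps reconstructs
   the data.
6. **Group t-maps** — voxelwise one-sample t-tests across the
   subject-specific maps (df = n_subjects - 1).

Component sign is fixed so each aggregate map has positive skew, which
resolves the ICA sign ambiguity deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import expit
from scipy.stats import skew

from .prep import GroupDataset, Mask

__all__ = [
    "OrderEstimate",
    "GroupICAModel",
    "estimate_order",
    "infomax",
    "fit_group_ica",
    "back_reconstruct",
    "component_tmaps",
    "save_model",
    "load_model",
]

#: component order the MDL analysis of the original 13-subject cohort
#: arrives at; used by the full-scale ("paper") pipeline profile.
PAPER_TARGET_ORDER = 55

_T_CAP = 1e6


@dataclass
class OrderEstimate:
    k_mdl: int
    criterion_curves: np.ndarray  # (n_subjects, n_candidates) MDL values
    per_subject_k: np.ndarray  # (n_subjects,)


@dataclass
class GroupICAModel:
    order_k: int
    aggregate_maps: np.ndarray  # (k, n_voxels), unit-variance rows
    subject_maps: np.ndarray  # (n_subjects, k, n_voxels)
    subject_timecourses: np.ndarray  # (n_subjects, k, n_time)
    stability_iq: np.ndarray  # (k,) clipped to [0, 1]
    retained: np.ndarray  # (k,) bool: Iq >= threshold and QC pass
    group_tmaps: np.ndarray  # (k, n_voxels)
    tmap_df: int
    mask: Mask
    reduction: dict = field(default_factory=dict, repr=False)
    iq_threshold: float = 0.9
    tr_seconds: float = 0.0

    @property
    def n_subjects(self) -> int:
        return self.subject_maps.shape[0]


# ---------------------------------------------------------------------------
# model order


def _mdl_curve(eigvals: np.ndarray, n_samples: int) -> np.ndarray:
    """MDL criterion over candidate source counts k = 0 .. p-2 for the
    descending eigenvalues of a p x p covariance from n_samples draws."""
    lam = np.sort(eigvals)[::-1].astype(float)
    p = lam.size
    floor = max(lam[0], 0.0) * 1e-10
    if floor <= 0:
        raise ValueError("degenerate covariance: all eigenvalues ~ 0")
    # eigenvalues at numerical-noise level are clamped to a common floor so
    # an exactly rank-deficient covariance yields a flat (zero) likelihood
    # term beyond the true rank
    lam = np.maximum(lam, floor)
    log_lam = np.log(lam)
    # tail sums for k..p-1
    rev_sum = np.cumsum(lam[::-1])[::-1]
    rev_logsum = np.cumsum(log_lam[::-1])[::-1]
    ks = np.arange(p - 1)
    m = p - ks  # tail length
    mean_log = rev_logsum[ks] / m
    log_mean = np.log(rev_sum[ks] / m)
    loglik = -n_samples * m * (mean_log - log_mean)
    penalty = 0.5 * ks * (2 * p - ks) * np.log(n_samples)
    return loglik + penalty


def estimate_order(
    group: GroupDataset, max_order: int | None = None
) -> OrderEstimate:
    """Cohort ICA order from per-subject MDL on temporal-covariance
    eigenvalues; returns the rounded mean of per-subject minima."""
    curves = []
    per_k = []
    for s in group.subjects:
        D = s.bold - s.bold.mean(axis=1, keepdims=True)  # V x T, voxel-centered
        C = (D.T @ D) / s.n_voxels
        lam = np.linalg.eigvalsh(C)[::-1]
        curve = _mdl_curve(lam, n_samples=s.n_voxels)
        if max_order is not None:
            curve = curve[: max_order + 1]
        curves.append(curve)
        per_k.append(int(np.argmin(curve)))
    n_cand = min(c.size for c in curves)
    curves_arr = np.vstack([c[:n_cand] for c in curves])
    per_k_arr = np.array(per_k)
    return OrderEstimate(
        k_mdl=int(round(per_k_arr.mean())),
        criterion_curves=curves_arr,
        per_subject_k=per_k_arr,
    )


# ---------------------------------------------------------------------------
# Infomax


def infomax(
    x_white: np.ndarray,
    seed: int = 0,
    lr: float = 0.01,
    max_iter: int = 500,
    tol: float = 1e-6,
    block: int | None = None,
    anneal: float = 0.9,
) -> tuple[np.ndarray, bool]:
    """Natural-gradient Infomax with logistic nonlinearity on whitened
    data (k x V).  Returns the unmixing matrix W and a convergence flag.

    The learning rate is annealed by ``anneal`` on weight blow-up and
    nudged down when the epoch-to-epoch weight change oscillates.
    """
    k, v = x_white.shape
    rng = np.random.default_rng(seed)
    W, _ = np.linalg.qr(rng.standard_normal((k, k)))
    block = block or int(np.ceil(np.sqrt(v)))
    eye = np.eye(k)
    prev_delta = np.inf
    for _ in range(max_iter):
        order = rng.permutation(v)
        w_old = W.copy()
        blown = False
        for start in range(0, v, block):
            idx = order[start : start + block]
            u = W @ x_white[:, idx]
            y = expit(u)
            W = W + lr * (eye + ((1.0 - 2.0 * y) @ u.T) / idx.size) @ W
            if not np.all(np.isfinite(W)) or np.abs(W).max() > 1e8:
                blown = True
                break
        if blown:
            lr *= anneal
            W = w_old
            continue
        delta = np.abs(W - w_old).max()
        if delta < tol:
            return W, True
        if delta > prev_delta:
            lr *= 0.98
        prev_delta = delta
    return W, False


# ---------------------------------------------------------------------------
# ICASSO-style stability clustering


def _cluster_runs(
    sources: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cluster pooled run components by absolute spatial correlation.

    Returns (centrotype_indices, iq_raw, cluster_labels); clusters are in
    arbitrary order.
    """
    n_comp = sources.shape[0]
    sim = np.abs(np.corrcoef(sources))
    np.fill_diagonal(sim, 1.0)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    cents, iqs = [], []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        inside = sim[np.ix_(members, members)]
        if members.size > 1:
            intra = (inside.sum() - members.size) / (members.size * (members.size - 1))
        else:
            intra = 1.0
        outside = np.setdiff1d(np.arange(n_comp), members)
        extra = sim[np.ix_(members, outside)].mean() if outside.size else 0.0
        iqs.append(intra - extra)
        cents.append(members[np.argmax(inside.sum(axis=1))])
    return np.array(cents), np.array(iqs), labels


# ---------------------------------------------------------------------------
# group ICA fit


def _preprocess_subject(bold: np.ndarray, zscore_voxels: bool) -> np.ndarray:
    """Voxel-centred (optionally standardised) data as time x voxel."""
    d = bold - bold.mean(axis=1, keepdims=True)
    if zscore_voxels:
        sd = d.std(axis=1, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        d = d / sd
    return d.T  # T x V


def fit_group_ica(
    group: GroupDataset,
    k: int,
    n_runs: int = 10,
    seed: int = 0,
    k1: int | None = None,
    iq_threshold: float = 0.9,
    zscore_voxels: bool = True,
    lr: float = 0.01,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> GroupICAModel:
    """Fit the full group spatial ICA with multi-run stability selection
    and GICA3 back-reconstruction.

    k1 defaults to ceil(1.5 k) capped by the data dimensions.  Runs differ
    only in their random initialisation; shuffling run order leaves the
    clustered result unchanged.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    m, t_len, v = group.n_subjects, group.n_time, group.n_voxels
    if k < 1 or k > min(t_len, v):
        raise ValueError("k out of range for the data")
    k1 = k1 or int(np.ceil(1.5 * k))
    k1 = min(k1, t_len, v)
    if k1 < k:
        raise ValueError("subject PCA dimension below k")

    # stage 1: subject PCA
    F_list, R_list = [], []
    for s in group.subjects:
        d = _preprocess_subject(s.bold, zscore_voxels)  # T x V
        u, sv, _ = np.linalg.svd(d, full_matrices=False)
        F = u[:, :k1]
        F_list.append(F)
        R_list.append(F.T @ d)  # k1 x V

    # stage 2: group PCA on the temporal concatenation
    stacked = np.vstack(R_list)  # (m*k1) x V
    ug, sg, _ = np.linalg.svd(stacked, full_matrices=False)
    G = ug[:, :k]  # (m*k1) x k, orthonormal columns
    X = G.T @ stacked  # k x V

    # whitening for ICA
    x_sd = X.std(axis=1)
    x_sd = np.where(x_sd > 0, x_sd, 1.0)
    Xw = X / x_sd[:, None]

    # multi-run Infomax
    run_seeds = np.random.SeedSequence(seed).spawn(n_runs)
    all_sources = []
    any_ok = False
    for rs in run_seeds:
        w_run, _ = infomax(
            Xw,
            seed=int(rs.generate_state(1)[0] % (2**31)),
            lr=lr,
            max_iter=max_iter,
            tol=tol,
        )
        s_run = w_run @ Xw
        sd = s_run.std(axis=1, keepdims=True)
        ok = np.all(np.isfinite(s_run)) and np.all(sd > 0)
        if ok:
            all_sources.append(s_run / sd)
            any_ok = True
    if not any_ok:
        raise RuntimeError("all ICA runs failed")
    pooled = np.vstack(all_sources)

    cents, iq_raw, _ = _cluster_runs(pooled, k)
    order = np.argsort(-iq_raw)  # most stable first
    cents, iq_raw = cents[order], iq_raw[order]
    S = pooled[cents].copy()  # k x V, unit-variance rows

    # deterministic sign: positive skew per aggregate map
    signs = np.where(skew(S, axis=1) < 0, -1.0, 1.0)
    S *= signs[:, None]

    # aggregate mixing consistent with the centrotype sources
    A_w = Xw @ S.T @ np.linalg.inv(S @ S.T)
    A_full = A_w * x_sd[:, None]  # X ~= A_full @ S

    iq = np.clip(iq_raw, 0.0, 1.0)
    qc_pass = np.ones(k, dtype=bool)  # mask-coverage QC; full masks always pass
    retained = (iq >= iq_threshold) & qc_pass

    model = GroupICAModel(
        order_k=k,
        aggregate_maps=S,
        subject_maps=np.empty((m, k, v)),
        subject_timecourses=np.empty((m, k, t_len)),
        stability_iq=iq,
        retained=retained,
        group_tmaps=np.empty((k, v)),
        tmap_df=m - 1,
        mask=group.mask,
        reduction={
            "F": F_list,
            "G_blocks": [G[i * k1 : (i + 1) * k1] for i in range(m)],
            "A_full": A_full,
            "k1": k1,
            "zscore_voxels": zscore_voxels,
        },
        iq_threshold=iq_threshold,
        tr_seconds=group.tr_seconds,
    )
    maps, tcs = back_reconstruct(model, group)
    model.subject_maps = maps
    model.subject_timecourses = tcs
    if m >= 2:
        model.group_tmaps, model.tmap_df = component_tmaps(maps)
    else:  # single-subject "group": no between-subject statistics
        model.group_tmaps, model.tmap_df = maps[0].copy(), 0
    return model


def back_reconstruct(
    model: GroupICAModel, group: GroupDataset
) -> tuple[np.ndarray, np.ndarray]:
    """GICA3 back-reconstruction of subject maps and time-courses.

    With A the aggregate mixing (X = A S) and G_i the i-th row block of
    the group-PCA basis, the subject map is S_i = A^-1 G_i^+ R_i and the
    time-course matrix is T_i = F_i G_i A.  The subject-mean map equals
    the aggregate map and, on noiseless exact-rank data, T_i S_i
    reconstructs the (preprocessed) subject data.
    """
    red = model.reduction
    if not red:
        raise ValueError("model has no stored reduction state")
    A = red["A_full"]
    A_inv = np.linalg.inv(A)
    m = group.n_subjects
    k, v = model.aggregate_maps.shape
    maps = np.empty((m, k, v))
    tcs = np.empty((m, k, group.n_time))
    for i, s in enumerate(group.subjects):
        d = _preprocess_subject(s.bold, red["zscore_voxels"])
        F = red["F"][i]
        Gi = red["G_blocks"][i]
        Ri = F.T @ d
        maps[i] = A_inv @ np.linalg.pinv(Gi) @ Ri
        tcs[i] = (F @ Gi @ A).T
    return maps, tcs


def component_tmaps(subject_maps: np.ndarray) -> tuple[np.ndarray, int]:
    """Voxelwise one-sample t across subjects for every component.

    Zero-variance voxels (identical maps across subjects) would diverge;
    their t is capped at +-1e6.
    """
    m = subject_maps.shape[0]
    if m < 2:
        raise ValueError("need at least 2 subjects for t-maps")
    mean = subject_maps.mean(axis=0)
    sd = subject_maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(m))
    t = np.where(np.isfinite(t), t, np.sign(mean) * _T_CAP)
    return np.clip(t, -_T_CAP, _T_CAP), m - 1


# ---------------------------------------------------------------------------
# model bundle I/O (JSON index + binary arrays)


def save_model(model: GroupICAModel, path: str | Path) -> None:
    path = Path(path)
    arrays = {
        "aggregate_maps": model.aggregate_maps,
        "subject_maps": model.subject_maps,
        "subject_timecourses": model.subject_timecourses,
        "stability_iq": model.stability_iq,
        "retained": model.retained,
        "group_tmaps": model.group_tmaps,
        "mask_indices": model.mask.flat_indices,
        "A_full": model.reduction["A_full"],
    }
    for i, F in enumerate(model.reduction["F"]):
        arrays[f"F_{i}"] = F
        arrays[f"G_{i}"] = model.reduction["G_blocks"][i]
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    index = {
        "order_k": model.order_k,
        "tmap_df": model.tmap_df,
        "iq_threshold": model.iq_threshold,
        "tr_seconds": model.tr_seconds,
        "mask_shape": list(model.mask.shape),
        "k1": model.reduction["k1"],
        "zscore_voxels": bool(model.reduction["zscore_voxels"]),
        "n_subjects": model.n_subjects,
    }
    path.with_suffix(".json").write_text(json.dumps(index, indent=2))


def load_model(path: str | Path) -> GroupICAModel:
    path = Path(path)
    index = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as z:
        arrays = {name: z[name] for name in z.files}
    m = index["n_subjects"]
    reduction = {
        "F": [arrays[f"F_{i}"] for i in range(m)],
        "G_blocks": [arrays[f"G_{i}"] for i in range(m)],
        "A_full": arrays["A_full"],
        "k1": index["k1"],
        "zscore_voxels": index["zscore_voxels"],
    }
    return GroupICAModel(
        order_k=index["order_k"],
        aggregate_maps=arrays["aggregate_maps"],
        subject_maps=arrays["subject_maps"],
        subject_timecourses=arrays["subject_timecourses"],
        stability_iq=arrays["stability_iq"],
        retained=arrays["retained"].astype(bool),
        group_tmaps=arrays["group_tmaps"],
        tmap_df=index["tmap_df"],
        mask=Mask(tuple(index["mask_shape"]), arrays["mask_indices"]),
        reduction=reduction,
        iq_threshold=index["iq_threshold"],
        tr_seconds=index["tr_seconds"],
    )
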