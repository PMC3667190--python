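"""Intersubject correlation (ISC) mapping.

Voxelwise Pearson correlations are computed for every unordered subject
pair, Fisher-transformed (z = atanh r), and tested against zero with a
one-sample t-test over pairs (df = n_pairs - 1; 78 pairs and 77 df for a
13-subject cohort).  Thresholding combines a voxelwise criterion with a
cluster-extent rule on the 3-D grid.  Family-wise error control is
offered as a fixed t cut-off (the replication mode, t > 5.1 / extent 20),
Bonferroni over voxels, or a Monte-Carlo max-statistic null built from
circular time shifts, which preserve autocorrelation while destroying
inter-subject alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .prep import GroupDataset, Mask

__all__ = [
    "ISCResult",
    "MonteCarloNull",
    "pairwise_isc",
    "group_ttest",
    "threshold_clusters",
    "monte_carlo_null",
    "run_isc",
]

_R_CLIP = 1.0 - 1e-7


@dataclass
class Cluster:
    label: int
    voxels: np.ndarray  # indices into the mask's voxel order
    peak_voxel: int  # index into the mask's voxel order
    peak_coord: tuple[int, int, int]
    peak_stat: float

    @property
    def size(self) -> int:
        return int(self.voxels.size)


@dataclass
class ISCResult:
    pair_z: np.ndarray  # (n_pairs, n_voxels) Fisher z, NaN where invalid
    pair_index: list[tuple[int, int]]
    group_t: np.ndarray  # (n_voxels,)
    df: int
    mask_sig: np.ndarray  # boolean (n_voxels,)
    clusters: list[Cluster]
    mask: Mask

    @property
    def n_pairs(self) -> int:
        return len(self.pair_index)


@dataclass
class MonteCarloNull:
    max_t: np.ndarray  # (n_perm,) max-voxel group t per permutation

    def critical_t(self, alpha: float) -> float:
        """(1 - alpha) quantile of the max-statistic distribution: the
        FWE-corrected critical t."""
        return float(np.quantile(self.max_t, 1.0 - alpha))


def _zscore_time(bold: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardise each voxel time series; returns (z, valid_voxels)."""
    mu = bold.mean(axis=1, keepdims=True)
    sd = bold.std(axis=1, keepdims=True)
    valid = sd[:, 0] > 0
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (bold - mu) / sd_safe, valid


def fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


def pairwise_isc(group: GroupDataset) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Fisher-z correlation maps for all unordered subject pairs.

    Zero-variance voxels (in either subject of a pair) yield NaN and are
    excluded downstream.
    """
    n = group.n_subjects
    if n < 2:
        raise ValueError("ISC requires at least 2 subjects")
    T = group.n_time
    zs, valids = [], []
    for s in group.subjects:
        z, valid = _zscore_time(s.bold)
        zs.append(z)
        valids.append(valid)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    pair_z = np.empty((len(pairs), group.n_voxels))
    for p, (i, j) in enumerate(pairs):
        r = np.einsum("vt,vt->v", zs[i], zs[j]) / T
        z = fisher_z(r)
        z[~(valids[i] & valids[j])] = np.nan
        pair_z[p] = z
    return pair_z, pairs


def group_ttest(
    pair_z: np.ndarray, min_valid_frac: float = 0.9
) -> tuple[np.ndarray, int]:
    """One-sample t of Fisher z against zero per voxel; df = n_pairs - 1.

    Voxels with fewer than ``min_valid_frac`` of pairs valid are NaN.
    """
    n_pairs = pair_z.shape[0]
    if n_pairs < 2:
        raise ValueError("need at least 2 pairs")
    valid = np.isfinite(pair_z)
    n_valid = valid.sum(axis=0)
    enough = n_valid >= max(2, int(np.ceil(min_valid_frac * n_pairs)))
    t = np.full(pair_z.shape[1], np.nan)
    if enough.any():
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(pair_z[:, enough], axis=0)
            sd = np.nanstd(pair_z[:, enough], axis=0, ddof=1)
            nv = n_valid[enough].astype(float)
            ratio = np.divide(
                mean, sd / np.sqrt(nv), out=np.zeros_like(mean), where=sd > 0
            )
            tt = np.where(
                sd > 0, ratio, np.where(mean == 0, 0.0, np.inf) * np.sign(mean)
            )
        t[enough] = tt
    return t, n_pairs - 1


_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


def threshold_clusters(
    group_t: np.ndarray,
    df: int,
    mask: Mask,
    alpha: float = 0.01,
    fwe_method: str = "fixed_t",
    t_fixed: float = 5.1,
    extent: int = 20,
    connectivity: int = 6,
    null: MonteCarloNull | None = None,
) -> tuple[np.ndarray, list[Cluster]]:
    """Voxelwise threshold plus cluster-extent rule.

    fwe_method: "fixed_t" (use ``t_fixed``), "bonferroni" (alpha over the
    voxel count), or "monte_carlo" (critical t from a max-statistic
    ``null``).  Connected components (face connectivity by default) with
    fewer than ``extent`` voxels are dropped.
    """
    if extent < 1:
        raise ValueError("extent must be >= 1")
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be 6, 18 or 26")
    if fwe_method == "fixed_t":
        crit = t_fixed
    elif fwe_method == "bonferroni":
        n_test = int(np.isfinite(group_t).sum())
        crit = stats.t.ppf(1.0 - alpha / max(n_test, 1), df)
    elif fwe_method == "monte_carlo":
        if null is None:
            raise ValueError("monte_carlo method requires a null distribution")
        crit = null.critical_t(alpha)
    else:
        raise ValueError(f"unknown fwe_method {fwe_method!r}")

    supra = np.isfinite(group_t) & (group_t > crit)
    vol = mask.to_volume(supra.astype(float)) > 0
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    labels, n_lab = ndimage.label(vol, structure=structure)
    lab_flat = mask.from_volume(labels)
    mask_sig = np.zeros(group_t.size, dtype=bool)
    clusters: list[Cluster] = []
    coords = mask.coords
    next_label = 1
    for lab in range(1, n_lab + 1):
        vox = np.flatnonzero(lab_flat == lab)
        if vox.size < extent:
            continue
        peak_local = vox[np.nanargmax(group_t[vox])]
        clusters.append(
            Cluster(
                label=next_label,
                voxels=vox,
                peak_voxel=int(peak_local),
                peak_coord=tuple(int(c) for c in coords[peak_local]),
                peak_stat=float(group_t[peak_local]),
            )
        )
        mask_sig[vox] = True
        next_label += 1
    clusters.sort(key=lambda c: -c.size)
    for i, c in enumerate(clusters):
        c.label = i + 1
    return mask_sig, clusters


def monte_carlo_null(
    group: GroupDataset,
    n_perm: int = 200,
    seed: int = 0,
    min_shift: int = 10,
    min_valid_frac: float = 0.9,
) -> MonteCarloNull:
    """Max-statistic null distribution from circular time shifts.

    Each permutation circularly shifts every subject's series by an
    independent random offset of at least ``min_shift`` TRs and recomputes
    the max-voxel group t.  Because standardisation is shift-invariant,
    the shifted-pair correlation equals the circular cross-correlation of
    the standardised series at the relative lag, which is evaluated for
    all lags at once by FFT.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n, T, V = group.n_subjects, group.n_time, group.n_voxels
    if T <= 2 * min_shift:
        raise ValueError("time series too short for the minimum shift")
    rng = np.random.default_rng(seed)
    zs, valids = [], []
    for s in group.subjects:
        z, valid = _zscore_time(s.bold)
        zs.append(z)
        valids.append(valid)
    ffts = [np.fft.rfft(z, axis=1) for z in zs]
    shifts = rng.integers(min_shift, T - min_shift + 1, size=(n_perm, n))
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    n_pairs = len(pairs)
    sum_z = np.zeros((n_perm, V))
    sum_z2 = np.zeros((n_perm, V))
    n_valid = np.zeros((n_perm, V))
    for i, j in pairs:
        # circular cross-correlation for all lags: (V, T)
        cc = np.fft.irfft(np.conj(ffts[i]) * ffts[j], n=T, axis=1) / T
        lags = (shifts[:, j] - shifts[:, i]) % T  # (n_perm,)
        z = fisher_z(cc[:, lags].T)  # (n_perm, V)
        ok = valids[i] & valids[j]
        z[:, ~ok] = 0.0
        sum_z += z
        sum_z2 += z**2
        n_valid += ok[None, :].astype(float)
    need = max(2, int(np.ceil(min_valid_frac * n_pairs)))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sum_z / n_valid
        var = (sum_z2 - n_valid * mean**2) / (n_valid - 1)
        var = np.maximum(var, 0.0)
        t = mean / np.sqrt(var / n_valid)
    t[:, ~(n_valid[0] >= need)] = -np.inf
    max_t = t.max(axis=1)
    return MonteCarloNull(max_t=max_t)


def run_isc(
    group: GroupDataset,
    alpha: float = 0.01,
    fwe_method: str = "fixed_t",
    t_fixed: float = 5.1,
    extent: int = 20,
    connectivity: int = 6,
    n_perm: int = 200,
    seed: int = 0,
) -> ISCResult:
    """Full ISC stage: pairwise maps, group t, threshold + extent."""
    pair_z, pairs = pairwise_isc(group)
    group_t, df = group_ttest(pair_z)
    null = None
    if fwe_method == "monte_carlo":
        null = monte_carlo_null(group, n_perm=n_perm, seed=seed)
    mask_sig, clusters = threshold_clusters(
        group_t,
        df,
        group.mask,
        alpha=alpha,
        fwe_method=fwe_method,
        t_fixed=t_fixed,
        extent=extent,
        connectivity=connectivity,
        null=null,
    )
    return ISCResult(pair_z, pairs, group_t, df, mask_sig, clusters, group.mask)
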