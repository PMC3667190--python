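"""Shared data containers, volume trimming, and nuisance regression.

The pipeline operates on registered, masked BOLD data: one voxel x time
matrix per subject plus a table of motion confounds (six rigid-body
realignment parameters, one row per volume).  Spatial preprocessing
(realignment, normalisation, smoothing) is assumed to have happened
upstream; everything here works on the matrix representation.

Voxels are indexed in a fixed lexicographic order over the 3-D grid with
the x coordinate varying fastest (Fortran order).  All indexing is 0-based.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Mask",
    "SubjectData",
    "GroupDataset",
    "trim_volumes",
    "regress_out_nuisance",
    "nuisance_design",
    "save_group",
    "load_group",
]

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


@dataclass(frozen=True)
class Mask:
    """Voxel selection on a 3-D grid.

    ``flat_indices`` are indices into the flattened grid in Fortran order
    (x fastest); their order defines the voxel order of every voxel x time
    matrix in the pipeline.
    """

    shape: tuple[int, int, int]
    flat_indices: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.flat_indices, dtype=np.intp)
        if idx.ndim != 1:
            raise ValueError("flat_indices must be 1-D")
        n_grid = int(np.prod(self.shape))
        if idx.size and (idx.min() < 0 or idx.max() >= n_grid):
            raise ValueError("mask indices outside grid")
        object.__setattr__(self, "flat_indices", idx)

    @classmethod
    def full(cls, shape: tuple[int, int, int]) -> "Mask":
        return cls(tuple(shape), np.arange(int(np.prod(shape)), dtype=np.intp))

    @property
    def n_voxels(self) -> int:
        return int(self.flat_indices.size)

    @property
    def coords(self) -> np.ndarray:
        """(n_voxels, 3) integer grid coordinates."""
        xyz = np.unravel_index(self.flat_indices, self.shape, order="F")
        return np.stack(xyz, axis=1)

    def to_volume(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        values = np.asarray(values)
        vol = np.full(int(np.prod(self.shape)), fill, dtype=float)
        vol[self.flat_indices] = values
        return vol.reshape(self.shape, order="F")

    def from_volume(self, vol: np.ndarray) -> np.ndarray:
        return np.asarray(vol).reshape(-1, order="F")[self.flat_indices]

    def __eq__(self, other):
        return (
            isinstance(other, Mask)
            and self.shape == other.shape
            and np.array_equal(self.flat_indices, other.flat_indices)
        )


@dataclass
class SubjectData:
    """One subject's masked BOLD matrix and confound table.

    bold: (n_voxels, n_time); confounds: (n_time, k) with the six motion
    parameters first.
    """

    bold: np.ndarray
    confounds: np.ndarray
    subject_id: str
    tr_seconds: float

    def __post_init__(self):
        self.bold = np.asarray(self.bold, dtype=float)
        self.confounds = np.asarray(self.confounds, dtype=float)
        if self.bold.ndim != 2:
            raise ValueError("bold must be voxel x time")
        if self.confounds.ndim != 2:
            raise ValueError("confounds must be time x k")
        if self.confounds.shape[0] != self.bold.shape[1]:
            raise ValueError(
                f"confound rows ({self.confounds.shape[0]}) must match "
                f"bold time points ({self.bold.shape[1]})"
            )
        if not np.all(np.isfinite(self.bold)):
            raise ValueError("non-finite values in bold data")
        if not np.all(np.isfinite(self.confounds)):
            raise ValueError("non-finite values in confounds")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_voxels(self) -> int:
        return self.bold.shape[0]

    @property
    def n_time(self) -> int:
        return self.bold.shape[1]


@dataclass
class GroupDataset:
    """Cohort container: subjects sharing mask geometry and time length."""

    subjects: list[SubjectData]
    mask: Mask
    tr_seconds: float = field(default=0.0)

    def __post_init__(self):
        if not self.subjects:
            raise ValueError("empty cohort")
        n_vox = {s.n_voxels for s in self.subjects}
        n_time = {s.n_time for s in self.subjects}
        if len(n_vox) != 1 or len(n_time) != 1:
            raise ValueError("subjects disagree on voxel count or time length")
        if n_vox.pop() != self.mask.n_voxels:
            raise ValueError("bold voxel count does not match mask")
        if self.tr_seconds == 0.0:
            self.tr_seconds = self.subjects[0].tr_seconds

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_voxels(self) -> int:
        return self.subjects[0].n_voxels

    @property
    def n_time(self) -> int:
        return self.subjects[0].n_time


def trim_volumes(data: SubjectData, n_start: int, n_end: int) -> SubjectData:
    """Drop ``n_start`` volumes from the start and ``n_end`` from the end.

    Removes onset/offset transients; bold and confounds are truncated
    consistently.
    """
    if n_start < 0 or n_end < 0:
        raise ValueError("trim counts must be non-negative")
    if n_start + n_end >= data.n_time:
        raise ValueError(
            f"cannot trim {n_start}+{n_end} volumes from {data.n_time}"
        )
    stop = data.n_time - n_end
    return replace(
        data,
        bold=data.bold[:, n_start:stop].copy(),
        confounds=data.confounds[n_start:stop].copy(),
    )


def nuisance_design(
    data: SubjectData, include_global: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Build the nuisance design: constant, linear drift, motion, global mean.

    Motion and global columns are demeaned and unit-normalised so the rank
    check is scale-free.
    """
    t = data.n_time
    cols: list[np.ndarray] = [np.ones(t)]
    names = ["constant"]
    drift = np.linspace(-0.5, 0.5, t)
    cols.append(drift)
    names.append("drift")
    for j in range(data.confounds.shape[1]):
        c = data.confounds[:, j].astype(float)
        name = MOTION_COLUMNS[j] if j < len(MOTION_COLUMNS) else f"confound_{j}"
        cols.append(c)
        names.append(name)
    if include_global:
        cols.append(data.bold.mean(axis=0))
        names.append("global")
    X = np.column_stack(cols)
    # demean/normalise everything but the constant; columns that are
    # effectively zero (e.g. the global mean of already-residualised data)
    # are zeroed rather than blown up by normalisation
    X[:, 1:] -= X[:, 1:].mean(axis=0)
    norms = np.linalg.norm(X[:, 1:], axis=0)
    tiny = norms <= max(norms.max(), 1.0) * 1e-10
    X[:, 1:][:, tiny] = 0.0
    keep = ~tiny
    X[:, 1:][:, keep] /= norms[keep]
    return X, names


def _prune_collinear(X: np.ndarray, names: list[str], tol: float = 1e-8):
    """Drop columns that are (near-)linearly dependent on earlier ones."""
    keep: list[int] = []
    dropped: list[str] = []
    basis = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        col = X[:, j]
        if basis.shape[1]:
            resid = col - basis @ (basis.T @ col)
        else:
            resid = col.copy()
        if np.linalg.norm(resid) <= tol * max(np.linalg.norm(col), 1.0):
            dropped.append(names[j])
            continue
        keep.append(j)
        basis = np.column_stack([basis, resid / np.linalg.norm(resid)])
    return X[:, keep], [names[k] for k in keep], dropped


def regress_out_nuisance(
    data: SubjectData, include_global: bool = True
) -> SubjectData:
    """Remove motion, linear drift, constant and (optionally) global mean
    by least-squares projection; returns the residual data.

    Residuals are orthogonal to every retained design column.  Raises if
    the design is rank deficient even after pruning collinear columns.
    """
    X, names = nuisance_design(data, include_global=include_global)
    Xp, kept, dropped = _prune_collinear(X, names)
    if dropped:
        warnings.warn(f"dropped collinear nuisance columns: {dropped}")
    rank = np.linalg.matrix_rank(Xp)
    if rank < Xp.shape[1]:
        raise ValueError(
            f"nuisance design rank deficient after pruning (dropped {dropped})"
        )
    Q, _ = np.linalg.qr(Xp)
    resid = data.bold - (data.bold @ Q) @ Q.T
    return replace(data, bold=resid)


# ---------------------------------------------------------------------------
# I/O: NIfTI (via nibabel) or flat .npy + JSON sidecar; confounds as TSV.


def save_group(
    group: GroupDataset, out_dir: str | Path, fmt: str = "npy", voxel_size: float = 1.0
) -> None:
    """Write a cohort to ``out_dir``.

    fmt="nifti": one 4-D NIfTI per subject (identity affine scaled by
    ``voxel_size``) plus a 3-D mask image.  fmt="npy": flat arrays with a
    JSON sidecar.  Confounds always go to per-subject TSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": fmt,
        "tr_seconds": group.tr_seconds,
        "mask_shape": list(group.mask.shape),
        "subjects": [s.subject_id for s in group.subjects],
    }
    if fmt == "nifti":
        import nibabel as nib

        affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
        mask_img = nib.Nifti1Image(
            group.mask.to_volume(np.ones(group.n_voxels)).astype(np.uint8), affine
        )
        nib.save(mask_img, out / "mask.nii")
        for s in group.subjects:
            vol4d = np.stack(
                [group.mask.to_volume(s.bold[:, t]) for t in range(s.n_time)],
                axis=-1,
            )
            img = nib.Nifti1Image(vol4d.astype(np.float32), affine)
            img.header.set_zooms((voxel_size,) * 3 + (group.tr_seconds,))
            nib.save(img, out / f"{s.subject_id}_bold.nii")
    elif fmt == "npy":
        np.save(out / "mask_indices.npy", group.mask.flat_indices)
        for s in group.subjects:
            np.save(out / f"{s.subject_id}_bold.npy", s.bold)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    for s in group.subjects:
        df = pd.DataFrame(
            s.confounds,
            columns=[
                MOTION_COLUMNS[j] if j < len(MOTION_COLUMNS) else f"confound_{j}"
                for j in range(s.confounds.shape[1])
            ],
        )
        df.to_csv(out / f"{s.subject_id}_confounds.tsv", sep="\t", index=False)
    (out / "dataset.json").write_text(json.dumps(meta, indent=2))


def load_group(in_dir: str | Path) -> GroupDataset:
    """Read a cohort written by :func:`save_group`."""
    src = Path(in_dir)
    meta = json.loads((src / "dataset.json").read_text())
    shape = tuple(meta["mask_shape"])
    tr = float(meta["tr_seconds"])
    if meta["format"] == "nifti":
        import nibabel as nib

        mask_vol = np.asarray(nib.load(src / "mask.nii").dataobj) > 0
        flat = np.flatnonzero(mask_vol.reshape(-1, order="F"))
        mask = Mask(shape, flat)
        subjects = []
        for sid in meta["subjects"]:
            vol4d = np.asarray(nib.load(src / f"{sid}_bold.nii").dataobj, dtype=float)
            bold = np.stack(
                [mask.from_volume(vol4d[..., t]) for t in range(vol4d.shape[-1])],
                axis=1,
            )
            conf = pd.read_csv(src / f"{sid}_confounds.tsv", sep="\t").to_numpy()
            subjects.append(SubjectData(bold, conf, sid, tr))
    else:
        mask = Mask(shape, np.load(src / "mask_indices.npy"))
        subjects = []
        for sid in meta["subjects"]:
            bold = np.load(src / f"{sid}_bold.npy")
            conf = pd.read_csv(src / f"{sid}_confounds.tsv", sep="\t").to_numpy()
            subjects.append(SubjectData(bold, conf, sid, tr))
    return GroupDataset(subjects, mask, tr)
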