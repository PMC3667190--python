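"""Synthetic multi-subject BOLD data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes for a cohort listening to the same naturalistic audio stimulus:

* **extrinsic** components — spatial maps whose time-courses are shared
  across all subjects (stimulus-driven; optionally equal to supplied
  stimulus regressors),
* **intrinsic** components — maps with subject-specific band-limited
  (0.01-0.1 Hz) time-courses, optionally temporally coupled to an
  extrinsic time-course at a prescribed Pearson correlation,
* nuisance structure — per-subject linear drift, a global signal,
  motion-correlated signal driven by a random-walk six-parameter motion
  table, and AR(1)+white Gaussian noise.

Defaults follow the acquisition this pipeline targets: 13 subjects,
451 retained volumes at TR = 2.5 s.  Spatial maps are boxcar blobs on a
small 3-D grid (20 x 20 x 5 by default) so that cluster-extent logic is
exercisable; blob supports are pairwise disjoint unless disabled.  The
default amplitudes put extrinsic signal variance equal to noise variance
at support voxels (SNR 1), which yields pairwise intersubject
correlations near 0.5 there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .prep import Mask, SubjectData, GroupDataset
from .stimreg import Regressor, StimulusTrack

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "SyntheticDataset",
    "bandlimited_noise",
    "make_coupled_intrinsic",
    "generate_dataset",
    "synthesize_audio_tracks",
]


@dataclass
class SynthConfig:
    n_subjects: int = 13
    grid_shape: tuple[int, int, int] = (20, 20, 5)
    n_volumes: int = 451
    tr_seconds: float = 2.5
    n_extrinsic: int = 4
    n_intrinsic: int = 4
    support_shape: tuple[int, int, int] = (5, 5, 2)
    extrinsic_amplitude: float = 1.0
    intrinsic_amplitude: float = 1.0
    noise_sd: float = 1.0
    ar1_coef: float = 0.3
    drift_amplitude: float = 1.0
    global_amplitude: float = 0.5
    motion_amplitude: float = 0.5
    coupling: np.ndarray | None = None  # (n_intrinsic, n_extrinsic) target r
    disjoint_supports: bool = True
    seed: int = 0


@dataclass
class GroundTruth:
    extrinsic_maps: np.ndarray  # (n_extrinsic, n_voxels), unit max |loading|
    extrinsic_timecourses: np.ndarray  # (n_extrinsic, T), shared
    intrinsic_maps: np.ndarray  # (n_intrinsic, n_voxels)
    intrinsic_timecourses: np.ndarray  # (n_subjects, n_intrinsic, T)
    coupling: np.ndarray  # (n_intrinsic, n_extrinsic)
    noise_sd: float
    ar1_coef: float
    drift_slopes: np.ndarray  # (n_subjects,)
    global_amplitude: float
    motion_tables: np.ndarray  # (n_subjects, T, 6)
    seed: int

    @property
    def all_maps(self) -> np.ndarray:
        return np.vstack([self.extrinsic_maps, self.intrinsic_maps])


@dataclass
class SyntheticDataset:
    subjects: list[SubjectData]
    truth: GroundTruth
    mask_shape: tuple[int, int, int]
    tr_seconds: float

    @property
    def group(self) -> GroupDataset:
        return GroupDataset(self.subjects, Mask.full(self.mask_shape), self.tr_seconds)


def _zscore(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("constant series cannot be standardised")
    return x / sd


def bandlimited_noise(
    n_time: int,
    fs_hz: float,
    rng: np.random.Generator,
    band_hz: tuple[float, float] = (0.01, 0.1),
) -> np.ndarray:
    """Unit-variance Gaussian noise restricted to a frequency band,
    emulating resting-state-like slow fluctuations."""
    white = rng.standard_normal(n_time)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_time, d=1.0 / fs_hz)
    keep = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not keep.any():  # degenerate band: keep the lowest nonzero bin
        keep = np.zeros_like(freqs, dtype=bool)
        keep[min(1, keep.size - 1)] = True
    spec[~keep] = 0.0
    return _zscore(np.fft.irfft(spec, n=n_time))


def make_coupled_intrinsic(
    extrinsic_tc: np.ndarray,
    rho: float,
    seed: int,
    fs_hz: float = 0.4,
) -> np.ndarray:
    """A unit-variance series with sample correlation ``rho`` to
    ``extrinsic_tc``.

    Fresh band-limited noise is orthogonalised against the target and the
    two are mixed with weights rho and sqrt(1 - rho^2), so the sample
    correlation equals rho to machine precision.
    """
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    x = _zscore(np.asarray(extrinsic_tc, dtype=float))
    rng = np.random.default_rng(seed)
    n = bandlimited_noise(x.size, fs_hz, rng)
    n = n - (n @ x) / (x @ x) * x  # exact orthogonalisation
    n = _zscore(n)
    return rho * x + np.sqrt(1.0 - rho**2) * n


def _place_supports(
    cfg: SynthConfig, n_components: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Boxcar blob supports as flat voxel index arrays (Fortran order)."""
    gx, gy, gz = cfg.grid_shape
    bx, by, bz = cfg.support_shape
    if bx > gx or by > gy or bz > gz:
        raise ValueError("support blob larger than grid")
    if cfg.disjoint_supports:
        slots = [
            (ix * bx, iy * by, iz * bz)
            for ix in range(gx // bx)
            for iy in range(gy // by)
            for iz in range(gz // bz)
        ]
        if n_components > len(slots):
            raise ValueError("not enough disjoint blob slots for components")
        corners = [slots[i] for i in rng.permutation(len(slots))[:n_components]]
    else:
        corners = [
            (
                rng.integers(0, gx - bx + 1),
                rng.integers(0, gy - by + 1),
                rng.integers(0, gz - bz + 1),
            )
            for _ in range(n_components)
        ]
    supports = []
    for cx, cy, cz in corners:
        xs, ys, zs = np.meshgrid(
            np.arange(cx, cx + bx),
            np.arange(cy, cy + by),
            np.arange(cz, cz + bz),
            indexing="ij",
        )
        flat = np.ravel_multi_index(
            (xs.ravel(), ys.ravel(), zs.ravel()), cfg.grid_shape, order="F"
        )
        supports.append(np.sort(flat))
    return supports


def _ar1_noise(
    shape: tuple[int, ...], sd: float, phi: float, rng: np.random.Generator
) -> np.ndarray:
    """AR(1) noise with marginal standard deviation ``sd`` and lag-1
    coefficient ``phi`` along the last axis."""
    if sd == 0:
        return np.zeros(shape)
    burn = 100
    n_time = shape[-1]
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    w = rng.normal(0.0, innov_sd, shape[:-1] + (n_time + burn,))
    e = lfilter([1.0], [1.0, -phi], w, axis=-1)
    return e[..., burn:]


def generate_dataset(
    config: SynthConfig, regressors: list[Regressor] | None = None
) -> SyntheticDataset:
    """Generate a cohort with full ground truth; deterministic given
    ``config.seed``.

    If stimulus ``regressors`` are supplied, the first extrinsic
    time-courses are the standardised regressors (their length must equal
    ``config.n_volumes``); remaining extrinsic time-courses are shared
    band-limited noise.
    """
    cfg = config
    if cfg.noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    n_vox = int(np.prod(cfg.grid_shape))
    n_comp = cfg.n_extrinsic + cfg.n_intrinsic
    if n_comp > n_vox:
        raise ValueError("component count exceeds voxel count")
    if regressors is not None and len(regressors) > cfg.n_extrinsic:
        raise ValueError("more regressors than extrinsic components")
    seq = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(seq)
    T = cfg.n_volumes
    fs = 1.0 / cfg.tr_seconds

    supports = _place_supports(cfg, n_comp, rng)
    maps = np.zeros((n_comp, n_vox))
    for c, sup in enumerate(supports):
        maps[c, sup] = 1.0  # boxcar, unit maximum absolute loading
    ext_maps, int_maps = maps[: cfg.n_extrinsic], maps[cfg.n_extrinsic :]

    ext_tcs = np.empty((cfg.n_extrinsic, T))
    n_reg = len(regressors) if regressors else 0
    for r in range(n_reg):
        vals = regressors[r].values
        if vals.size != T:
            raise ValueError("regressor length must equal n_volumes")
        ext_tcs[r] = _zscore(vals)
    for c in range(n_reg, cfg.n_extrinsic):
        ext_tcs[c] = bandlimited_noise(T, fs, rng)

    coupling = (
        np.zeros((cfg.n_intrinsic, cfg.n_extrinsic))
        if cfg.coupling is None
        else np.asarray(cfg.coupling, dtype=float)
    )
    if coupling.shape != (cfg.n_intrinsic, cfg.n_extrinsic):
        raise ValueError("coupling must be (n_intrinsic, n_extrinsic)")

    int_tcs = np.empty((cfg.n_subjects, cfg.n_intrinsic, T))
    drift_slopes = rng.normal(0.0, 1.0, cfg.n_subjects) * cfg.drift_amplitude
    motion_tables = np.empty((cfg.n_subjects, T, 6))
    subject_seeds = seq.spawn(cfg.n_subjects)

    subjects: list[SubjectData] = []
    drift_shape = np.linspace(-0.5, 0.5, T)
    for s in range(cfg.n_subjects):
        srng = np.random.default_rng(subject_seeds[s])
        for c in range(cfg.n_intrinsic):
            nz = np.flatnonzero(coupling[c])
            if nz.size:
                e = int(nz[0])
                int_tcs[s, c] = make_coupled_intrinsic(
                    ext_tcs[e],
                    float(coupling[c, e]),
                    seed=int(srng.integers(2**31)),
                    fs_hz=fs,
                )
            else:
                int_tcs[s, c] = bandlimited_noise(T, fs, srng)

        bold = cfg.extrinsic_amplitude * ext_maps.T @ ext_tcs
        bold = bold + cfg.intrinsic_amplitude * int_maps.T @ int_tcs[s]
        if cfg.drift_amplitude:
            # per-voxel drift gain: scanner drift is not spatially uniform
            gain = srng.uniform(0.5, 1.5, n_vox)
            bold = bold + drift_slopes[s] * gain[:, None] * drift_shape[None, :]
        if cfg.global_amplitude:
            g = bandlimited_noise(T, fs, srng)
            bold = bold + cfg.global_amplitude * g[None, :]
        # motion: random-walk table, injected through random spatial weights
        steps = srng.normal(0.0, 0.02, (T, 6))
        motion = np.cumsum(steps, axis=0)
        motion_tables[s] = motion
        if cfg.motion_amplitude:
            mz = motion - motion.mean(axis=0)
            sds = mz.std(axis=0)
            sds[sds == 0] = 1.0
            mz = mz / sds
            weights = srng.normal(0.0, 1.0, (n_vox, 6)) / np.sqrt(6.0)
            bold = bold + cfg.motion_amplitude * weights @ mz.T
        bold = bold + _ar1_noise((n_vox, T), cfg.noise_sd, cfg.ar1_coef, srng)
        subjects.append(
            SubjectData(bold, motion, subject_id=f"sub-{s + 1:02d}", tr_seconds=cfg.tr_seconds)
        )

    truth = GroundTruth(
        extrinsic_maps=ext_maps,
        extrinsic_timecourses=ext_tcs,
        intrinsic_maps=int_maps,
        intrinsic_timecourses=int_tcs,
        coupling=coupling,
        noise_sd=cfg.noise_sd,
        ar1_coef=cfg.ar1_coef,
        drift_slopes=drift_slopes,
        global_amplitude=cfg.global_amplitude,
        motion_tables=motion_tables,
        seed=cfg.seed,
    )
    return SyntheticDataset(subjects, truth, cfg.grid_shape, cfg.tr_seconds)


def synthesize_audio_tracks(
    duration_s: float,
    rate_hz: float = 8000.0,
    seed: int = 0,
    duty: tuple[float, float] = (0.60, 0.65),
    segment_s: float = 2.5,
) -> tuple[StimulusTrack, StimulusTrack]:
    """Two synthetic audio tracks standing in for separated speech and
    non-speech soundtracks.

    Each track is noise carried by an on/off segment pattern with the
    given duty cycles; the "speech" track adds a syllabic-rate (4 Hz)
    amplitude modulation.  Purely synthetic: no linguistic content.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    n_seg = max(1, int(np.ceil(duration_s / segment_s)))

    def _gate(duty_frac: float, r: np.random.Generator) -> np.ndarray:
        on = r.random(n_seg) < duty_frac
        seg_idx = np.minimum((t / segment_s).astype(int), n_seg - 1)
        gate = on[seg_idx].astype(float)
        # smooth the gate edges (~50 ms) to avoid clicks
        width = max(1, int(0.05 * rate_hz))
        kernel = np.ones(width) / width
        return np.convolve(gate, kernel, mode="same")

    speech_carrier = rng.standard_normal(n)
    speech_mod = 0.55 + 0.45 * np.sin(2 * np.pi * 4.0 * t + rng.uniform(0, 2 * np.pi))
    speech = speech_carrier * speech_mod * _gate(duty[0], rng)
    nonspeech = (
        rng.standard_normal(n) * 0.6
        + 0.4 * np.sin(2 * np.pi * 220.0 * t)
    ) * _gate(duty[1], rng)
    return (
        StimulusTrack(speech, rate_hz, label="speech"),
        StimulusTrack(nonspeech, rate_hz, label="non_speech"),
    )
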