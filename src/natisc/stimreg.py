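"""Stimulus regressor construction from audio waveforms.

The chain mirrors standard practice for naturalistic auditory fMRI:

1. full-wave rectification of the track,
2. low-pass filtering (Butterworth, zero-phase, 8 Hz cut-off by default)
   and decimation (factor 16: 48 kHz -> 3 kHz) to obtain the amplitude
   envelope,
3. convolution with a canonical double-gamma haemodynamic response
   function (HRF),
4. polyphase FIR anti-aliased resampling down to the scanner sampling
   rate 1/TR (0.4 Hz at TR = 2.5 s), and
5. truncation to the retained volume range, mirroring the EPI trimming.

The module also computes windowed-RMS presence/loudness statistics used to
characterise how often each sound category is present and which one is
louder when both are active.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile
from scipy.stats import gamma as gamma_dist

__all__ = [
    "StimulusTrack",
    "Regressor",
    "AudioStats",
    "HRFSpec",
    "hrf_kernel",
    "envelope",
    "to_regressor",
    "audio_stats",
    "read_wav",
    "read_csv_track",
    "write_regressors_tsv",
    "read_regressors_tsv",
]


@dataclass
class StimulusTrack:
    """A mono waveform for one sound category (speech or non_speech)."""

    samples: np.ndarray
    rate_hz: float
    label: str = "stimulus"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz


@dataclass
class Regressor:
    """A stimulus time course sampled at the fMRI rate (1/TR)."""

    values: np.ndarray
    rate_hz: float
    label: str = "stimulus"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite regressor values")


@dataclass
class AudioStats:
    """Windowed-RMS summary of one track relative to another.

    presence_fraction: fraction of windows whose RMS exceeds the silence
    threshold.  louder_fraction: among windows where both tracks are
    present, the fraction where this track is louder (ties split 50/50).
    mean_db_difference: mean 20*log10(RMS ratio) over co-active windows.
    The last two are NaN when no window is co-active.
    """

    presence_fraction: float
    louder_fraction: float
    mean_db_difference: float


@dataclass(frozen=True)
class HRFSpec:
    """Canonical double-gamma HRF: response peak ~6 s, undershoot ~16 s,
    peak/undershoot amplitude ratio 6, 32 s support."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    undershoot_ratio: float = 6.0
    duration_s: float = 32.0


def hrf_kernel(spec: HRFSpec, rate_hz: float) -> np.ndarray:
    """Sample the double-gamma HRF at ``rate_hz``, normalised to unit sum
    (unit DC gain, so regressor scale is rate-independent)."""
    t = np.arange(0.0, spec.duration_s, 1.0 / rate_hz)
    peak = gamma_dist.pdf(
        t, spec.peak_delay_s / spec.peak_dispersion_s, scale=spec.peak_dispersion_s
    )
    under = gamma_dist.pdf(
        t,
        spec.undershoot_delay_s / spec.undershoot_dispersion_s,
        scale=spec.undershoot_dispersion_s,
    )
    h = peak - under / spec.undershoot_ratio
    s = h.sum()
    if s <= 0:
        raise ValueError("degenerate HRF kernel")
    return h / s


def envelope(
    track: StimulusTrack, cutoff_hz: float = 8.0, decim: int = 16, order: int = 4
) -> StimulusTrack:
    """Amplitude envelope: full-wave rectify, zero-phase Butterworth
    low-pass, then decimate by an integer factor.

    With the defaults a 48 kHz track yields a 3 kHz envelope.
    """
    if decim < 1 or int(decim) != decim:
        raise ValueError("decim must be a positive integer")
    if cutoff_hz >= track.rate_hz / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    rect = np.abs(track.samples)
    sos = signal.butter(order, cutoff_hz, fs=track.rate_hz, output="sos")
    smooth = signal.sosfiltfilt(sos, rect)
    return StimulusTrack(
        smooth[:: int(decim)], track.rate_hz / decim, label=track.label
    )


def _resample_fraction(rate_in: float, rate_out: float) -> Fraction:
    frac = Fraction(rate_out).limit_denominator(10**6) / Fraction(
        rate_in
    ).limit_denominator(10**6)
    return frac.limit_denominator(10**7)


def to_regressor(
    env: StimulusTrack,
    tr_seconds: float,
    hrf: HRFSpec | None = None,
    n_volumes: int | None = None,
    trim_start: int = 0,
    trim_end: int = 0,
) -> Regressor:
    """HRF-convolve an envelope and resample it to the fMRI rate 1/TR.

    Resampling uses a polyphase Hamming-windowed-sinc FIR anti-aliasing
    filter.  If ``n_volumes`` is given the output is matched to that length
    and then truncated by ``trim_start``/``trim_end`` volumes, mirroring
    the EPI volume trimming.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    target_hz = 1.0 / tr_seconds
    if env.rate_hz < target_hz:
        raise ValueError("envelope rate below target fMRI rate")
    hrf = hrf or HRFSpec()
    kernel = hrf_kernel(hrf, env.rate_hz)
    conv = signal.fftconvolve(env.samples, kernel, mode="full")[: env.samples.size]
    frac = _resample_fraction(env.rate_hz, target_hz)
    up, down = frac.numerator, frac.denominator
    values = signal.resample_poly(conv, up, down, window="hamming")
    prov = [
        f"hrf_convolved(peak={hrf.peak_delay_s}s)",
        f"resampled({env.rate_hz}->{target_hz}Hz, polyphase hamming FIR)",
    ]
    if n_volumes is not None:
        if values.size < n_volumes:
            values = np.pad(values, (0, n_volumes - values.size), mode="edge")
            prov.append(f"edge_padded_to({n_volumes})")
        elif values.size > n_volumes:
            values = values[:n_volumes]
            prov.append(f"truncated_to({n_volumes})")
        if trim_start + trim_end >= values.size:
            raise ValueError("over-trimming regressor")
        values = values[trim_start : values.size - trim_end]
        if trim_start or trim_end:
            prov.append(f"trimmed({trim_start},{trim_end})")
    return Regressor(values, target_hz, label=env.label, provenance=prov)


def audio_stats(
    a: StimulusTrack,
    b: StimulusTrack,
    window_s: float = 0.1,
    silence_db: float = -40.0,
) -> tuple[AudioStats, AudioStats]:
    """Windowed-RMS presence and relative loudness of two tracks.

    Each track's silence threshold is ``silence_db`` relative to its own
    maximum window RMS.  Returns one :class:`AudioStats` per track; the
    dB difference of the second track is the negative of the first's.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if a.rate_hz != b.rate_hz or a.samples.size != b.samples.size:
        raise ValueError("tracks must share sampling rate and duration")
    win = max(1, int(round(window_s * a.rate_hz)))
    n_win = a.samples.size // win
    if n_win == 0:
        raise ValueError("track shorter than one window")

    def _rms(x: np.ndarray) -> np.ndarray:
        seg = x[: n_win * win].reshape(n_win, win)
        return np.sqrt(np.mean(seg**2, axis=1))

    rms_a, rms_b = _rms(a.samples), _rms(b.samples)

    def _present(r: np.ndarray) -> np.ndarray:
        peak = r.max()
        if peak == 0:
            return np.zeros_like(r, dtype=bool)
        return r > peak * 10 ** (silence_db / 20.0)

    pres_a, pres_b = _present(rms_a), _present(rms_b)
    both = pres_a & pres_b
    if not both.any():
        return (
            AudioStats(pres_a.mean(), math.nan, math.nan),
            AudioStats(pres_b.mean(), math.nan, math.nan),
        )
    ra, rb = rms_a[both], rms_b[both]
    louder_a = (np.sum(ra > rb) + 0.5 * np.sum(ra == rb)) / both.sum()
    db_diff = float(np.mean(20.0 * np.log10(ra / rb)))
    return (
        AudioStats(float(pres_a.mean()), float(louder_a), db_diff),
        AudioStats(float(pres_b.mean()), float(1.0 - louder_a), -db_diff),
    )


# ---------------------------------------------------------------------------
# I/O


def read_wav(path: str | Path, label: str = "stimulus") -> StimulusTrack:
    """Read a PCM WAV file as a mono track (channels averaged), scaled
    to [-1, 1] for integer encodings."""
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    return StimulusTrack(data.astype(float), float(rate), label=label)


def read_csv_track(
    path: str | Path, rate_hz: float, label: str = "stimulus"
) -> StimulusTrack:
    values = np.loadtxt(str(path), delimiter=",")
    return StimulusTrack(values, rate_hz, label=label)


def write_regressors_tsv(regressors: list[Regressor], path: str | Path) -> None:
    """Write regressors as a TSV with one column per label; the sampling
    rate is recorded in a header comment."""
    if not regressors:
        raise ValueError("no regressors")
    n = {r.values.size for r in regressors}
    if len(n) != 1:
        raise ValueError("regressor lengths differ")
    df = pd.DataFrame({r.label: r.values for r in regressors})
    with open(path, "w") as fh:
        fh.write(f"# rate_hz={regressors[0].rate_hz}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_regressors_tsv(path: str | Path) -> list[Regressor]:
    with open(path) as fh:
        header = fh.readline().strip()
        rate = float(header.split("=", 1)[1]) if header.startswith("#") else None
        df = pd.read_csv(fh, sep="\t")
    if rate is None:
        raise ValueError("missing rate header")
    return [
        Regressor(df[c].to_numpy(), rate, label=str(c)) for c in df.columns
    ]
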