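"""Framewise spectral analysis and per-call acoustic feature extraction.

The analysis chain mirrors the classic batch workflow for tonal primate
calls: decimate to 11.05 kHz, compute a 1024-point FFT every 32 samples
(~11 Hz frequency resolution over a 5.5 kHz band, ~2.9 ms frame spacing),
classify each frame as noisy / complex / tonal from the periodicity of its
normalized autocorrelation, estimate F0 and harmonic-to-noise ratio on
tonal frames, and summarize the distribution of spectral amplitude per
frame through its quartile frequencies and peak frequency.  A fixed,
versioned catalogue of 112 named per-call features is then aggregated from
the framewise tracks.

Frame classification rules (thresholds configurable):

* no autocorrelation peak above ``peak_height`` in the lag band -> noisy;
* peaks present whose lags deviate from a harmonic series by more than
  ``harmonic_tol`` -> complex;
* periodic peaks -> tonal, F0 = rate / best lag (parabolic interpolation),
  HNR = 10 log10(r / (1 - r)) at the interpolated peak height r.

Octave jumps in the F0 track are suppressed automatically: the lag track is
median filtered and frames deviating more than 40% from the filtered track
are snapped back to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import fft as spfft
from scipy import signal as sps

from .synth import CallRecording

__all__ = [
    "SpectroParams",
    "FrameTable",
    "preprocess",
    "spectrogram",
    "classify_and_track_f0",
    "frame_energy_features",
    "extract_features",
    "extract_table",
    "impute_tonal_features",
    "feature_catalogue",
    "CATALOGUE_VERSION",
    "ChannelError",
    "DegenerateInputError",
]

CATALOGUE_VERSION = "1.0"


class ChannelError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


@dataclass
class SpectroParams:
    """Spectrogram and F0-tracking parameters.

    Defaults give 10.79 Hz bins (reported rounded as 11 Hz), a 5.5 kHz
    band, and 32/11050 s = 2.896 ms frame spacing.
    """

    target_rate: int = 11050
    fft_len: int = 1024
    hop: int = 32
    window: str = "hamming"
    f0_min: float = 150.0
    f0_max: float = 1500.0
    peak_height: float = 0.4      # normalized autocorrelation height for a peak
    harmonic_tol: float = 0.15    # relative deviation tolerated for "periodic"
    max_jump: float = 0.4         # octave-jump suppression threshold on the lag track
    floor_db: float = -30.0       # relative floor for global frequency range
    peak_prominence: float = 0.05  # relative prominence for global energy peaks

    def __post_init__(self) -> None:
        if self.fft_len & (self.fft_len - 1):
            raise ValueError("fft_len must be a power of two")
        if self.hop > self.fft_len:
            raise ValueError("hop must be <= fft_len")
        if not (self.f0_min < self.f0_max <= self.target_rate / 2 / 3):
            raise ValueError("need f0_min < f0_max <= Nyquist/3")

    @property
    def freq_resolution(self) -> float:
        return self.target_rate / self.fft_len

    @property
    def freq_range(self) -> float:
        return self.target_rate / 2.0

    @property
    def time_resolution(self) -> float:
        return self.hop / self.target_rate


@dataclass
class FrameTable:
    """Framewise analysis results for one call."""

    times: np.ndarray                 # frame centers, s
    spectra: np.ndarray               # n_frames x n_bins amplitude spectra
    freqs: np.ndarray                 # bin center frequencies, Hz
    frames: np.ndarray | None = None  # windowed time-domain segments
    frame_class: np.ndarray | None = None   # 'noisy' | 'complex' | 'tonal'
    f0: np.ndarray | None = None            # Hz, NaN where not tonal
    hnr: np.ndarray | None = None           # dB, NaN where not tonal
    peak_freq: np.ndarray | None = None
    q1: np.ndarray | None = None
    q2: np.ndarray | None = None
    q3: np.ndarray | None = None
    energy: np.ndarray | None = None
    zero_frames: np.ndarray | None = None


# ---------------------------------------------------------------------------
# preprocessing and spectrogram
# ---------------------------------------------------------------------------

_DECIM_FILTERS: dict[tuple[int, int], np.ndarray] = {}


def _antialias_filter(rate: int, target: int) -> np.ndarray:
    key = (rate, target)
    if key not in _DECIM_FILTERS:
        # sharp linear-phase lowpass just under the target Nyquist; the
        # narrow transition keeps energy above the analysis band suppressed
        cutoff = 0.484 * target
        ntaps = 2047
        _DECIM_FILTERS[key] = sps.firwin(ntaps, cutoff, fs=rate)
    return _DECIM_FILTERS[key]


def preprocess(recording: CallRecording, params: SpectroParams | None = None) -> np.ndarray:
    """Anti-aliased decimation of a mono recording to the analysis rate."""
    params = params or SpectroParams()
    wav = np.asarray(recording.waveform, dtype=float)
    if wav.ndim != 1:
        raise ChannelError("expected a mono waveform")
    rate = recording.sample_rate
    if rate == params.target_rate:
        return wav
    if rate < 2 * params.target_rate:
        raise DegenerateInputError(
            f"sampling rate {rate} below 2x target {params.target_rate}; upsampling refused"
        )
    h = _antialias_filter(rate, params.target_rate)
    filtered = sps.fftconvolve(wav, h, mode="same")  # symmetric taps: zero net delay
    frac = math.gcd(params.target_rate, rate)
    up, down = params.target_rate // frac, rate // frac
    return sps.resample_poly(filtered, up, down)


def spectrogram(waveform: np.ndarray, params: SpectroParams | None = None) -> FrameTable:
    """Short-time amplitude spectra at hop spacing."""
    params = params or SpectroParams()
    x = np.asarray(waveform, dtype=float)
    if len(x) < params.fft_len:
        raise DegenerateInputError(
            f"waveform of {len(x)} samples shorter than one {params.fft_len}-pt frame"
        )
    win = sps.get_window(params.window, params.fft_len, fftbins=True)
    frames = np.lib.stride_tricks.sliding_window_view(x, params.fft_len)[:: params.hop]
    tapered = frames * win
    spectra = np.abs(np.fft.rfft(tapered, axis=1))
    freqs = np.fft.rfftfreq(params.fft_len, d=1.0 / params.target_rate)
    centers = (np.arange(len(frames)) * params.hop + params.fft_len / 2) / params.target_rate
    return FrameTable(times=centers, spectra=spectra, freqs=freqs, frames=tapered)


# ---------------------------------------------------------------------------
# frame classification and F0
# ---------------------------------------------------------------------------


def _parabolic(y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through (i-1, i, i+1); returns (pos, height)."""
    if i <= 0 or i >= len(y) - 1:
        return float(i), float(y[i])
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return float(i), float(b)
    delta = 0.5 * (a - c) / denom
    return i + delta, b - 0.25 * (a - c) * delta


def classify_and_track_f0(table: FrameTable, params: SpectroParams | None = None) -> FrameTable:
    """Classify frames and estimate F0/HNR from normalized autocorrelation."""
    params = params or SpectroParams()
    if table.frames is None:
        raise ValueError("need time-domain frames; run spectrogram() first")
    frames = table.frames - table.frames.mean(axis=1, keepdims=True)
    n = frames.shape[1]

    sr = params.target_rate
    lag_min = max(2, int(np.floor(sr / params.f0_max)))
    lag_max = min(n - 2, int(np.ceil(sr / params.f0_min)))

    nfft = spfft.next_fast_len(n + lag_max + 2, real=True)
    spec = np.fft.rfft(frames, n=nfft, axis=1)
    ac = np.fft.irfft(np.abs(spec) ** 2, n=nfft, axis=1)[:, : lag_max + 2]
    norm = ac[:, :1].copy()
    norm[norm <= 0] = 1.0
    ac = ac / norm

    n_frames = frames.shape[0]
    f0 = np.full(n_frames, np.nan)
    hnr = np.full(n_frames, np.nan)
    best_lag = np.full(n_frames, np.nan)

    # local maxima above threshold within the admissible lag band
    band = ac[:, lag_min : lag_max + 2]
    inner = band[:, 1:-1]
    peak_mask = (inner > band[:, :-2]) & (inner >= band[:, 2:]) & (inner >= params.peak_height)
    has_peak = peak_mask.any(axis=1)

    heights = np.where(peak_mask, inner, -np.inf)
    top = np.argmax(heights, axis=1) + lag_min + 1  # lag of the highest peak
    top_safe = np.where(has_peak, top, 1)

    # periodicity: every detected peak lag must sit near an integer multiple
    # of the candidate period
    lag_grid = np.arange(lag_min + 1, lag_max + 1, dtype=float)
    ratio = lag_grid[None, :] / top_safe[:, None]
    mult = np.round(ratio)
    dev = np.abs(ratio - mult)
    aperiodic = peak_mask & ((dev > params.harmonic_tol) | (mult < 1))
    is_complex = has_peak & aperiodic.any(axis=1)
    is_tonal = has_peak & ~is_complex

    frame_class = np.full(n_frames, "noisy", dtype=object)
    frame_class[is_complex] = "complex"
    frame_class[is_tonal] = "tonal"

    # parabolic lag interpolation and HNR for tonal frames
    idx = np.flatnonzero(is_tonal)
    if len(idx):
        ti = top_safe[idx]
        a = ac[idx, ti - 1]
        b = ac[idx, ti]
        c = ac[idx, ti + 1]
        denom = a - 2 * b + c
        delta = np.where(denom != 0, 0.5 * (a - c) / np.where(denom == 0, 1.0, denom), 0.0)
        delta = np.clip(delta, -0.5, 0.5)
        pos = ti + delta
        height = np.clip(b - 0.25 * (a - c) * delta, 1e-6, 1.0 - 1e-6)
        best_lag[idx] = pos
        f0[idx] = sr / pos
        hnr[idx] = 10.0 * np.log10(height / (1.0 - height))

    # octave-jump suppression on the lag track
    tonal = frame_class == "tonal"
    if tonal.sum() >= 3:
        lags_t = best_lag[tonal]
        med = sps.medfilt(lags_t, kernel_size=min(5, 2 * (len(lags_t) // 2) + 1))
        bad = np.abs(lags_t - med) / med > params.max_jump
        lags_t[bad] = med[bad]
        best_lag[tonal] = lags_t
        f0[tonal] = sr / lags_t

    table.frame_class = frame_class
    table.f0 = f0
    table.hnr = hnr
    return table


def frame_energy_features(table: FrameTable, params: SpectroParams | None = None) -> FrameTable:
    """Quartile frequencies, peak frequency and energy per frame.

    Quartile k is the center frequency of the first bin at which the
    cumulative (linear) amplitude reaches k/4 of the frame total; all-zero
    frames get 0 Hz quartiles and are flagged.
    """
    params = params or SpectroParams()
    S = table.spectra
    totals = S.sum(axis=1)
    zero = totals <= 0
    safe_tot = np.where(zero, 1.0, totals)
    cum = np.cumsum(S, axis=1) / safe_tot[:, None]
    qs = []
    for kq in (0.25, 0.5, 0.75):
        idx = np.argmax(cum >= kq, axis=1)
        qs.append(np.where(zero, 0.0, table.freqs[idx]))
    table.q1, table.q2, table.q3 = qs
    table.peak_freq = table.freqs[np.argmax(S, axis=1)]
    table.peak_freq = np.where(zero, 0.0, table.peak_freq)
    table.energy = totals
    table.zero_frames = zero
    return table


# ---------------------------------------------------------------------------
# the 112-feature catalogue
# ---------------------------------------------------------------------------

_TRACKS = [
    ("f0", "Hz", "fundamental frequency (tonal frames)"),
    ("hnr", "dB", "harmonic-to-noise ratio (tonal frames)"),
    ("peak_freq", "Hz", "framewise peak frequency"),
    ("q1", "Hz", "first amplitude quartile frequency"),
    ("q2", "Hz", "second amplitude quartile frequency"),
    ("q3", "Hz", "third amplitude quartile frequency"),
    ("energy", "lin", "frame amplitude sum"),
]

_STATS = [
    ("mean", "mean over frames"),
    ("min", "minimum over frames"),
    ("max", "maximum over frames"),
    ("start", "value in the first frame"),
    ("end", "value in the last frame"),
    ("range", "max - min"),
    ("sd", "standard deviation over frames"),
    ("slope", "linear trend per second"),
    ("loc_max", "time of maximum as fraction of duration"),
    ("loc_min", "time of minimum as fraction of duration"),
]

_GLOBAL = [
    ("duration", "s", "call duration"),
    ("tonal_fraction", "1", "fraction of tonal frames"),
    ("complex_fraction", "1", "fraction of complex frames"),
    ("noisy_fraction", "1", "fraction of noisy frames"),
    ("n_tonal_segments", "count", "number of contiguous tonal stretches"),
    ("longest_tonal_segment", "s", "duration of the longest tonal stretch"),
    ("tonal_onset", "1", "time of first tonal frame as fraction of duration"),
    ("tonal_offset", "1", "time of last tonal frame as fraction of duration"),
    ("amp_ratio_f0_h2", "dB", "mean amplitude ratio F0 vs 2nd harmonic"),
    ("amp_ratio_f0_h3", "dB", "mean amplitude ratio F0 vs 3rd harmonic"),
    ("amp_ratio_f0_h3_max", "dB", "max amplitude ratio F0 vs 3rd harmonic"),
    ("amp_ratio_f0_h3_min", "dB", "min amplitude ratio F0 vs 3rd harmonic"),
    ("harmonic_richness", "count", "harmonics above the amplitude floor in the mean spectrum"),
    ("global_peak_freq", "Hz", "peak of the call-average spectrum"),
    ("global_freq_min", "Hz", "lowest bin above the relative floor"),
    ("global_freq_max", "Hz", "highest bin above the relative floor"),
    ("global_freq_range", "Hz", "global_freq_max - global_freq_min"),
    ("n_global_energy_peaks", "count", "prominent peaks in the call-average spectrum"),
    ("global_peak1_freq", "Hz", "frequency of the strongest global energy peak"),
    ("global_peak2_freq", "Hz", "frequency of the 2nd global energy peak"),
    ("global_peak2_rel_amp", "dB", "2nd global peak amplitude relative to the 1st"),
    ("global_q1", "Hz", "first amplitude quartile of the call-average spectrum"),
    ("global_q2", "Hz", "second amplitude quartile of the call-average spectrum"),
    ("global_q3", "Hz", "third amplitude quartile of the call-average spectrum"),
    ("spectral_centroid_mean", "Hz", "mean framewise amplitude-weighted frequency"),
    ("spectral_centroid_sd", "Hz", "sd of framewise amplitude-weighted frequency"),
    ("iqr_freq_mean", "Hz", "mean framewise q3 - q1"),
    ("iqr_freq_sd", "Hz", "sd of framewise q3 - q1"),
    ("time_of_max_energy", "1", "time of the loudest frame as fraction of duration"),
    ("f0_cv", "1", "coefficient of variation of F0"),
    ("f0_arch_height", "Hz", "max F0 minus mean of start/end F0"),
    ("f0_start_slope", "Hz/s", "F0 slope over the first third of tonal frames"),
    ("f0_end_slope", "Hz/s", "F0 slope over the last third of tonal frames"),
    ("q2_start_slope", "Hz/s", "q2 slope over the first third of the call"),
    ("q2_end_slope", "Hz/s", "q2 slope over the last third of the call"),
]

#: Features that are undefined on calls without tonal frames.
TONAL_FEATURES = frozenset(
    [f"f0_{s}" for s, _ in _STATS]
    + [f"hnr_{s}" for s, _ in _STATS]
    + ["f0_delta", "hnr_delta",
       "amp_ratio_f0_h2", "amp_ratio_f0_h3", "amp_ratio_f0_h3_max", "amp_ratio_f0_h3_min",
       "harmonic_richness", "tonal_onset", "tonal_offset", "longest_tonal_segment",
       "f0_cv", "f0_arch_height", "f0_start_slope", "f0_end_slope"]
)


def feature_catalogue() -> pd.DataFrame:
    """The fixed, ordered manifest of per-call features (112 entries)."""
    rows = []
    for track, unit, desc in _TRACKS:
        for stat, sdesc in _STATS:
            u = unit if stat not in ("slope", "loc_max", "loc_min") else (
                "1" if stat.startswith("loc") else f"{unit}/s")
            rows.append((f"{track}_{stat}", u, f"{sdesc} of {desc}"))
    for track, unit, desc in _TRACKS:
        rows.append((f"{track}_delta", unit, f"mean absolute frame-to-frame change of {desc}"))
    for name, unit, desc in _GLOBAL:
        rows.append((name, unit, desc))
    return pd.DataFrame(rows, columns=["name", "unit", "description"])


def _track_stats(values: np.ndarray, times: np.ndarray, duration: float) -> dict[str, float]:
    valid = np.isfinite(values)
    out = {s: np.nan for s, _ in _STATS}
    if valid.sum() == 0:
        return out
    v, t = values[valid], times[valid]
    out["mean"] = float(np.mean(v))
    out["min"] = float(np.min(v))
    out["max"] = float(np.max(v))
    out["start"] = float(v[0])
    out["end"] = float(v[-1])
    out["range"] = out["max"] - out["min"]
    out["sd"] = float(np.std(v))
    out["slope"] = float(np.polyfit(t, v, 1)[0]) if len(v) >= 2 else 0.0
    out["loc_max"] = float(t[np.argmax(v)] / duration) if duration > 0 else np.nan
    out["loc_min"] = float(t[np.argmin(v)] / duration) if duration > 0 else np.nan
    return out


def _segment_slope(values: np.ndarray, times: np.ndarray, part: str) -> float:
    valid = np.isfinite(values)
    v, t = values[valid], times[valid]
    if len(v) < 3:
        return np.nan
    k = max(2, len(v) // 3)
    if part == "start":
        v, t = v[:k], t[:k]
    else:
        v, t = v[-k:], t[-k:]
    return float(np.polyfit(t, v, 1)[0])


def _amp_at(spectrum: np.ndarray, freqs: np.ndarray, f: float) -> float:
    """Spectral amplitude near f: max over the bin and its neighbours."""
    i = int(np.argmin(np.abs(freqs - f)))
    lo, hi = max(0, i - 1), min(len(spectrum), i + 2)
    return float(np.max(spectrum[lo:hi]))


def extract_features(
    recording: CallRecording,
    params: SpectroParams | None = None,
) -> pd.Series:
    """Full per-call feature vector (one entry per catalogue name).

    Tonal-dependent features are NaN on calls without tonal frames; the
    table-level extractor imputes them and flags the call.
    """
    params = params or SpectroParams()
    wav = preprocess(recording, params)
    table = spectrogram(wav, params)
    table = classify_and_track_f0(table, params)
    table = frame_energy_features(table, params)

    duration = len(wav) / params.target_rate
    t = table.times
    feats: dict[str, float] = {}

    tracks = {
        "f0": table.f0,
        "hnr": table.hnr,
        "peak_freq": table.peak_freq,
        "q1": table.q1,
        "q2": table.q2,
        "q3": table.q3,
        "energy": table.energy,
    }
    for name, values in tracks.items():
        stats = _track_stats(np.asarray(values, dtype=float), t, duration)
        for s, _ in _STATS:
            feats[f"{name}_{s}"] = stats[s]
    for name, values in tracks.items():
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        feats[f"{name}_delta"] = float(np.mean(np.abs(np.diff(v)))) if len(v) >= 2 else np.nan

    cls = table.frame_class
    n_frames = len(cls)
    tonal = cls == "tonal"
    feats["duration"] = duration
    feats["tonal_fraction"] = float(tonal.mean())
    feats["complex_fraction"] = float((cls == "complex").mean())
    feats["noisy_fraction"] = float((cls == "noisy").mean())

    # contiguous tonal stretches
    runs = []
    count = 0
    for flag in tonal:
        if flag:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    feats["n_tonal_segments"] = float(len(runs))
    feats["longest_tonal_segment"] = (max(runs) * params.time_resolution) if runs else np.nan
    if tonal.any():
        feats["tonal_onset"] = float(t[tonal][0] / duration)
        feats["tonal_offset"] = float(t[tonal][-1] / duration)
    else:
        feats["tonal_onset"] = np.nan
        feats["tonal_offset"] = np.nan

    # harmonic amplitude ratios on tonal frames (amplitude near k*f0 taken
    # as the max over the nearest bin and its neighbours)
    ti = np.flatnonzero(tonal)
    if len(ti):
        df_bin = table.freqs[1] - table.freqs[0]
        spec_t = table.spectra[ti]
        nbins = spec_t.shape[1]

        def harm_amp(k: int) -> np.ndarray:
            ctr = np.clip(np.round(k * table.f0[ti] / df_bin).astype(int), 1, nbins - 2)
            stacked = np.stack([spec_t[np.arange(len(ti)), ctr + o] for o in (-1, 0, 1)])
            return stacked.max(axis=0)

        a1, a2, a3 = harm_amp(1), harm_amp(2), harm_amp(3)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = 20.0 * np.log10(a1 / a2)
            r3 = 20.0 * np.log10(a1 / a3)
        r2 = r2[np.isfinite(r2)]
        r3 = r3[np.isfinite(r3)]
    else:
        r2 = r3 = np.array([])
    feats["amp_ratio_f0_h2"] = float(np.mean(r2)) if len(r2) else np.nan
    feats["amp_ratio_f0_h3"] = float(np.mean(r3)) if len(r3) else np.nan
    feats["amp_ratio_f0_h3_max"] = float(np.max(r3)) if len(r3) else np.nan
    feats["amp_ratio_f0_h3_min"] = float(np.min(r3)) if len(r3) else np.nan

    # call-average spectrum descriptors
    avg = table.spectra.mean(axis=0)
    peak_amp = avg.max()
    if peak_amp <= 0:
        for nm in ("global_peak_freq", "global_freq_min", "global_freq_max",
                   "global_freq_range", "global_q1", "global_q2", "global_q3",
                   "global_peak1_freq", "global_peak2_freq"):
            feats[nm] = 0.0
        feats["n_global_energy_peaks"] = 0.0
        feats["global_peak2_rel_amp"] = np.nan
        feats["harmonic_richness"] = np.nan
    else:
        floor = peak_amp * 10.0 ** (params.floor_db / 20.0)
        above = np.flatnonzero(avg >= floor)
        feats["global_peak_freq"] = float(table.freqs[np.argmax(avg)])
        feats["global_freq_min"] = float(table.freqs[above[0]])
        feats["global_freq_max"] = float(table.freqs[above[-1]])
        feats["global_freq_range"] = feats["global_freq_max"] - feats["global_freq_min"]
        cum = np.cumsum(avg) / avg.sum()
        for kq, nm in ((0.25, "global_q1"), (0.5, "global_q2"), (0.75, "global_q3")):
            feats[nm] = float(table.freqs[np.argmax(cum >= kq)])
        pk, props = sps.find_peaks(avg, prominence=params.peak_prominence * peak_amp)
        feats["n_global_energy_peaks"] = float(len(pk))
        if len(pk) >= 1:
            order = np.argsort(avg[pk])[::-1]
            feats["global_peak1_freq"] = float(table.freqs[pk[order[0]]])
            if len(pk) >= 2:
                feats["global_peak2_freq"] = float(table.freqs[pk[order[1]]])
                feats["global_peak2_rel_amp"] = float(
                    20.0 * np.log10(avg[pk[order[1]]] / avg[pk[order[0]]])
                )
            else:
                feats["global_peak2_freq"] = feats["global_peak1_freq"]
                feats["global_peak2_rel_amp"] = 0.0
        else:
            feats["global_peak1_freq"] = feats["global_peak_freq"]
            feats["global_peak2_freq"] = feats["global_peak_freq"]
            feats["global_peak2_rel_amp"] = 0.0
        if tonal.any() and np.isfinite(feats["f0_mean"]) and feats["f0_mean"] > 0:
            k = 1
            while k * feats["f0_mean"] < table.freqs[-1] and \
                    _amp_at(avg, table.freqs, k * feats["f0_mean"]) >= floor:
                k += 1
            feats["harmonic_richness"] = float(k - 1)
        else:
            feats["harmonic_richness"] = np.nan

    centroid = (table.spectra * table.freqs).sum(axis=1) / np.where(
        table.energy > 0, table.energy, 1.0)
    feats["spectral_centroid_mean"] = float(np.mean(centroid))
    feats["spectral_centroid_sd"] = float(np.std(centroid))
    iqr = table.q3 - table.q1
    feats["iqr_freq_mean"] = float(np.mean(iqr))
    feats["iqr_freq_sd"] = float(np.std(iqr))
    feats["time_of_max_energy"] = float(t[np.argmax(table.energy)] / duration)

    if tonal.any():
        f0v = table.f0[tonal]
        feats["f0_cv"] = float(np.std(f0v) / np.mean(f0v)) if np.mean(f0v) > 0 else np.nan
        feats["f0_arch_height"] = float(np.max(f0v) - 0.5 * (f0v[0] + f0v[-1]))
        feats["f0_start_slope"] = _segment_slope(table.f0, t, "start")
        feats["f0_end_slope"] = _segment_slope(table.f0, t, "end")
    else:
        feats["f0_cv"] = np.nan
        feats["f0_arch_height"] = np.nan
        feats["f0_start_slope"] = np.nan
        feats["f0_end_slope"] = np.nan
    feats["q2_start_slope"] = _segment_slope(table.q2, t, "start")
    feats["q2_end_slope"] = _segment_slope(table.q2, t, "end")

    order = feature_catalogue()["name"].tolist()
    return pd.Series({name: feats[name] for name in order}, name=recording.call_id)


def impute_tonal_features(df: pd.DataFrame, female_ids: pd.Series) -> pd.DataFrame:
    """Fill tonal features of fully non-tonal calls.

    Uses the within-individual mean where available, otherwise the run
    mean; adds a boolean ``imputed_tonal`` column flagging affected calls.
    """
    out = df.copy()
    nan_rows = out.isna().any(axis=1)
    out["imputed_tonal"] = nan_rows
    if not nan_rows.any():
        return out
    feat_cols = [c for c in df.columns]
    by_female = out[feat_cols].groupby(female_ids.values).transform("mean")
    run_mean = out[feat_cols].mean()
    for c in feat_cols:
        out[c] = out[c].fillna(by_female[c]).fillna(run_mean[c])
    return out


def extract_table(
    calls: Sequence[CallRecording],
    params: SpectroParams | None = None,
    impute: bool = True,
) -> pd.DataFrame:
    """Feature matrix for a set of calls (rows ordered as given).

    Index = call_id; first column = female_id; remaining columns follow the
    catalogue order.  With ``impute=True`` tonal features of fully
    non-tonal calls are filled (within-female mean, then run mean) so the
    result has no missing values.
    """
    params = params or SpectroParams()
    rows = [extract_features(c, params) for c in calls]
    df = pd.DataFrame(rows)
    female = pd.Series([c.female_id for c in calls], index=df.index, name="female_id")
    if impute:
        df = impute_tonal_features(df, female)
    df.insert(0, "female_id", female)
    df = df.copy()  # defragment after the imputation column inserts
    df.index.name = "call_id"
    return df


class CooFeatureExtractor:
    """Transformer-style wrapper: lists of CallRecording -> feature matrix.

    Follows the scikit-learn transformer protocol (stateless fit,
    ``transform`` returning a DataFrame) so the extractor can sit in a
    Pipeline in front of :class:`cookin.dfa.StepwiseLDA`.
    """

    def __init__(self, params: SpectroParams | None = None, impute: bool = True):
        self.params = params
        self.impute = impute

    def get_params(self, deep: bool = True) -> dict:
        return {"params": self.params, "impute": self.impute}

    def set_params(self, **kw) -> "CooFeatureExtractor":
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    def fit(self, X: Sequence[CallRecording], y=None) -> "CooFeatureExtractor":
        self.n_features_out_ = len(feature_catalogue())
        return self

    def transform(self, X: Sequence[CallRecording]) -> pd.DataFrame:
        return extract_table(X, self.params, impute=self.impute)

    def fit_transform(self, X: Sequence[CallRecording], y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)
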