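"""Frame-based extraction of the seven acoustic call parameters.

The analyser mirrors a conventional bioacoustic workflow: short Hann-windowed
frames on a fixed hop, a dynamic-range gate that drops quiet frames,
autocorrelation pitch tracking inside a fixed pitch window, and per-frame
spectral statistics (energy quartiles, Wiener entropy, spectral slope)
averaged over the retained frames.

Default settings follow the study protocol for little auk chick calls:
48 kHz audio, 60 dB dynamic range, 800–3500 Hz pitch window, 5 ms step.
The window length (1024 samples ≈ 21.3 ms) resolves at least two periods of
the 800 Hz pitch floor while keeping ~60 frames on a 0.3 s call.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import uniform_filter1d

from .schema import (
    CallRecording,
    CallTooShortError,
    ConfigError,
    DataError,
    FeatureVector,
    SilentCallError,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisSettings:
    """Analyser configuration.

    Attributes
    ----------
    sample_rate : Hz of the expected input audio.
    dynamic_range_db : frames whose RMS falls more than this below the
        loudest frame are excluded from all spectral averaging.
    pitch_floor_hz, pitch_ceiling_hz : f0 search window.
    step_ms : hop between frame centres.
    window_samples : analysis window length (Hann taper).
    voicing_threshold : minimum normalised autocorrelation peak for a frame
        to count as voiced.
    entropy_smooth_bins : moving-average width (spectral bins) applied to the
        power spectrum before Wiener entropy; compensates the downward bias
        that single-bin periodogram fluctuations impose on the geometric mean.
    pooled_spectrum : if True, quartiles/slope/entropy are computed on the
        energy-summed spectrum of all retained frames instead of per frame.
    """

    sample_rate: int = 48000
    dynamic_range_db: float = 60.0
    pitch_floor_hz: float = 800.0
    pitch_ceiling_hz: float = 3500.0
    step_ms: float = 5.0
    window_samples: int = 1024
    voicing_threshold: float = 0.45
    f0_spectral_support: float = 0.05
    entropy_smooth_bins: int = 9
    pooled_spectrum: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.pitch_floor_hz < self.pitch_ceiling_hz:
            raise ConfigError("need 0 < pitch floor < pitch ceiling")
        if self.pitch_ceiling_hz >= self.sample_rate / 2:
            raise ConfigError("pitch ceiling must lie below Nyquist")
        if self.hop_samples > self.window_samples:
            raise ConfigError("step must not exceed the window length")

    @property
    def hop_samples(self) -> int:
        return max(1, int(round(self.step_ms * 1e-3 * self.sample_rate)))


@dataclass
class FrameSpectra:
    """Windowed per-frame power spectra plus the retained-frame mask."""

    freqs_hz: np.ndarray        # (n_bins,)
    power: np.ndarray           # (n_frames, n_bins)
    retained: np.ndarray        # (n_frames,) bool
    frames: np.ndarray          # (n_frames, window) raw (unwindowed) frames
    settings: AnalysisSettings = field(repr=False)

    @property
    def retained_power(self) -> np.ndarray:
        return self.power[self.retained]


def _frame_signal(samples: np.ndarray, window: int, hop: int) -> np.ndarray:
    if samples.size < window:
        raise CallTooShortError(
            f"call too short: {samples.size} samples < one {window}-sample window"
        )
    return sliding_window_view(samples, window)[::hop]


def frame_spectra(samples: np.ndarray, settings: AnalysisSettings) -> FrameSpectra:
    """Short-time power spectra with dynamic-range gating.

    Frames whose RMS is more than ``dynamic_range_db`` below the loudest
    frame's RMS are masked out of all spectral averaging.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise DataError("empty waveform")
    frames = _frame_signal(samples, settings.window_samples, settings.hop_samples)
    rms = np.sqrt(np.mean(frames**2, axis=1))
    peak = rms.max()
    if peak <= 0:
        raise SilentCallError("silent call: zero energy in every frame")
    with np.errstate(divide="ignore"):
        rel_db = 20.0 * np.log10(np.where(rms > 0, rms / peak, np.nan))
    retained = np.nan_to_num(rel_db, nan=-np.inf) > -settings.dynamic_range_db

    taper = np.hanning(settings.window_samples)
    spec = np.fft.rfft(frames * taper, axis=1)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(settings.window_samples, d=1.0 / settings.sample_rate)
    return FrameSpectra(freqs_hz=freqs, power=power, retained=retained,
                        frames=frames, settings=settings)


def track_f0(fs: FrameSpectra) -> Tuple[np.ndarray, Optional[float]]:
    """Autocorrelation pitch track over the retained frames.

    Per frame the normalised autocorrelation is searched for its maximum at
    lags inside the pitch window; the peak position is refined by parabolic
    interpolation. Frames whose peak falls below the voicing threshold are
    unvoiced (NaN). Returns (per-frame f0 array aligned with all frames,
    mean f0 over voiced frames or None).
    """
    s = fs.settings
    win = s.window_samples
    lag_min = max(2, int(np.ceil(s.sample_rate / s.pitch_ceiling_hz)))
    lag_max = min(win - 2, int(np.floor(s.sample_rate / s.pitch_floor_hz)))
    if lag_max <= lag_min:
        raise ConfigError("pitch window leaves no searchable lag range")

    frames = fs.frames - fs.frames.mean(axis=1, keepdims=True)
    nfft = 2 * win
    spec = np.fft.rfft(frames, n=nfft, axis=1)
    acf = np.fft.irfft(np.abs(spec) ** 2, axis=1)[:, :win]
    r0 = acf[:, :1]
    valid = r0[:, 0] > 0
    norm = np.where(r0 > 0, acf / np.where(r0 > 0, r0, 1.0), 0.0)
    # unbiased-lag correction keeps long-lag peaks comparable with lag 0
    lags = np.arange(win)
    norm = norm * (win / np.maximum(win - lags, 1))

    f0 = np.full(fs.power.shape[0], np.nan)
    for i in np.nonzero(fs.retained & valid)[0]:
        # local maxima, refined by parabolic interpolation: at a non-integer
        # period the integer-lag sample underestimates the true peak height
        seg = norm[i, lag_min - 1 : lag_max + 2]
        inner = seg[1:-1]
        is_max = (inner >= seg[:-2]) & (inner >= seg[2:])
        idx = np.flatnonzero(is_max)
        if idx.size == 0:
            continue
        y0, y1, y2 = seg[idx], seg[idx + 1], seg[idx + 2]
        denom = y0 - 2 * y1 + y2
        shift = np.where(denom < 0, 0.5 * (y0 - y2) / np.where(denom < 0, denom, 1), 0.0)
        height = np.where(denom < 0, y1 - 0.125 * (y0 - y2) ** 2 / np.where(denom < 0, denom, 1), y1)
        # spectral confirmation: a real pitch candidate has energy at its
        # own fundamental; a subharmonic ACF peak (octave error driven by
        # inter-harmonic energy) does not
        lag_cand = lag_min + idx + shift
        freq_cand = s.sample_rate / lag_cand
        df = fs.freqs_hz[1] - fs.freqs_hz[0]
        frame_max = fs.power[i].max()
        support = np.empty(idx.size, dtype=bool)
        for j, fc in enumerate(freq_cand):
            b = int(round(fc / df))
            blo, bhi = max(b - 2, 0), min(b + 3, fs.power.shape[1])
            support[j] = (fs.power[i, blo:bhi].max()
                          >= s.f0_spectral_support * frame_max)
        usable = support & (height >= s.voicing_threshold)
        if not usable.any():
            continue
        # among supported near-threshold peaks, rank by harmonic summation:
        # the true fundamental aligns spectral energy at all its multiples,
        # which neither subharmonic ACF peaks nor stray band peaks do
        best_j, best_score = -1, -np.inf
        for j in np.flatnonzero(usable):
            score = 0.0
            for k in range(1, 6):
                b = int(round(k * freq_cand[j] / df))
                if b >= fs.power.shape[1]:
                    break
                blo, bhi = max(b - 2, 0), min(b + 3, fs.power.shape[1])
                score += fs.power[i, blo:bhi].max()
            if score > best_score:
                best_j, best_score = int(j), score
        cand = float(freq_cand[best_j])
        if s.pitch_floor_hz <= cand <= s.pitch_ceiling_hz:
            f0[i] = cand
    voiced = f0[np.isfinite(f0)]
    mean_f0 = float(voiced.mean()) if voiced.size else None
    return f0, mean_f0


def _per_frame_or_pooled(fs: FrameSpectra) -> np.ndarray:
    power = fs.retained_power
    if power.shape[0] == 0:
        raise DataError("no retained frames")
    if fs.settings.pooled_spectrum:
        return power.sum(axis=0, keepdims=True)
    return power


def spectral_quartiles(fs: FrameSpectra) -> Tuple[float, float, float]:
    """Energy quartiles Q25/Q50/Q75 in Hz, averaged over retained frames.

    Per frame, the frequency at which the cumulative spectral power crosses
    25/50/75% of the frame total, linearly interpolated between bins.
    """
    power = _per_frame_or_pooled(fs)
    totals = power.sum(axis=1)
    if np.any(totals <= 0):
        ok = totals > 0
        if not ok.any():
            raise DataError("all-zero spectrum")
        logger.debug("spectral_quartiles: skipping %d zero-power frames", (~ok).sum())
        power, totals = power[ok], totals[ok]
    cum = np.cumsum(power, axis=1) / totals[:, None]
    qs = []
    for p in (0.25, 0.50, 0.75):
        per_frame = [np.interp(p, cum[i], fs.freqs_hz) for i in range(cum.shape[0])]
        qs.append(float(np.mean(per_frame)))
    return qs[0], qs[1], qs[2]


def wiener_entropy(fs: FrameSpectra) -> float:
    """Mean Wiener entropy over retained frames, in [0, 1].

    Per frame: geometric / arithmetic mean of the (lightly smoothed) power
    spectrum. 0 = pure tone, 1 = white noise. Zero-power frames are skipped.
    """
    power = _per_frame_or_pooled(fs)
    k = max(1, int(fs.settings.entropy_smooth_bins))
    smooth = uniform_filter1d(power, size=k, axis=1, mode="nearest")
    totals = smooth.sum(axis=1)
    ok = totals > 0
    if not ok.any():
        raise DataError("all-zero spectrum")
    if not ok.all():
        logger.debug("wiener_entropy: skipping %d zero-power frames", (~ok).sum())
    smooth = smooth[ok]
    am = smooth.mean(axis=1)
    floor = am[:, None] * 1e-12
    gm = np.exp(np.mean(np.log(smooth + floor), axis=1))
    ent = np.clip(gm / am, 0.0, 1.0)
    return float(ent.mean())


def spectral_slope(fs: FrameSpectra) -> float:
    """OLS slope of the max-normalised magnitude spectrum vs frequency (kHz).

    Averaged over retained frames; more negative = steeper high-frequency
    roll-off. Scale-invariant by the per-frame normalisation.
    """
    power = _per_frame_or_pooled(fs)
    mag = np.sqrt(power)
    peak = mag.max(axis=1, keepdims=True)
    peak = np.where(peak > 0, peak, 1.0)
    y = mag / peak
    x = fs.freqs_hz / 1000.0
    xc = x - x.mean()
    slopes = (y - y.mean(axis=1, keepdims=True)) @ xc / (xc @ xc)
    return float(slopes.mean())


def extract_features(
    recording: CallRecording, settings: Optional[AnalysisSettings] = None
) -> FeatureVector:
    """Extract the seven acoustic parameters from one annotated call.

    Duration is the annotated call length. A call with no voiced frame keeps
    its spectral features but is flagged (``f0_missing``) so downstream
    statistics can exclude it.
    """
    settings = settings or AnalysisSettings()
    if recording.sample_rate != settings.sample_rate:
        raise ConfigError(
            f"call {recording.call_id}: sample rate {recording.sample_rate} "
            f"!= analysis rate {settings.sample_rate}"
        )
    fs = frame_spectra(recording.samples, settings)
    _, mean_f0 = track_f0(fs)
    q25, q50, q75 = spectral_quartiles(fs)
    if mean_f0 is None:
        logger.info("call %s: no voiced frame, mean f0 missing", recording.call_id)
    return FeatureVector(
        duration_s=recording.duration_s,
        mean_f0_hz=mean_f0,
        q25_hz=q25,
        q50_hz=q50,
        q75_hz=q75,
        spectral_slope_per_khz=spectral_slope(fs),
        mean_entropy=wiener_entropy(fs),
        f0_missing=mean_f0 is None,
    )
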