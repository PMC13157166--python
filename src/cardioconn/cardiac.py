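"""Cardiac autonomic processing: from pulse recordings to per-subject HRV profiles.

The processing chain mirrors a standard wearable-PPG resting protocol:

1. beat detection on the photoplethysmogram (optional front end),
2. exclusion of the first 60 s of recording for physiological stabilization,
3. artifact flagging on the interbeat-interval (IBI) series,
4. division of artifact-free spans into 40-60 s segments with a 2-beat
   buffer around every flagged interval,
5. per-segment metrics -- mean IBI, mean heart rate, RMSSD, SDNN and
   high-frequency (0.15-0.40 Hz) spectral power from an autoregressive
   spectrum of the uniformly resampled tachogram,
6. unweighted averaging of segment metrics into an AutonomicProfile,
   with the HF power reported on the natural-log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import integrate, interpolate
from scipy.ndimage import median_filter
from statsmodels.regression.linear_model import burg

__all__ = [
    "PPGSignal",
    "BeatRecord",
    "Segment",
    "SegmentMetrics",
    "AutonomicProfile",
    "detect_beats",
    "trim_stabilization",
    "flag_artifacts",
    "segment_series",
    "segment_metrics",
    "ar_psd",
    "ar_band_power",
    "aggregate_profile",
    "process_beats",
]

HF_BAND_HZ = (0.15, 0.40)
LF_BAND_HZ = (0.04, 0.15)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class PPGSignal:
    """Raw photoplethysmogram (blood volume pulse), arbitrary amplitude units."""

    samples: np.ndarray
    sampling_rate_hz: float = 64.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not np.all(np.isfinite(samples)):
            raise ValueError("PPG samples must be finite")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz


@dataclass
class BeatRecord:
    """Ordered beat times with derived interbeat intervals and artifact flags.

    ``ibis_ms[k]`` is the interval ending at beat ``k + 1``;
    ``artifact_flags`` is per-interval and defaults to all clean.
    """

    beat_times_s: np.ndarray
    artifact_flags: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = np.asarray(self.beat_times_s, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("need at least two beat times")
        if not np.all(np.isfinite(t)):
            raise ValueError("beat times must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValueError("beat times must be strictly increasing")
        self.beat_times_s = t
        if self.artifact_flags is None:
            self.artifact_flags = np.zeros(t.size - 1, dtype=bool)
        else:
            flags = np.asarray(self.artifact_flags, dtype=bool)
            if flags.shape != (t.size - 1,):
                raise ValueError("artifact_flags must have one entry per interval")
            self.artifact_flags = flags

    @property
    def ibis_ms(self) -> np.ndarray:
        return 1000.0 * np.diff(self.beat_times_s)

    @property
    def n_intervals(self) -> int:
        return self.beat_times_s.size - 1

    @property
    def duration_s(self) -> float:
        return float(self.beat_times_s[-1] - self.beat_times_s[0])


@dataclass(frozen=True)
class Segment:
    """Half-open interval-index range [start, end) of artifact-free IBIs."""

    start: int
    end: int
    duration_s: float

    @property
    def n_intervals(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SegmentMetrics:
    mean_ibi_ms: float
    mean_hr_bpm: float
    rmssd_ms: float
    sdnn_ms: float
    hf_power_ms2: float
    hf_peak_hz: float
    duration_s: float = float("nan")


@dataclass(frozen=True)
class ProfileQC:
    n_segments: int
    mean_segment_duration_s: float
    total_analyzed_s: float
    hf_peak_plausible: bool


@dataclass(frozen=True)
class AutonomicProfile:
    """Segment-averaged autonomic metrics for one subject."""

    mean_ibi_ms: float
    mean_hr_bpm: float
    rmssd_ms: float
    sdnn_ms: float
    hf_power_ms2: float
    ln_hf_power: float
    qc: ProfileQC
    usable: bool = True

    def to_dict(self) -> dict:
        return {
            "mean_ibi_ms": self.mean_ibi_ms,
            "mean_hr_bpm": self.mean_hr_bpm,
            "rmssd_ms": self.rmssd_ms,
            "sdnn_ms": self.sdnn_ms,
            "hf_power_ms2": self.hf_power_ms2,
            "ln_hf_power": self.ln_hf_power,
            "n_segments": self.qc.n_segments,
            "mean_segment_duration_s": self.qc.mean_segment_duration_s,
            "total_analyzed_s": self.qc.total_analyzed_s,
            "hf_peak_plausible": self.qc.hf_peak_plausible,
            "usable": self.usable,
        }


# ---------------------------------------------------------------------------
# beat detection (simple documented substitute for proprietary detectors)


def detect_beats(ppg: PPGSignal, refractory_s: float = 0.3) -> BeatRecord:
    """Detect systolic upstroke maxima in a PPG signal.

    Band-passes 0.5-8 Hz, then picks local maxima above an adaptive
    threshold (half the local pulse envelope, tracked over a 2 s rolling
    window) subject to a 300 ms refractory period.  This is a deliberately
    simple detector intended for clean resting recordings.
    """
    x = ppg.samples
    fs = ppg.sampling_rate_hz
    if x.size < 10 * fs:
        raise ValueError("need at least 10 s of PPG signal")
    if np.ptp(x) == 0:
        raise ValueError("no beats detected: flat signal")

    nyq = fs / 2.0
    sos = sps.butter(2, [0.5 / nyq, min(8.0, 0.95 * nyq) / nyq], btype="bandpass", output="sos")
    xf = sps.sosfiltfilt(sos, x)

    # local amplitude envelope from a rolling maximum of |xf|
    win = max(3, int(round(2.0 * fs)))
    from scipy.ndimage import maximum_filter1d

    env = maximum_filter1d(np.abs(xf), size=win, mode="nearest")
    env = np.maximum(env, 1e-12)

    distance = max(1, int(round(refractory_s * fs)))
    peaks, _ = sps.find_peaks(xf, distance=distance)
    peaks = peaks[xf[peaks] >= 0.5 * env[peaks]]
    if peaks.size < 2:
        raise ValueError("no beats detected")
    return BeatRecord(beat_times_s=peaks / fs)


# ---------------------------------------------------------------------------
# trimming, artifact flagging, segmentation


def trim_stabilization(beats: BeatRecord, trim_s: float = 60.0) -> BeatRecord:
    """Drop all beats earlier than ``trim_s`` (half-open: t >= trim_s kept)."""
    if trim_s < 0:
        raise ValueError("trim_s must be non-negative")
    if trim_s == 0:
        return beats
    t = beats.beat_times_s
    if t[-1] <= trim_s:
        raise ValueError(f"record ends at {t[-1]:.1f} s, shorter than trim_s={trim_s:g} s")
    keep = t >= trim_s
    if keep.sum() < 2:
        raise ValueError("fewer than two beats remain after stabilization trim")
    first = int(np.argmax(keep))
    # flags indexed per interval; interval k spans beats (k, k+1)
    return BeatRecord(beat_times_s=t[first:], artifact_flags=beats.artifact_flags[first:])


def flag_artifacts(
    beats: BeatRecord,
    rel_thr: float = 0.30,
    abs_thr_ms: float = 250.0,
    window: int = 11,
) -> BeatRecord:
    """Flag aberrant intervals against a running median.

    Interval k is flagged iff ``|IBI_k - med_k|`` exceeds
    ``max(rel_thr * med_k, abs_thr_ms)`` where ``med_k`` is the running
    median over ``window`` intervals (edges padded by replication).  The
    two thresholds act jointly as a floor: setting both to zero flags
    every interval with any deviation at all (degenerate limit).
    """
    ibis = beats.ibis_ms
    med = median_filter(ibis, size=window, mode="nearest")
    thr = np.maximum(rel_thr * med, abs_thr_ms)
    flags = np.abs(ibis - med) > thr
    return BeatRecord(beat_times_s=beats.beat_times_s, artifact_flags=flags)


def _clean_spans(flags: np.ndarray, buffer_beats: int) -> list[tuple[int, int]]:
    """Maximal runs [start, end) of intervals clear of flags and their buffers."""
    n = flags.size
    excluded = flags.copy()
    idx = np.flatnonzero(flags)
    for k in idx:
        excluded[max(0, k - buffer_beats) : min(n, k + buffer_beats + 1)] = True
    spans = []
    start = None
    for i in range(n):
        if not excluded[i]:
            if start is None:
                start = i
        elif start is not None:
            spans.append((start, i))
            start = None
    if start is not None:
        spans.append((start, n))
    return spans


def segment_series(
    beats: BeatRecord,
    min_s: float = 40.0,
    max_s: float = 60.0,
    buffer_beats: int = 2,
) -> list[Segment]:
    """Divide artifact-free spans into 40-60 s segments.

    Within each maximal artifact-free span (flagged intervals plus a
    ``buffer_beats``-interval guard on each side removed), windows are
    placed greedily from the span start: intervals are accumulated while
    the window duration stays <= ``max_s``; a terminal remainder of at
    least ``min_s`` becomes a final segment.  No interval belongs to two
    segments and an empty result is allowed.
    """
    ibis_s = beats.ibis_ms / 1000.0
    segments: list[Segment] = []
    for span_start, span_end in _clean_spans(beats.artifact_flags, buffer_beats):
        i = span_start
        while i < span_end:
            j = i
            dur = 0.0
            while j < span_end and dur + ibis_s[j] <= max_s:
                dur += ibis_s[j]
                j += 1
            if j == i:  # single interval longer than max_s: skip it
                i += 1
                continue
            if dur >= min_s:
                segments.append(Segment(start=i, end=j, duration_s=dur))
            i = j
    return segments


# ---------------------------------------------------------------------------
# spectral machinery


def _ar_spectrum(x: np.ndarray, order: int, fs: float):
    """Burg AR spectrum of ``x``.

    Returns ``(psd_func, lines)`` where ``psd_func`` evaluates the
    one-sided density 2 sigma^2 / (fs |A(e^{-i 2 pi f / fs})|^2) and
    ``lines`` is a list of (frequency_hz, half_width_hz) pairs for the AR
    poles, used to build quadrature grids that resolve arbitrarily sharp
    spectral lines (a noise-free sinusoid drives poles within ~1e-7 of
    the unit circle, giving lines far narrower than any uniform grid).
    """
    x = np.asarray(x, dtype=float)
    phi, sigma2 = burg(x, order=order, demean=True)
    phi = np.asarray(phi, dtype=float)
    k = np.arange(1, phi.size + 1)

    def shape(f):
        f = np.atleast_1d(np.asarray(f, dtype=float))
        a = 1.0 - np.exp(-2j * np.pi * np.outer(f, k) / fs) @ phi.astype(complex)
        return 2.0 * sigma2 / fs / np.abs(a) ** 2

    roots = np.roots(np.concatenate(([1.0], -phi)))
    freqs = np.abs(np.angle(roots)) * fs / (2.0 * np.pi)
    widths = np.maximum(-np.log(np.minimum(np.abs(roots), 1.0 - 1e-15)), 1e-13) * fs / (
        2.0 * np.pi
    )
    lines = sorted({(round(float(f), 12), float(w)) for f, w in zip(freqs, widths)})

    # variance-matching normalization: the Burg innovation variance does
    # not guarantee that the model spectrum integrates to the sample
    # variance (it can be well off when poles sit near the unit circle),
    # so the density is rescaled to satisfy Parseval exactly.
    grid = _line_adaptive_grid(1e-9, fs / 2.0 - 1e-9, lines)
    total = float(np.trapezoid(shape(grid), grid))
    scale = float(x.var() / total) if total > 0 else 0.0

    def psd(f):
        return scale * shape(f)

    return psd, lines


def _line_adaptive_grid(
    lo: float, hi: float, lines, n_coarse: int = 2001, n_local: int = 4001
) -> np.ndarray:
    """Frequency grid over [lo, hi] that resolves each spectral line.

    Around a line at f0 with half-width d the substitution
    f = f0 + d tan(v) makes a Lorentzian peak a smooth bounded function
    of v, so uniform sampling in v concentrates points where the density
    varies; these local grids are merged with a uniform coarse grid.
    """
    grids = [np.linspace(lo, hi, n_coarse)]
    v = np.linspace(-np.pi / 2 + 1e-4, np.pi / 2 - 1e-4, n_local)
    span = hi - lo
    for f0, d in lines:
        if lo - 0.1 * span <= f0 <= hi + 0.1 * span:
            local = f0 + d * np.tan(v)
            grids.append(local[(local > lo) & (local < hi)])
    return np.unique(np.concatenate(grids + [np.array([lo, hi])]))


def ar_psd(
    tachogram: np.ndarray,
    order: int = 16,
    fs: float = 4.0,
    n_freq: int = 1024,
) -> tuple[np.ndarray, np.ndarray]:
    """Autoregressive (Burg) one-sided PSD of a uniformly sampled series.

    Returns ``(freqs, psd)`` on a uniform grid over (0, fs/2].  Total
    integrated power approximates the series variance.  A (near-)constant
    input yields an all-zero density with a warning.
    """
    x = np.asarray(tachogram, dtype=float)
    if x.size <= 4 * order:
        raise ValueError(f"series length {x.size} too short for AR order {order}")
    freqs = np.linspace(0, fs / 2.0, n_freq + 1)[1:]
    if np.var(x) < 1e-12 * max(1.0, np.mean(x) ** 2):
        warnings.warn("constant input: returning zero spectral density")
        return freqs, np.zeros_like(freqs)
    psd, _poles = _ar_spectrum(x, order, fs)
    return freqs, psd(freqs)


def ar_band_power(
    tachogram: np.ndarray,
    band_hz: tuple[float, float] = HF_BAND_HZ,
    order: int = 16,
    fs: float = 4.0,
) -> tuple[float, float]:
    """Integrated AR spectral power in ``band_hz`` and the in-band peak frequency.

    Integration uses adaptive quadrature anchored at the AR pole
    frequencies so that arbitrarily sharp spectral lines retain their
    full power (the band power of a pure sinusoid of amplitude a is
    a^2 / 2 regardless of line width).
    """
    x = np.asarray(tachogram, dtype=float)
    if x.size <= 4 * order:
        raise ValueError(f"series length {x.size} too short for AR order {order}")
    if np.var(x) < 1e-12 * max(1.0, np.mean(x) ** 2):
        return 0.0, float(band_hz[0])
    psd, lines = _ar_spectrum(x, order, fs)
    lo, hi = band_hz
    grid = _line_adaptive_grid(lo, hi, lines)
    dens = psd(grid)
    power = float(np.trapezoid(dens, grid))
    return power, float(grid[np.argmax(dens)])


# ---------------------------------------------------------------------------
# per-segment metrics


def _resample_tachogram(
    times_s: np.ndarray, ibis_ms: np.ndarray, fs: float = 4.0
) -> np.ndarray:
    """Cubic-spline resample of the IBI series onto a uniform grid, detrended.

    Each interval is stamped at its ending beat time.
    """
    cs = interpolate.CubicSpline(times_s, ibis_ms)
    t0, t1 = times_s[0], times_s[-1]
    n = int(np.floor((t1 - t0) * fs)) + 1
    grid = t0 + np.arange(n) / fs
    return sps.detrend(cs(grid), type="linear")


def segment_metrics(
    beats: BeatRecord,
    segment: Segment,
    ar_order: int = 16,
    resample_hz: float = 4.0,
    hr_mode: str = "instantaneous",
    hf_peak_search_hz: tuple[float, float] = (0.10, 2.0),
) -> SegmentMetrics:
    """Time- and frequency-domain HRV metrics for one segment.

    ``rmssd`` is the square root of the mean squared successive IBI
    difference, ``sdnn`` the sample (n-1) standard deviation of the IBIs,
    and ``hf_power`` the integral of the AR spectral density of the
    resampled, linearly detrended tachogram over 0.15-0.40 Hz.

    ``hr_mode``: "instantaneous" (default) averages 60000/IBI per beat;
    "interval-mean" reports 60000 / mean(IBI).
    """
    if segment.n_intervals < 16:
        raise ValueError(
            f"segment has {segment.n_intervals} intervals; need at least 16"
        )
    ibis = beats.ibis_ms[segment.start : segment.end]
    end_times = beats.beat_times_s[segment.start + 1 : segment.end + 1]

    mean_ibi = float(np.mean(ibis))
    if hr_mode == "instantaneous":
        mean_hr = float(np.mean(60000.0 / ibis))
    elif hr_mode == "interval-mean":
        mean_hr = 60000.0 / mean_ibi
    else:
        raise ValueError(f"unknown hr_mode {hr_mode!r}")
    diffs = np.diff(ibis)
    rmssd = float(np.sqrt(np.mean(diffs**2))) if diffs.size else 0.0
    sdnn = float(np.std(ibis, ddof=1))

    tach = _resample_tachogram(end_times, ibis, fs=resample_hz)
    # short segments cannot support the full model order; degrade gracefully
    order = min(ar_order, max(4, tach.size // 5))
    if np.ptp(tach) < 1e-9:
        hf_power, hf_peak = 0.0, HF_BAND_HZ[0]
    else:
        hf_power, _ = ar_band_power(tach, HF_BAND_HZ, order=order, fs=resample_hz)
        lo = max(hf_peak_search_hz[0], 1e-3)
        hi = min(hf_peak_search_hz[1], resample_hz / 2.0)
        _, hf_peak = ar_band_power(tach, (lo, hi), order=order, fs=resample_hz)

    return SegmentMetrics(
        mean_ibi_ms=mean_ibi,
        mean_hr_bpm=mean_hr,
        rmssd_ms=rmssd,
        sdnn_ms=sdnn,
        hf_power_ms2=hf_power,
        hf_peak_hz=hf_peak,
        duration_s=segment.duration_s,
    )


# ---------------------------------------------------------------------------
# aggregation


def aggregate_profile(
    metrics: list[SegmentMetrics],
    duration_weighted: bool = False,
) -> AutonomicProfile:
    """Average segment metrics into a subject-level profile.

    Metrics are averaged unweighted across segments by default
    (``duration_weighted=True`` weights by segment duration).  HF power
    is averaged on the absolute (ms^2) scale and then natural-log
    transformed.  A subject with zero usable segments is returned with
    ``usable=False`` and NaN metrics rather than dropped.
    """
    if not metrics:
        qc = ProfileQC(0, float("nan"), 0.0, False)
        nan = float("nan")
        return AutonomicProfile(nan, nan, nan, nan, nan, nan, qc, usable=False)

    w = np.array([m.duration_s for m in metrics]) if duration_weighted else np.ones(len(metrics))
    w = w / w.sum()

    def avg(attr: str) -> float:
        return float(np.sum(w * np.array([getattr(m, attr) for m in metrics])))

    hf_mean = avg("hf_power_ms2")
    powers = np.array([m.hf_power_ms2 for m in metrics])
    peaks = np.array([m.hf_peak_hz for m in metrics])
    if powers.sum() > 0:
        peak_mean = float(np.sum(powers * peaks) / powers.sum())
    else:
        peak_mean = float(np.mean(peaks))
    durations = np.array([m.duration_s for m in metrics])
    qc = ProfileQC(
        n_segments=len(metrics),
        mean_segment_duration_s=float(np.mean(durations)),
        total_analyzed_s=float(np.sum(durations)),
        hf_peak_plausible=bool(HF_BAND_HZ[0] <= peak_mean <= HF_BAND_HZ[1]),
    )
    return AutonomicProfile(
        mean_ibi_ms=avg("mean_ibi_ms"),
        mean_hr_bpm=avg("mean_hr_bpm"),
        rmssd_ms=avg("rmssd_ms"),
        sdnn_ms=avg("sdnn_ms"),
        hf_power_ms2=hf_mean,
        ln_hf_power=float(np.log(hf_mean)) if hf_mean > 0 else float("-inf"),
        qc=qc,
    )


def process_beats(
    beats: BeatRecord,
    trim_s: float = 60.0,
    rel_thr: float = 0.30,
    abs_thr_ms: float = 250.0,
    min_s: float = 40.0,
    max_s: float = 60.0,
    buffer_beats: int = 2,
    **metric_kwargs,
) -> AutonomicProfile:
    """Full per-subject chain: trim, flag, segment, measure, aggregate."""
    trimmed = trim_stabilization(beats, trim_s=trim_s)
    flagged = flag_artifacts(trimmed, rel_thr=rel_thr, abs_thr_ms=abs_thr_ms)
    segments = segment_series(flagged, min_s=min_s, max_s=max_s, buffer_beats=buffer_beats)
    usable = [s for s in segments if s.n_intervals >= 16]
    return aggregate_profile([segment_metrics(flagged, s, **metric_kwargs) for s in usable])
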