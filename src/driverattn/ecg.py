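"""Wavelet-based R-peak detection and time-domain HRV (meanRR, RMSSD).

Detection uses a maximal-overlap (undecimated/stationary) discrete wavelet
transform of the raw ECG: detail levels whose pass-bands overlap the QRS
energy band (~5-25 Hz at the given sampling rate) are retained, the partial
reconstruction is squared, and local maxima above an adaptive rolling
threshold are taken as beats, then refined to the raw-amplitude maximum.
The detector runs once on the full record; per-trial windows are applied to
the detected peak *times*, which avoids per-trial decomposition edge
artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage, signal

from .streams import SignalStream, Window


class FeatureMissing(ValueError):
    """A per-trial feature could not be computed; the trial is flagged."""


@dataclass
class HRVMetrics:
    """Time-domain HRV over one window: meanRR and RMSSD, both in ms."""

    mean_rr: float
    rmssd: float
    n_intervals: int


def detect_r_peaks(
    ecg: SignalStream,
    wavelet: str = "sym4",
    band: tuple = (5.0, 25.0),
    threshold_frac: float = 0.2,
    refractory_s: float = 0.25,
    rolling_s: float = 2.0,
    refine_s: float = 0.05,
) -> np.ndarray:
    """Detect R-peak times (session seconds) in a continuous ECG record.

    The threshold is ``threshold_frac`` times a rolling maximum of the
    squared wavelet reconstruction (window ``rolling_s``, which always
    contains at least one QRS complex at physiological rates), making the
    detector invariant to overall amplitude scale. Candidate peaks are
    separated by at least ``refractory_s`` and refined to the raw sample of
    maximum amplitude within ``±refine_s``.
    """
    fs = ecg.sampling_rate
    x = np.asarray(ecg.samples, dtype=float)
    if ecg.duration < max(2.0, refractory_s) or np.ptp(x) == 0.0:
        warnings.warn("ECG record too short or constant; no peaks detected")
        return np.array([])

    det = _qrs_band_reconstruction(x, fs, wavelet, band)
    energy = det ** 2

    win = max(int(round(rolling_s * fs)), 3)
    rolling = ndimage.maximum_filter(energy, size=win, mode="nearest")
    thresh = threshold_frac * rolling
    # a floor keeps quiet stretches (threshold near zero) from firing on noise
    thresh = np.maximum(thresh, 1e-3 * np.max(rolling))

    distance = max(int(round(refractory_s * fs)), 1)
    peaks, _ = signal.find_peaks(energy, height=thresh, distance=distance)
    if peaks.size == 0:
        return np.array([])

    # refine each detection to the raw-amplitude maximum within ±refine_s,
    # then drop refinements that collide inside one refractory period
    half = int(round(refine_s * fs))
    refined = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, x.size)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(refined)
    kept: list = []
    for idx in refined:
        if kept and idx - kept[-1] < distance:
            if x[idx] > x[kept[-1]]:
                kept[-1] = idx
        else:
            kept.append(idx)
    return ecg.start_time + np.asarray(kept) / fs


def _qrs_band_reconstruction(
    x: np.ndarray, fs: float, wavelet: str, band: tuple
) -> np.ndarray:
    """Partial MODWT reconstruction from detail levels overlapping ``band``.

    Level j details occupy ~[fs/2^(j+1), fs/2^j]. The stationary (à trous)
    transform with orthonormal rescaling is the shift-invariant,
    non-decimated transform this analysis requires.
    """
    max_level = int(np.floor(np.log2(fs / band[0])))
    max_level = min(max_level, pywt.swt_max_level(_padded_len(x.size, 8)), 8)
    levels = []
    for j in range(1, max_level + 1):
        lo, hi = fs / 2 ** (j + 1), fs / 2 ** j
        if hi > band[0] and lo < band[1]:
            levels.append(j)
    if not levels:
        levels = [max(max_level, 1)]
    J = max(levels)
    n = x.size
    pad = _padded_len(n, 2 ** J) - n
    xp = np.pad(x, (0, pad), mode="edge")
    coeffs = pywt.swt(xp, wavelet, level=J, norm=True, trim_approx=True)
    # coeffs = [cA_J, cD_J, cD_{J-1}, ..., cD_1]
    kept = [np.zeros_like(coeffs[0])]
    for i in range(1, J + 1):
        level = J - i + 1
        kept.append(coeffs[i] if level in levels else np.zeros_like(coeffs[i]))
    rec = pywt.iswt(kept, wavelet, norm=True)
    return rec[:n]


def _padded_len(n: int, multiple: int) -> int:
    return n + (-n) % multiple


def rr_intervals(peak_times: np.ndarray, window: Window) -> np.ndarray:
    """Successive R-R intervals (ms) from the peaks inside ``window``."""
    peak_times = np.asarray(peak_times, dtype=float)
    inside = peak_times[(peak_times >= window.t_start) & (peak_times < window.t_end)]
    if inside.size < 3:
        raise FeatureMissing(
            f"only {inside.size} R peaks in [{window.t_start}, {window.t_end}); "
            "need >=3 for RMSSD"
        )
    return np.diff(inside) * 1000.0


def hrv_metrics(peak_times: np.ndarray, window: Window) -> HRVMetrics:
    """meanRR and RMSSD (ms) from the R peaks inside a pre-stimulus window.

    meanRR is the arithmetic mean of successive peak differences; RMSSD is
    the root of the mean squared successive differences of those intervals.
    """
    intervals = rr_intervals(peak_times, window)
    return hrv_from_intervals(intervals)


def hrv_from_intervals(intervals_ms: np.ndarray) -> HRVMetrics:
    intervals_ms = np.asarray(intervals_ms, dtype=float)
    if intervals_ms.size < 2:
        raise FeatureMissing("need >=2 RR intervals for RMSSD")
    diffs = np.diff(intervals_ms)
    return HRVMetrics(
        mean_rr=float(np.mean(intervals_ms)),
        rmssd=float(np.sqrt(np.mean(diffs ** 2))),
        n_intervals=int(intervals_ms.size),
    )
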