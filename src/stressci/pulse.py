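"""Heart-rate extraction from raw pulse waveforms.

Pipeline: zero-phase band-pass filtering (default 0.5-5 Hz, covering
30-200 bpm fundamentals plus low harmonics) -> prominence-thresholded
peak detection with a refractory period -> heart rate from the median
inter-beat interval. Zero-phase (forward-backward) filtering is used so
beat times are not shifted by the filter's group delay; the median IBI
makes the rate robust to isolated missed or spurious peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .cohort import PulseTrace
from .errors import InvalidParameterError

DEFAULT_BAND = (0.5, 5.0)
DEFAULT_REFRACTORY_S = 0.3       # caps detectable HR at 200 bpm
DEFAULT_MIN_PROMINENCE = 0.3     # fraction of the filtered signal range
MIN_BEATS = 3


@dataclass(frozen=True)
class HrResult:
    beat_times: np.ndarray
    hr: float | None
    n_beats: int
    quality_flag: str  # "ok" | "low_snr" | "too_short"


def bandpass_filter(trace: PulseTrace, low_hz: float = DEFAULT_BAND[0],
                    high_hz: float = DEFAULT_BAND[1], order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass; removes DC, preserves timing."""
    nyq = trace.sample_rate / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise InvalidParameterError(
            f"band [{low_hz}, {high_hz}] Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyq} Hz)")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=trace.sample_rate, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(trace.values, dtype=float))


def detect_peaks(filtered, sample_rate: float,
                 refractory_s: float = DEFAULT_REFRACTORY_S,
                 min_prominence: float = DEFAULT_MIN_PROMINENCE) -> np.ndarray:
    """Beat times (s) as prominence-thresholded local maxima.

    No two peaks closer than the refractory period; the prominence
    threshold is a fraction of the filtered signal's range. For plateaus
    of equal-height samples the earliest index wins.
    """
    if refractory_s <= 0:
        raise InvalidParameterError("refractory_s must be positive")
    x = np.asarray(filtered, dtype=float)
    min_len = max(int(round(refractory_s * sample_rate)), 3)
    if x.size < min_len:
        return np.empty(0)
    rng_x = float(np.ptp(x))
    if rng_x == 0.0:
        return np.empty(0)
    idx, props = signal.find_peaks(
        x,
        distance=max(int(round(refractory_s * sample_rate)), 1),
        prominence=min_prominence * rng_x,
        plateau_size=(None, None),
    )
    left_edges = props.get("left_edges")
    if left_edges is not None and len(left_edges) == len(idx):
        idx = left_edges  # earliest sample of an equal-height plateau
    return idx / sample_rate


def hr_from_peaks(beat_times) -> HrResult:
    """Heart rate from the median inter-beat interval of detected beats."""
    beat_times = np.asarray(beat_times, dtype=float)
    n = int(beat_times.size)
    if n < MIN_BEATS:
        return HrResult(beat_times=beat_times, hr=None, n_beats=n,
                        quality_flag="too_short")
    ibis = np.diff(beat_times)
    if np.any(ibis <= 0):
        raise InvalidParameterError("beat_times must be strictly increasing")
    median_ibi = float(np.median(ibis))
    hr = 60.0 / median_ibi
    # wildly dispersed intervals indicate a noise-dominated detection
    flag = "ok"
    if np.median(np.abs(ibis - median_ibi)) > 0.25 * median_ibi:
        flag = "low_snr"
    return HrResult(beat_times=beat_times, hr=hr, n_beats=n, quality_flag=flag)


def estimate_hr(trace: PulseTrace, low_hz: float = DEFAULT_BAND[0],
                high_hz: float = DEFAULT_BAND[1],
                refractory_s: float = DEFAULT_REFRACTORY_S,
                min_prominence: float = DEFAULT_MIN_PROMINENCE) -> HrResult:
    """Full readout chain: filter, detect peaks, convert to bpm."""
    filtered = bandpass_filter(trace, low_hz, high_hz)
    beats = detect_peaks(filtered, trace.sample_rate, refractory_s, min_prominence)
    return hr_from_peaks(beats)


def brute_force_peak_count(x, sample_rate: float,
                           refractory_s: float = DEFAULT_REFRACTORY_S,
                           min_prominence: float = DEFAULT_MIN_PROMINENCE) -> int:
    """Exhaustive local-maximum scan used as an independent check.

    Implements the detection rule from first principles, one sample at a
    time: find every strict local maximum, compute its topographic
    prominence by walking outward to the nearest higher sample on each
    side, drop maxima below the prominence threshold, then resolve the
    refractory spacing by keeping peaks highest-first.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return 0
    candidates = [i for i in range(1, x.size - 1)
                  if x[i] > x[i - 1] and x[i] >= x[i + 1]]
    thresh = min_prominence * float(np.ptp(x))
    kept = []
    for i in candidates:
        left_min = x[i]
        j = i - 1
        while j >= 0 and x[j] <= x[i]:
            left_min = min(left_min, x[j])
            j -= 1
        right_min = x[i]
        j = i + 1
        while j < x.size and x[j] <= x[i]:
            right_min = min(right_min, x[j])
            j += 1
        if x[i] - max(left_min, right_min) >= thresh:
            kept.append(i)
    # refractory: highest peak wins, neighbours within the window drop out
    refractory_n = refractory_s * sample_rate
    kept.sort(key=lambda i: -x[i])
    accepted = []
    for i in kept:
        if all(abs(i - a) >= refractory_n for a in accepted):
            accepted.append(i)
    return len(accepted)
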