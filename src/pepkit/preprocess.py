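"""EEG filtering, perturbation-onset detection and cross-rate alignment.

Continuous EEG is filtered offline with a 2nd-order Butterworth bandpass
(2.5-30 Hz) and a 60 Hz IIR notch, both applied forward-backward (zero phase)
so epoch latencies are not skewed by group delay. Perturbation onsets are read
from the platform accelerometer as the first sustained excursion beyond a
multiple of the pre-event noise SD, then mapped onto the EEG clock by
nearest-sample rounding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .simulate import MASTOID_LEFT, MASTOID_RIGHT

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Offline EEG filter: Butterworth bandpass + IIR notch, zero-phase."""

    bandpass_order: int = 2
    bandpass_low: float = 2.5
    bandpass_high: float = 30.0
    notch_freq: float = 60.0
    notch_quality: float = 30.0

    def __post_init__(self) -> None:
        if self.bandpass_order < 1:
            raise ValueError("bandpass_order must be >= 1")
        if not (0 < self.bandpass_low < self.bandpass_high):
            raise ValueError("need 0 < bandpass_low < bandpass_high")
        if self.notch_freq <= 0 or self.notch_quality <= 0:
            raise ValueError("notch parameters must be positive")


@dataclass(frozen=True)
class OnsetDetectionSpec:
    """Threshold rule operationalizing 'first noticeable accelerometer burst'.

    Baseline noise statistics come from ``baseline_window_s`` before each
    event marker; onset is the first time within ``search_window_s`` after the
    marker where |a - baseline mean| exceeds ``threshold_k`` baseline SDs for
    at least ``min_consecutive_samples`` consecutive samples.
    """

    baseline_window_s: float = 1.0
    threshold_k: float = 5.0
    min_consecutive_samples: int = 3
    search_window_s: float = 1.0

    def __post_init__(self) -> None:
        if min(
            self.baseline_window_s, self.threshold_k,
            self.min_consecutive_samples, self.search_window_s,
        ) <= 0:
            raise ValueError("all onset-detection parameters must be positive")


def design_filters(spec: FilterSpec, sampling_rate: float) -> np.ndarray:
    """Cascade the bandpass and notch into one second-order-section array."""
    nyq = sampling_rate / 2.0
    if spec.bandpass_high >= nyq:
        raise ValueError(
            f"bandpass_high={spec.bandpass_high} Hz at/above Nyquist ({nyq} Hz)"
        )
    if spec.notch_freq >= nyq:
        raise ValueError(
            f"notch_freq={spec.notch_freq} Hz at/above Nyquist ({nyq} Hz)"
        )
    sos_bp = signal.butter(
        spec.bandpass_order,
        [spec.bandpass_low, spec.bandpass_high],
        btype="bandpass",
        fs=sampling_rate,
        output="sos",
    )
    b_n, a_n = signal.iirnotch(spec.notch_freq, spec.notch_quality, fs=sampling_rate)
    return np.vstack([sos_bp, signal.tf2sos(b_n, a_n)])


def apply_bandpass_notch(
    eeg: np.ndarray, spec: FilterSpec, sampling_rate: float
) -> np.ndarray:
    """Zero-phase bandpass + notch along the last axis; shape preserved.

    Forward-backward application doubles the effective order (a 2nd-order
    design acts as 4th order in magnitude) and cancels phase distortion.
    """
    if sampling_rate <= 2 * spec.bandpass_high:
        raise ValueError("sampling rate must exceed twice the bandpass high edge")
    sos = design_filters(spec, sampling_rate)
    return signal.sosfiltfilt(sos, np.asarray(eeg, dtype=float), axis=-1)


@dataclass(frozen=True)
class OnsetEvent:
    """Detection result for one event marker."""

    trial_index: int
    onset_time_s: float | None
    detected: bool


def detect_onsets(
    acceleration: np.ndarray,
    markers: list[tuple[int, float]],
    spec: OnsetDetectionSpec,
    sampling_rate: float,
) -> list[OnsetEvent]:
    """Detect per-event perturbation onsets from the platform accelerometer.

    ``markers`` are (trial_index, marker_time_s) pairs; the marker time is the
    event's position on the shared wall clock (a TTL pulse in the real
    acquisition). Events whose search window contains no sustained threshold
    crossing are returned flagged ``detected=False``, never dropped.

    A degenerate baseline (zero SD, e.g. an idealized noiseless trace) falls
    back to an absolute threshold of 5% of the window's peak |acceleration|.
    """
    a = np.asarray(acceleration, dtype=float)
    n = len(a)
    out: list[OnsetEvent] = []
    for trial_index, t_marker in markers:
        i_marker = int(round(t_marker * sampling_rate))
        i_base0 = i_marker - int(round(spec.baseline_window_s * sampling_rate))
        i_end = i_marker + int(round(spec.search_window_s * sampling_rate))
        if i_base0 < 0 or i_end > n:
            raise ValueError(
                f"trial {trial_index}: baseline/search window outside recording"
            )
        baseline = a[i_base0:i_marker]
        mu, sd = float(baseline.mean()), float(baseline.std())
        window = a[i_marker:i_end]
        if sd <= 1e-12:
            peak = float(np.abs(window).max())
            threshold = 0.05 * peak
            logger.info(
                "trial %d: degenerate accelerometer baseline (zero SD); "
                "using absolute threshold %.4g", trial_index, threshold,
            )
            if peak == 0.0:
                out.append(OnsetEvent(trial_index, None, False))
                continue
            above = np.abs(window - mu) > threshold
        else:
            above = np.abs(window - mu) > spec.threshold_k * sd

        idx = _first_run(above, spec.min_consecutive_samples)
        if idx is None:
            out.append(OnsetEvent(trial_index, None, False))
        else:
            out.append(
                OnsetEvent(trial_index, (i_marker + idx) / sampling_rate, True)
            )
    return out


def _first_run(mask: np.ndarray, run_length: int) -> int | None:
    """Index of the first run of >= run_length consecutive True values."""
    if run_length == 1:
        hits = np.flatnonzero(mask)
        return int(hits[0]) if hits.size else None
    conv = np.convolve(mask.astype(int), np.ones(run_length, dtype=int), "valid")
    hits = np.flatnonzero(conv == run_length)
    return int(hits[0]) if hits.size else None


def onset_to_eeg_index(onset_time_s: float, eeg_sampling_rate: float,
                       n_samples: int | None = None) -> int:
    """Map an onset time to the nearest sample index on the EEG clock."""
    if onset_time_s < 0:
        raise ValueError("onset time must be nonnegative")
    idx = int(round(onset_time_s * eeg_sampling_rate))
    if n_samples is not None and idx >= n_samples:
        raise ValueError(
            f"onset at {onset_time_s} s lies outside the {n_samples}-sample recording"
        )
    return idx


def average_mastoid_channels(
    eeg: np.ndarray, channel_map: dict[str, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-ear mastoid means and their combined average.

    Returns (left, right, combined) where left/right are the samplewise means
    of L5-L7 / R5-R7 and combined is the mean of the two ear means (equal to
    the 6-channel grand mean for the standard 3+3 montage, but robust to
    asymmetric montages).
    """
    missing = [
        ch for ch in MASTOID_LEFT + MASTOID_RIGHT if ch not in channel_map
    ]
    if missing:
        raise ValueError(f"missing mastoid channels: {missing}")
    left = np.mean([eeg[channel_map[ch]] for ch in MASTOID_LEFT], axis=0)
    right = np.mean([eeg[channel_map[ch]] for ch in MASTOID_RIGHT], axis=0)
    return left, right, (left + right) / 2.0
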