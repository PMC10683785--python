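"""Per-event EEG epoching: extraction, baseline correction, normalization, QC.

For each perturbation event a 300 ms post-onset EEG window is extracted
together with baseline statistics from the 300-100 ms pre-onset window. Epochs
then pass through a strict state machine::

    raw -> corrected -> normalized

Correction removes the epoch's least-squares linear trend (slope only — the
epoch mean is preserved so that referencing to the baseline mean removes DC
shifts exactly) and expresses samples in baseline-SD units:
``(detrended - baseline_mean) / baseline_sd``. Normalization then scales all
of a subject's epochs per channel by the maximum absolute value of that
subject's first event epoch, making magnitudes comparable across subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import average_mastoid_channels
from .protocol import ProtocolDefinition
from .simulate import ContinuousRecording

logger = logging.getLogger(__name__)

EPOCH_DURATION_S = 0.300
BASELINE_START_S = 0.300   # baseline window starts 300 ms before onset ...
BASELINE_END_S = 0.100     # ... and ends 100 ms before onset (half-open)
DEGENERATE_SD_TOL = 1e-12


@dataclass(frozen=True)
class Epoch:
    """One trial x channel EEG window with its baseline statistics."""

    subject_id: str
    trial_index: int
    channel_name: str
    analysis_label: str
    samples: np.ndarray
    baseline_mean: float
    baseline_sd: float
    state: str = "raw"           # raw | corrected | normalized
    valid: bool = True
    invalid_reason: str | None = None

    def invalidated(self, reason: str) -> "Epoch":
        return replace(self, valid=False, invalid_reason=reason)


@dataclass
class EpochSet:
    """Epochs grouped by subject x channel, in trial order, plus the
    per-subject x channel normalization reference scale."""

    epochs: list[Epoch] = field(default_factory=list)
    reference_scale: dict[tuple[str, str], float] = field(default_factory=dict)

    def add(self, epoch: Epoch) -> None:
        self.epochs.append(epoch)

    def group(self, subject_id: str, channel: str) -> list[Epoch]:
        sel = [
            e for e in self.epochs
            if e.subject_id == subject_id and e.channel_name == channel
        ]
        return sorted(sel, key=lambda e: e.trial_index)

    @property
    def subjects(self) -> list[str]:
        return sorted({e.subject_id for e in self.epochs})

    @property
    def channels(self) -> list[str]:
        return sorted({e.channel_name for e in self.epochs})


def _epoch_geometry(sampling_rate: float) -> tuple[int, int, int]:
    n_epoch = int(round(EPOCH_DURATION_S * sampling_rate))
    n_pre = int(round(BASELINE_START_S * sampling_rate))
    n_pre_end = int(round(BASELINE_END_S * sampling_rate))
    return n_epoch, n_pre, n_pre_end


def extract_epoch_from_series(
    series: np.ndarray,
    onset_index: int,
    sampling_rate: float,
    subject_id: str = "",
    trial_index: int = 0,
    channel_name: str = "",
    analysis_label: str = "predictable",
) -> Epoch:
    """Extract a raw epoch ([onset, onset+300 ms)) from one continuous series.

    Baseline statistics (mean, SD) come from [onset-300 ms, onset-100 ms).
    Windows falling outside the recording yield an invalid epoch (logged),
    never an exception — the event is accounted for in QC.
    """
    series = np.asarray(series, dtype=float)
    n_epoch, n_pre, n_pre_end = _epoch_geometry(sampling_rate)
    lo, hi = onset_index - n_pre, onset_index + n_epoch
    if lo < 0 or hi > len(series):
        logger.warning(
            "subject %s trial %d channel %s: epoch window [%d, %d) outside "
            "recording of %d samples", subject_id, trial_index, channel_name,
            lo, hi, len(series),
        )
        return Epoch(
            subject_id, trial_index, channel_name, analysis_label,
            samples=np.zeros(n_epoch), baseline_mean=float("nan"),
            baseline_sd=float("nan"), valid=False,
            invalid_reason="window out of bounds",
        )
    baseline = series[lo : onset_index - n_pre_end]
    return Epoch(
        subject_id, trial_index, channel_name, analysis_label,
        samples=series[onset_index:hi].copy(),
        baseline_mean=float(baseline.mean()),
        baseline_sd=float(baseline.std()),
    )


def extract_epoch(
    recording: ContinuousRecording,
    onset_index: int,
    channel: str,
    trial_index: int = 0,
    analysis_label: str = "predictable",
    eeg: np.ndarray | None = None,
) -> Epoch:
    """Extract a raw epoch for one channel of a recording.

    ``channel`` may name a recorded channel or the derived ``"mastoid"``
    series (mean of per-ear mastoid means). ``eeg`` overrides the recording's
    array (e.g. the filtered version) without copying the recording.
    """
    data = recording.eeg if eeg is None else eeg
    if channel == "mastoid":
        cmap = {ch: i for i, ch in enumerate(recording.channels)}
        _, _, series = average_mastoid_channels(data, cmap)
    else:
        series = data[recording.channel_index(channel)]
    return extract_epoch_from_series(
        series, onset_index, recording.eeg_sampling_rate,
        subject_id=recording.subject.subject_id, trial_index=trial_index,
        channel_name=channel, analysis_label=analysis_label,
    )


def detrend_and_baseline_correct(epoch: Epoch, divide_by_sd: bool = True) -> Epoch:
    """raw -> corrected: remove the linear trend, reference to the baseline.

    The least-squares slope is removed from the epoch samples with the epoch
    mean preserved, then samples become ``(x - baseline_mean) / baseline_sd``
    (baseline-z units). With ``divide_by_sd=False`` only the baseline mean is
    subtracted (plain baseline correction). A baseline SD at/below 1e-12
    invalidates the epoch (degenerate baseline).
    """
    if epoch.state != "raw":
        raise ValueError(f"cannot correct an epoch in state {epoch.state!r}")
    if not epoch.valid:
        return epoch
    if not np.isfinite(epoch.baseline_sd) or (
        divide_by_sd and epoch.baseline_sd <= DEGENERATE_SD_TOL
    ):
        logger.warning(
            "subject %s trial %d channel %s: degenerate baseline SD %g",
            epoch.subject_id, epoch.trial_index, epoch.channel_name,
            epoch.baseline_sd,
        )
        return epoch.invalidated("degenerate baseline")
    x = epoch.samples
    t = np.arange(len(x), dtype=float)
    slope, intercept = np.polyfit(t, x, 1)
    trend = slope * t + intercept
    detrended = x - (trend - trend.mean())   # slope removed, epoch mean kept
    corrected = detrended - epoch.baseline_mean
    if divide_by_sd:
        corrected = corrected / epoch.baseline_sd
    return replace(epoch, samples=corrected, state="corrected")


def normalize_subject_epochs(epoch_set: EpochSet) -> EpochSet:
    """corrected -> normalized: scale by each subject's first event epoch.

    Per subject x channel the reference scale is the maximum absolute sample
    of the first (lowest trial index) valid corrected epoch; every epoch in
    the group is divided by it, so the first epoch's maximum magnitude becomes
    exactly 1. If the first analyzable event is missing, the earliest valid
    epoch substitutes (logged).
    """
    out = EpochSet()
    for epoch in epoch_set.epochs:
        if epoch.valid and epoch.state != "corrected":
            raise ValueError(
                f"cannot normalize an epoch in state {epoch.state!r}"
            )
    for sid in epoch_set.subjects:
        for ch in epoch_set.channels:
            group = epoch_set.group(sid, ch)
            valid = [e for e in group if e.valid]
            if not valid:
                for e in group:
                    out.add(e)
                continue
            ref_epoch = valid[0]
            first_trial = min(e.trial_index for e in group)
            if ref_epoch.trial_index != first_trial:
                logger.info(
                    "subject %s channel %s: first event epoch (trial %d) "
                    "unavailable; normalizing to trial %d instead",
                    sid, ch, first_trial, ref_epoch.trial_index,
                )
            scale = float(np.abs(ref_epoch.samples).max())
            if scale <= 0:
                raise ValueError(
                    f"subject {sid} channel {ch}: degenerate normalization "
                    "reference (first epoch identically zero)"
                )
            out.reference_scale[(sid, ch)] = scale
            for e in group:
                if e.valid:
                    out.add(
                        replace(e, samples=e.samples / scale, state="normalized")
                    )
                else:
                    out.add(e)
    return out


@dataclass(frozen=True)
class QCReport:
    """Event-level accounting: analyzed = planned - missing."""

    planned_events: int
    missing_events: int
    analyzed_events: int
    per_subject: dict[str, dict[str, int]]

    def to_dict(self) -> dict:
        return {
            "planned_events": self.planned_events,
            "missing_events": self.missing_events,
            "analyzed_events": self.analyzed_events,
            "per_subject": self.per_subject,
        }


def qc_accounting(
    epoch_set: EpochSet, protocol: ProtocolDefinition,
    subjects: list[str] | None = None,
) -> QCReport:
    """Tally planned / missing / analyzed events over a cohort epoch set.

    Missingness is event-level (a dropped event is absent at every channel),
    so the count is taken per subject over analyzable trials using any one
    channel present for that subject.
    """
    analyzable = {t.index for t in protocol.analyzable_trials}
    if subjects is None:
        subjects = epoch_set.subjects
    per_subject: dict[str, dict[str, int]] = {}
    planned = missing = 0
    for sid in subjects:
        channels = sorted(
            {e.channel_name for e in epoch_set.epochs if e.subject_id == sid}
        )
        if channels:
            group = epoch_set.group(sid, channels[0])
            valid_trials = {e.trial_index for e in group if e.valid}
        else:
            valid_trials = set()
        n_missing = len(analyzable - valid_trials)
        per_subject[sid] = {
            "planned": len(analyzable),
            "missing": n_missing,
            "analyzed": len(analyzable) - n_missing,
        }
        planned += len(analyzable)
        missing += n_missing
    return QCReport(
        planned_events=planned,
        missing_events=missing,
        analyzed_events=planned - missing,
        per_subject=per_subject,
    )
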