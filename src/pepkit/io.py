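"""On-disk dataset layout and real-session ingest.

Synthetic cohorts are written one directory per subject: EEG and platform
acceleration as ``.npy`` arrays plus a JSON sidecar holding the subject
profile, event markers, ground-truth onsets and the generating config; a
cohort ``manifest.json`` sits at the root.

Real sessions in EDF or BrainVision format are mapped into the same
:class:`~pepkit.simulate.ContinuousRecording` model through MNE; ground-truth
fields stay unset and markers come from the file's annotations.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .simulate import ContinuousRecording, SubjectProfile


def save_recording(recording: ContinuousRecording, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.save(out_dir / "eeg.npy", recording.eeg)
    np.save(out_dir / "acceleration.npy", recording.acceleration)
    sidecar = {
        "subject": {
            "subject_id": recording.subject.subject_id,
            "age_group": recording.subject.age_group,
            "sex": recording.subject.sex,
            "subject_gain": recording.subject.subject_gain,
        },
        "channels": list(recording.channels),
        "eeg_sampling_rate": recording.eeg_sampling_rate,
        "accel_sampling_rate": recording.accel_sampling_rate,
        "event_markers": [list(m) for m in recording.event_markers],
        "true_onsets": recording.true_onsets,
        "incomplete_trials": sorted(recording.incomplete_trials),
    }
    (out_dir / "session.json").write_text(json.dumps(sidecar, indent=1))


def load_recording(subject_dir: Path) -> ContinuousRecording:
    subject_dir = Path(subject_dir)
    meta = json.loads((subject_dir / "session.json").read_text())
    return ContinuousRecording(
        subject=SubjectProfile(**meta["subject"]),
        eeg=np.load(subject_dir / "eeg.npy"),
        channels=tuple(meta["channels"]),
        eeg_sampling_rate=meta["eeg_sampling_rate"],
        acceleration=np.load(subject_dir / "acceleration.npy"),
        accel_sampling_rate=meta["accel_sampling_rate"],
        event_markers=[tuple(m) for m in meta["event_markers"]],
        true_onsets=meta["true_onsets"],
        incomplete_trials=set(meta["incomplete_trials"]),
    )


def save_cohort(recordings, manifest: dict, out_dir: Path) -> None:
    """Write a cohort dataset: per-subject directories + root manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        save_recording(rec, out_dir / rec.subject.subject_id)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_cohort(dataset_dir: Path):
    """Load a saved cohort; yields recordings lazily, returns (iter, manifest)."""
    dataset_dir = Path(dataset_dir)
    manifest = json.loads((dataset_dir / "manifest.json").read_text())
    subject_ids = [s["subject_id"] for s in manifest["subjects"]]

    def _iter():
        for sid in subject_ids:
            yield load_recording(dataset_dir / sid)

    return _iter(), manifest


# ---------------------------------------------------------------------------
# Real-data ingest
# ---------------------------------------------------------------------------

#: channels the analysis needs to find in a real montage
REQUIRED_EEG_CHANNELS = ("Fz", "Cz", "L5", "L6", "L7", "R5", "R6", "R7")


class IngestError(RuntimeError):
    pass


def ingest_real_session(
    path: str | Path,
    format: str,
    subject: SubjectProfile | None = None,
    acceleration: np.ndarray | None = None,
    accel_sampling_rate: float = 150.0,
) -> ContinuousRecording:
    """Read an EDF or BrainVision EEG session into a ContinuousRecording.

    Channel names must include Fz, Cz and the six mastoid cEEGrid channels
    (L5-L7, R5-R7); markers are taken from the file's annotations (the .vmrk
    marker file for BrainVision). Ground-truth fields stay unset. Platform
    acceleration, recorded by a separate device in the real acquisition, may
    be supplied as an array on its own clock.
    """
    import mne

    path = Path(path)
    if format == "edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif format == "brainvision":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unknown format {format!r} (expected edf|brainvision)")

    available = set(raw.ch_names)
    missing = [ch for ch in REQUIRED_EEG_CHANNELS if ch not in available]
    if missing:
        raise IngestError(
            f"session is missing required channel(s): {', '.join(missing)}"
        )
    unmapped = sorted(available - set(REQUIRED_EEG_CHANNELS))
    if unmapped:
        import logging
        logging.getLogger(__name__).info("unmapped channels ignored: %s", unmapped)

    picked = raw.copy().pick(list(REQUIRED_EEG_CHANNELS))
    data = picked.get_data() * 1e6  # MNE stores volts; the model uses uV
    fs = float(picked.info["sfreq"])

    events = [
        onset
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
        if not str(desc).startswith("New Segment")
    ]
    if not events:
        raise IngestError(
            "no event markers found: the session has no annotations / .vmrk "
            "events; supply a marker stream to analyze perturbation events"
        )
    markers = [(k + 1, int(round(onset * fs))) for k, onset in enumerate(events)]

    if subject is None:
        subject = SubjectProfile(
            subject_id=path.stem, age_group="young", sex="female"
        )
    if acceleration is None:
        acceleration = np.zeros(
            int(round(data.shape[1] / fs * accel_sampling_rate))
        )
    return ContinuousRecording(
        subject=subject,
        eeg=data,
        channels=tuple(REQUIRED_EEG_CHANNELS),
        eeg_sampling_rate=fs,
        acceleration=np.asarray(acceleration, dtype=float),
        accel_sampling_rate=accel_sampling_rate,
        event_markers=markers,
        true_onsets=None,
        incomplete_trials=set(),
    )
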