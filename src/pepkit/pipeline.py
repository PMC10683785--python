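"""End-to-end orchestration: simulate -> preprocess -> epochs -> analyze.

One :class:`RunConfig` (serializable to YAML) drives the whole pipeline and,
with its seed, reproduces a run bit-for-bit. Recordings are processed one
subject at a time so a 40-subject cohort never has to sit in memory at once.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .epochs import (
    EpochSet,
    detrend_and_baseline_correct,
    extract_epoch_from_series,
    normalize_subject_epochs,
    qc_accounting,
    QCReport,
)
from .preprocess import (
    FilterSpec,
    OnsetDetectionSpec,
    apply_bandpass_notch,
    average_mastoid_channels,
    detect_onsets,
    onset_to_eeg_index,
)
from .protocol import ProtocolDefinition, build_default_protocol
from .simulate import (
    ContinuousRecording,
    GeneratorConfig,
    SubjectProfile,
    iter_cohort,
    build_cohort_profiles,
    assign_dropout,
    cohort_manifest,
)
from .stats import (
    ANALYSIS_CHANNELS,
    cohens_d,
    split_plot_anova,
    summarize_rms,
    tukey_age_sex,
)

logger = logging.getLogger(__name__)

try:
    PACKAGE_VERSION = _pkg_version("pepkit")
except Exception:  # pragma: no cover - not installed
    PACKAGE_VERSION = "unknown"


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible run needs; fully serializable."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    onset: OnsetDetectionSpec = field(default_factory=OnsetDetectionSpec)
    channels: tuple[str, ...] = ANALYSIS_CHANNELS
    divide_by_sd: bool = True
    make_figures: bool = True

    def to_dict(self) -> dict:
        d = {
            "generator": self.generator.to_dict(),
            "filter": asdict(self.filter),
            "onset": asdict(self.onset),
            "channels": list(self.channels),
            "divide_by_sd": self.divide_by_sd,
            "make_figures": self.make_figures,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "generator" in d:
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        if "filter" in d:
            d["filter"] = FilterSpec(**d["filter"])
        if "onset" in d:
            d["onset"] = OnsetDetectionSpec(**d["onset"])
        if "channels" in d:
            d["channels"] = tuple(d["channels"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def with_seed(self, seed: int) -> "RunConfig":
        from dataclasses import replace
        return replace(self, generator=GeneratorConfig.from_dict(
            {**self.generator.to_dict(), "seed": seed}
        ))


# ---------------------------------------------------------------------------
# Per-subject processing
# ---------------------------------------------------------------------------

def preprocess_and_epoch(
    recording: ContinuousRecording,
    protocol: ProtocolDefinition,
    filter_spec: FilterSpec,
    onset_spec: OnsetDetectionSpec,
    channels: Iterable[str] = ANALYSIS_CHANNELS,
    divide_by_sd: bool = True,
) -> EpochSet:
    """Filter one recording, detect onsets, extract and correct its epochs.

    Only analyzable trials (label != excluded) produce epochs; incomplete
    trials and undetected onsets produce none (they surface as missing events
    in QC). Returned epochs are in the ``corrected`` state.
    """
    # Build the analysis series first (mastoid averaging commutes with the
    # linear zero-phase filter), then filter them in one batched call.
    channels = tuple(channels)
    series_stack = []
    for ch in channels:
        if ch == "mastoid":
            cmap = {c: i for i, c in enumerate(recording.channels)}
            _, _, combined = average_mastoid_channels(recording.eeg, cmap)
            series_stack.append(combined)
        else:
            series_stack.append(recording.eeg[recording.channel_index(ch)])
    filtered = apply_bandpass_notch(
        np.vstack(series_stack), filter_spec, recording.eeg_sampling_rate
    )
    filtered_by_channel = dict(zip(channels, filtered))
    marker_times = [
        (trial, idx / recording.eeg_sampling_rate)
        for trial, idx in recording.event_markers
    ]
    onsets = {
        ev.trial_index: ev
        for ev in detect_onsets(
            recording.acceleration, marker_times, onset_spec,
            recording.accel_sampling_rate,
        )
    }
    epoch_set = EpochSet()
    sid = recording.subject.subject_id
    for trial in protocol.analyzable_trials:
        if trial.index in recording.incomplete_trials:
            logger.info("subject %s trial %d: incomplete event, skipped",
                        sid, trial.index)
            continue
        ev = onsets.get(trial.index)
        if ev is None or not ev.detected:
            logger.warning("subject %s trial %d: no onset detected",
                           sid, trial.index)
            continue
        onset_idx = onset_to_eeg_index(
            ev.onset_time_s, recording.eeg_sampling_rate,
            n_samples=recording.eeg.shape[1],
        )
        for ch in channels:
            raw = extract_epoch_from_series(
                filtered_by_channel[ch], onset_idx,
                recording.eeg_sampling_rate,
                subject_id=sid, trial_index=trial.index,
                channel_name=ch, analysis_label=trial.analysis_label,
            )
            epoch_set.add(
                detrend_and_baseline_correct(raw, divide_by_sd=divide_by_sd)
                if raw.valid else raw
            )
    return epoch_set


# ---------------------------------------------------------------------------
# Cohort-level analysis
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    rms_table: pd.DataFrame
    anova: pd.DataFrame
    posthoc: pd.DataFrame
    effect_sizes: pd.DataFrame
    qc: QCReport
    config: RunConfig
    manifest: dict | None = None

    def summary(self) -> dict:
        """Machine-readable run summary."""
        contrasts = {}
        for ch in self.config.channels:
            sub = self.rms_table[self.rms_table["channel"] == ch]
            by_cond = sub.groupby("condition")["mean_rms"].mean()
            contrasts[ch] = {
                "unpredictable_mean_rms": float(by_cond.get("unpredictable", np.nan)),
                "predictable_mean_rms": float(by_cond.get("predictable", np.nan)),
            }
        return {
            "package_version": PACKAGE_VERSION,
            "config_hash": self.config.config_hash(),
            "seed": self.config.generator.seed,
            "qc": self.qc.to_dict(),
            "condition_contrast": contrasts,
            "anova": self.anova.to_dict(orient="records"),
            "posthoc": self.posthoc.to_dict(orient="records"),
            "effect_sizes": self.effect_sizes.to_dict(orient="records"),
        }


def analyze_recordings(
    recordings: Iterable[ContinuousRecording],
    protocol: ProtocolDefinition,
    config: RunConfig,
) -> tuple[pd.DataFrame, QCReport]:
    """Run preprocessing, epoching, normalization and RMS summarization over a
    stream of recordings; returns the tidy RMS table and the QC report."""
    rows = []
    qc_per_subject: dict[str, dict[str, int]] = {}
    planned = missing = 0
    for rec in recordings:
        es = preprocess_and_epoch(
            rec, protocol, config.filter, config.onset,
            channels=config.channels, divide_by_sd=config.divide_by_sd,
        )
        es_norm = normalize_subject_epochs(es)
        qc = qc_accounting(
            es_norm, protocol, subjects=[rec.subject.subject_id]
        )
        qc_per_subject.update(qc.per_subject)
        planned += qc.planned_events
        missing += qc.missing_events
        rows.append(
            summarize_rms(es_norm, {rec.subject.subject_id: rec.subject})
        )
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    report = QCReport(
        planned_events=planned, missing_events=missing,
        analyzed_events=planned - missing, per_subject=qc_per_subject,
    )
    return table, report


def run_statistics(
    rms_table: pd.DataFrame, channels: Iterable[str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-channel split-plot ANOVA, Tukey age x sex follow-up, Cohen's d."""
    anova_frames, posthoc_rows, effect_rows = [], [], []
    for ch in channels:
        anova_frames.append(split_plot_anova(rms_table, ch))
        for res in tukey_age_sex(rms_table, ch):
            posthoc_rows.append(
                {
                    "channel": ch, "pair": " vs ".join(res.pair),
                    "mean_difference": res.mean_difference, "q": res.q,
                    "p_adjusted": res.p_adjusted,
                    "significant": res.significant,
                }
            )
        for effect in ("condition", "age", "sex"):
            es = cohens_d(rms_table, effect, ch)
            effect_rows.append(
                {
                    "channel": ch, "effect": effect, "cohens_d": es.cohens_d,
                    "definition": es.definition,
                }
            )
    return (
        pd.concat(anova_frames, ignore_index=True),
        pd.DataFrame(posthoc_rows),
        pd.DataFrame(effect_rows),
    )


def run_pipeline(
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
    recordings: Iterable[ContinuousRecording] | None = None,
    protocol: ProtocolDefinition | None = None,
) -> PipelineResult:
    """Execute the full pipeline and optionally write a run directory.

    With no ``recordings`` a synthetic cohort is generated from
    ``config.generator`` (streamed subject-by-subject). The run directory
    contains the config, QC JSON, RMS/ANOVA/post-hoc/effect-size CSVs, the
    summary JSON and boxplot figures.
    """
    config = config or RunConfig()
    protocol = protocol or build_default_protocol()
    manifest = None
    if recordings is None:
        profiles = build_cohort_profiles(config.generator)
        dropout = assign_dropout(config.generator, protocol, profiles)
        manifest = cohort_manifest(config.generator, protocol, profiles, dropout)
        recordings = iter_cohort(config.generator, protocol)

    rms_table, qc = analyze_recordings(recordings, protocol, config)
    anova, posthoc, effects = run_statistics(rms_table, config.channels)
    for df in (anova, posthoc, effects):
        df.attrs["config_hash"] = config.config_hash()
        df.attrs["package_version"] = PACKAGE_VERSION
    result = PipelineResult(
        rms_table=rms_table, anova=anova, posthoc=posthoc,
        effect_sizes=effects, qc=qc, config=config, manifest=manifest,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "config.yaml")
        stamp = {"config_hash": config.config_hash(),
                 "package_version": PACKAGE_VERSION}
        for name, df in (
            ("rms_table", rms_table), ("anova", anova),
            ("posthoc", posthoc), ("effect_sizes", effects),
        ):
            df.to_csv(out_dir / f"{name}.csv", index=False)
        (out_dir / "qc.json").write_text(json.dumps(qc.to_dict(), indent=1))
        (out_dir / "summary.json").write_text(
            json.dumps({**stamp, **result.summary()}, indent=1)
        )
        if manifest is not None:
            (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        if config.make_figures:
            write_figures(rms_table, out_dir / "figures")
    return result


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def write_figures(rms_table: pd.DataFrame, fig_dir: str | Path) -> list[Path]:
    """Boxplot panels: condition, age and sex x age contrasts per channel."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = Path(fig_dir)
    fig_dir.mkdir(parents=True, exist_ok=True)
    channels = sorted(rms_table["channel"].unique())
    written = []

    def _boxpanel(fname, group_col, title):
        fig, axes = plt.subplots(
            1, len(channels), figsize=(4 * len(channels), 3.5), sharey=False
        )
        for ax, ch in zip(np.atleast_1d(axes), channels):
            sub = rms_table[rms_table["channel"] == ch]
            levels = sorted(sub[group_col].unique())
            data = [
                sub.loc[sub[group_col] == lv, "mean_rms"].to_numpy()
                for lv in levels
            ]
            ax.boxplot(data, tick_labels=levels)
            ax.set_title(ch)
            ax.set_ylabel("mean RMS (normalized)")
        fig.suptitle(title)
        fig.tight_layout()
        path = fig_dir / fname
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)

    _boxpanel("condition.png", "condition", "Perturbation type")
    _boxpanel("age.png", "age_group", "Age group")

    # sex x age panel per channel
    fig, axes = plt.subplots(
        1, len(channels), figsize=(4 * len(channels), 3.5)
    )
    for ax, ch in zip(np.atleast_1d(axes), channels):
        sub = rms_table[rms_table["channel"] == ch]
        cells = [
            (f"{a[0].upper()}{s[0].upper()}",
             sub.loc[(sub["age_group"] == a) & (sub["sex"] == s),
                     "mean_rms"].to_numpy())
            for a in ("young", "elder") for s in ("female", "male")
        ]
        ax.boxplot([c[1] for c in cells], tick_labels=[c[0] for c in cells])
        ax.set_title(ch)
        ax.set_ylabel("mean RMS (normalized)")
    fig.suptitle("Age x sex cells (Y=young, E=elder, F=female, M=male)")
    fig.tight_layout()
    path = fig_dir / "age_sex.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    written.append(path)
    return written
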