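"""Perturbation-trial protocol: the 34-trial platform-translation sequence.

The study protocol delivers 34 rapid support-surface translations to a standing
subject: a long habituation run of posterior translations with five anterior
"catch" trials interleaved. Each trial carries an analysis label:

* ``unpredictable`` — the very first translation (delivered without warning)
  and the five anterior catch trials (6 trials total);
* ``excluded`` — trials 2-5, dropped from analysis so that the predictable
  set reflects habituated responses (4 trials);
* ``predictable`` — the remaining 24 posterior translations.

Protocols are plain data so alternative sequences can be loaded from a config
file; :func:`build_default_protocol` returns the study sequence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

DIRECTIONS = ("posterior", "anterior")
ANALYSIS_LABELS = ("unpredictable", "predictable", "excluded")

#: 1-based indices of the anterior (catch) trials in the default sequence.
DEFAULT_ANTERIOR_TRIALS = frozenset({16, 22, 28, 29, 34})
#: 1-based indices of trials labelled unpredictable (first trial + catches).
DEFAULT_UNPREDICTABLE_TRIALS = frozenset({1, 16, 22, 28, 29, 34})
#: 1-based indices of trials excluded from analysis (early habituation run).
DEFAULT_EXCLUDED_TRIALS = frozenset({2, 3, 4, 5})
DEFAULT_N_TRIALS = 34


@dataclass(frozen=True)
class TrialSpec:
    """One platform translation: its position in the sequence, direction and label."""

    index: int
    direction: str
    analysis_label: str

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"trial index must be 1-based positive, got {self.index}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.analysis_label not in ANALYSIS_LABELS:
            raise ValueError(f"unknown analysis label {self.analysis_label!r}")
        if self.analysis_label == "excluded" and self.direction != "posterior":
            raise ValueError("excluded trials are posterior by construction")


@dataclass(frozen=True)
class ProtocolDefinition:
    """An ordered perturbation sequence with unique 1-based trial indices."""

    trials: tuple[TrialSpec, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        indices = [t.index for t in self.trials]
        if len(set(indices)) != len(indices):
            raise ValueError("trial indices must be unique within a protocol")

    def __len__(self) -> int:
        return len(self.trials)

    def trial(self, index: int) -> TrialSpec:
        """Return the trial with 1-based sequence index ``index``."""
        for t in self.trials:
            if t.index == index:
                return t
        raise KeyError(f"no trial with index {index}")

    @property
    def analyzable_trials(self) -> tuple[TrialSpec, ...]:
        """Trials entering analysis (label != excluded), in sequence order."""
        return tuple(t for t in self.trials if t.analysis_label != "excluded")

    def to_table(self) -> str:
        """Serialize as a plain-text table: one row per trial."""
        lines = ["index\tdirection\tanalysis_label"]
        lines += [f"{t.index}\t{t.direction}\t{t.analysis_label}" for t in self.trials]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_table(cls, text: str, name: str = "custom") -> "ProtocolDefinition":
        """Parse the plain-text table produced by :meth:`to_table`."""
        rows = [ln for ln in text.strip().splitlines() if ln.strip()]
        if not rows or rows[0].split("\t") != ["index", "direction", "analysis_label"]:
            raise ValueError("missing protocol table header")
        trials = tuple(
            TrialSpec(int(i), d, lab)
            for i, d, lab in (row.split("\t") for row in rows[1:])
        )
        return cls(trials=trials, name=name)

    @classmethod
    def from_records(
        cls, records: Iterable[Mapping[str, object]], name: str = "custom"
    ) -> "ProtocolDefinition":
        """Build from an iterable of dicts (e.g. parsed YAML/JSON config)."""
        trials = tuple(
            TrialSpec(
                int(r["index"]), str(r["direction"]), str(r["analysis_label"])
            )
            for r in records
        )
        return cls(trials=trials, name=name)


def build_default_protocol() -> ProtocolDefinition:
    """Return the study's fixed 34-trial sequence.

    Anterior catch trials sit at positions 16, 22, 28, 29 and 34; every other
    trial is a posterior translation. Trial 1 and the catch trials are labelled
    unpredictable, trials 2-5 excluded, the remaining posterior trials
    predictable.
    """
    trials = []
    for index in range(1, DEFAULT_N_TRIALS + 1):
        direction = "anterior" if index in DEFAULT_ANTERIOR_TRIALS else "posterior"
        if index in DEFAULT_UNPREDICTABLE_TRIALS:
            label = "unpredictable"
        elif index in DEFAULT_EXCLUDED_TRIALS:
            label = "excluded"
        else:
            label = "predictable"
        trials.append(TrialSpec(index=index, direction=direction, analysis_label=label))
    return ProtocolDefinition(trials=tuple(trials), name="default-34")


def condition_counts(protocol: ProtocolDefinition) -> dict[str, int]:
    """Tally analysis labels over a protocol.

    Returns a dict with a key for every label in :data:`ANALYSIS_LABELS`
    (zero where absent); counts sum to ``len(protocol)``.
    """
    if len(protocol) == 0:
        raise ValueError("cannot tally an empty protocol")
    tally = Counter(t.analysis_label for t in protocol.trials)
    return {label: tally.get(label, 0) for label in ANALYSIS_LABELS}


def direction_counts(protocol: ProtocolDefinition) -> dict[str, int]:
    """Tally translation directions over a protocol."""
    if len(protocol) == 0:
        raise ValueError("cannot tally an empty protocol")
    tally = Counter(t.direction for t in protocol.trials)
    return {d: tally.get(d, 0) for d in DIRECTIONS}
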