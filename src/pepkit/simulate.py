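"""Synthetic cohort generator: synchronized EEG + platform-acceleration sessions.

Emulates the study protocol: 40 standing subjects (2 age groups x 2 sexes,
10 per cell) each receive 34 rapid platform translations while EEG is recorded
at 1,000 Hz from Fz, Cz and three cEEGrid channels over each mastoid
(L5-L7, R5-R7), and platform acceleration is recorded at 150 Hz on a
synchronized clock.

Signal model, per channel::

    eeg(t) = 1/f^alpha background + 60 Hz line component
             + sum over trials of PEP(t - onset_k) * gain_k

where the perturbation-evoked potential (PEP) is a biphasic
(negative-then-positive) deflection starting 90-130 ms after perturbation
onset, and ``gain_k`` multiplies a per-channel base amplitude by the subject's
individual gain, a condition gain on unpredictable trials, an age gain for
elders (Cz and mastoid), and an extra mastoid gain for elderly males. These
gain directions reproduce the study's reported effect structure; the default
condition gains are calibrated by simulation so the full analysis pipeline
recovers a condition-effect Cohen's d of ~0.5 at the combined mastoid, ~0.3
at Fz and ~0.2 at Cz (see the package methods note).

Platform kinematics follow a triangular-velocity profile honouring the nominal
peak acceleration (0.2 g) and displacement (20 cm); the nominal 100 cm/s peak
velocity is infeasible for that pair, so peak velocity is capped at
sqrt(a * d) (~63 cm/s) — see :func:`simulate_platform_motion`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace, asdict
from typing import Iterator, Sequence

import numpy as np

from .protocol import ProtocolDefinition, build_default_protocol

AGE_GROUPS = ("young", "elder")
SEXES = ("male", "female")
DEFAULT_CHANNELS = ("Fz", "Cz", "L5", "L6", "L7", "R5", "R6", "R7")
MASTOID_LEFT = ("L5", "L6", "L7")
MASTOID_RIGHT = ("R5", "R6", "R7")

GRAVITY = 9.81  # m/s^2


def channel_group(name: str) -> str:
    """Map a channel name to its amplitude group: 'Fz', 'Cz' or 'mastoid'."""
    if name in ("Fz", "Cz"):
        return name
    if name in MASTOID_LEFT or name in MASTOID_RIGHT:
        return "mastoid"
    raise KeyError(f"unknown channel {name!r}")


# ---------------------------------------------------------------------------
# Subject / platform / generator configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectProfile:
    """One cohort member: demographic cell plus an individual amplitude gain."""

    subject_id: str
    age_group: str
    sex: str
    subject_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age group {self.age_group!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if not self.subject_gain > 0:
            raise ValueError("subject_gain must be positive")


@dataclass(frozen=True)
class PlatformProfile:
    """Kinematic parameters of one platform translation.

    Defaults encode the nominal study kinematics: 20 cm displacement,
    100 cm/s commanded peak velocity, 0.2 g peak acceleration, platform
    accelerometer sampled at 150 Hz.
    """

    sampling_rate: float = 150.0
    peak_acceleration: float = 0.2 * GRAVITY
    target_displacement: float = 0.20
    target_peak_velocity: float = 1.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.peak_acceleration <= 0:
            raise ValueError("peak_acceleration must be positive")
        if self.target_displacement < 0:
            raise ValueError("target_displacement must be nonnegative")
        if self.target_peak_velocity <= 0:
            raise ValueError("target_peak_velocity must be positive")


@dataclass(frozen=True)
class GeneratorConfig:
    """All simulation parameters; ``seed`` fully determines the output.

    Per-channel-group values are keyed by 'Fz', 'Cz', 'mastoid'. The default
    ``condition_gain`` values are the package's calibrated defaults (targets:
    pipeline-recovered condition Cohen's d of 0.5 mastoid / 0.3 Fz / 0.2 Cz).
    """

    eeg_sampling_rate: float = 1000.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    pep_latency_ms: tuple[float, float] = (90.0, 130.0)
    pep_duration_ms: float = 130.0
    pep_base_amplitude: dict = field(
        default_factory=lambda: {"Fz": 6.0, "Cz": 7.0, "mastoid": 3.6}
    )
    condition_gain: dict = field(
        default_factory=lambda: {"Fz": 1.04, "Cz": 1.03, "mastoid": 1.27}
    )
    age_gain: dict = field(
        default_factory=lambda: {"Fz": 1.0, "Cz": 1.25, "mastoid": 1.25}
    )
    elder_male_mastoid_gain: float = 1.80
    first_trial_gain: float = 2.0
    amplitude_jitter_sigma: float = 0.25
    subject_gain_sigma: float = 0.25
    noise_alpha: float = 1.0
    noise_rms: dict = field(
        default_factory=lambda: {"Fz": 2.2, "Cz": 2.6, "mastoid": 1.2}
    )
    line_noise_amplitude: float = 2.0
    line_noise_freq: float = 60.0
    accel_noise_rms: float = 0.01
    platform: PlatformProfile = field(default_factory=PlatformProfile)
    pre_roll_s: float = 3.0
    inter_onset_s: float = 8.0
    post_roll_s: float = 2.0
    n_per_cell: int = 10
    dropout_events: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.pep_latency_ms
        if not (0 < lo <= hi <= 150):
            raise ValueError("pep_latency_ms bounds must lie inside (0, 150]")
        for name, d in (
            ("pep_base_amplitude", self.pep_base_amplitude),
            ("condition_gain", self.condition_gain),
            ("age_gain", self.age_gain),
            ("noise_rms", self.noise_rms),
        ):
            for k, v in d.items():
                if not v > 0:
                    raise ValueError(f"{name}[{k!r}] must be strictly positive")
        if not self.elder_male_mastoid_gain > 0:
            raise ValueError("elder_male_mastoid_gain must be strictly positive")
        if not self.first_trial_gain > 0:
            raise ValueError("first_trial_gain must be strictly positive")
        if self.amplitude_jitter_sigma < 0:
            raise ValueError("amplitude_jitter_sigma must be nonnegative")
        if self.inter_onset_s < 7.0:
            raise ValueError("inter-onset interval must be >= 7 s (platform return)")
        if self.dropout_events < 0:
            raise ValueError("dropout_events must be nonnegative")
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channels"] = list(self.channels)
        d["pep_latency_ms"] = list(self.pep_latency_ms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "platform" in d and isinstance(d["platform"], dict):
            d["platform"] = PlatformProfile(**d["platform"])
        if "channels" in d:
            d["channels"] = tuple(d["channels"])
        if "pep_latency_ms" in d:
            d["pep_latency_ms"] = tuple(d["pep_latency_ms"])
        return cls(**d)

    def with_unit_gains(self) -> "GeneratorConfig":
        """Null configuration: no condition, age or sex effects (all gains 1)."""
        unit = {k: 1.0 for k in self.condition_gain}
        return replace(
            self,
            condition_gain=dict(unit),
            age_gain={k: 1.0 for k in self.age_gain},
            elder_male_mastoid_gain=1.0,
            first_trial_gain=1.0,
        )


@dataclass
class ContinuousRecording:
    """One subject's synchronized session.

    ``eeg`` is channels x samples in microvolts at ``eeg_sampling_rate``;
    ``acceleration`` is platform acceleration in m/s^2 at the platform rate.
    ``event_markers`` hold (trial_index, sample index on the EEG clock) for
    every trial, excluded ones included. ``true_onsets`` (seconds) and
    ``incomplete_trials`` exist only for simulated data.
    """

    subject: SubjectProfile
    eeg: np.ndarray
    channels: tuple[str, ...]
    eeg_sampling_rate: float
    acceleration: np.ndarray
    accel_sampling_rate: float
    event_markers: list[tuple[int, int]]
    true_onsets: list[float] | None = None
    incomplete_trials: set[int] = field(default_factory=set)

    @property
    def duration_s(self) -> float:
        return self.eeg.shape[1] / self.eeg_sampling_rate

    def channel_index(self, name: str) -> int:
        return self.channels.index(name)


# ---------------------------------------------------------------------------
# Platform kinematics
# ---------------------------------------------------------------------------

def integrate_platform_motion(acceleration: np.ndarray, sampling_rate: float) -> float:
    """Numerically double-integrate an acceleration trace to net displacement (m).

    Acceleration -> velocity by left-rectangle cumulative sum (exact for the
    sample-and-hold traces the simulator emits), velocity -> displacement by
    the trapezoidal rule. This is the quadrature under which generated traces
    satisfy the displacement invariant.
    """
    dt = 1.0 / sampling_rate
    velocity = np.concatenate([[0.0], np.cumsum(acceleration[:-1]) * dt])
    return float(np.trapezoid(velocity, dx=dt))


def simulate_platform_motion(
    profile: PlatformProfile, direction: str = "posterior"
) -> np.ndarray:
    """Acceleration trace (m/s^2) of one platform translation.

    Velocity follows a trapezoidal profile honouring ``peak_acceleration`` and
    ``target_displacement``. If the commanded peak velocity cannot be reached
    within the displacement (``v^2/a > d``) the profile degenerates to a
    triangle with peak velocity ``sqrt(a*d)`` and a warning is issued — the
    nominal study kinematics (0.2 g, 100 cm/s, 20 cm) fall in this regime.
    Sign encodes direction: posterior negative, anterior positive. The
    returned trace double-integrates (:func:`integrate_platform_motion`) to
    the target displacement to well below 1e-6 m.
    """
    if direction not in ("posterior", "anterior"):
        raise ValueError(f"unknown direction {direction!r}")
    a = profile.peak_acceleration
    d = profile.target_displacement
    fs = profile.sampling_rate
    dt = 1.0 / fs
    if d == 0.0:
        return np.zeros(2)

    v_max_feasible = np.sqrt(a * d)
    if profile.target_peak_velocity > v_max_feasible:
        warnings.warn(
            "target peak velocity "
            f"{profile.target_peak_velocity:.3f} m/s infeasible for "
            f"a={a:.3f} m/s^2, d={d:.3f} m; capping at sqrt(a*d)="
            f"{v_max_feasible:.3f} m/s (triangular velocity profile)",
            stacklevel=2,
        )
    v_pk = min(profile.target_peak_velocity, v_max_feasible)

    t_ramp = v_pk / a                       # accelerate / decelerate duration
    t_cruise = (d - v_pk * t_ramp) / v_pk   # zero for the triangular case
    t_total = 2 * t_ramp + t_cruise

    n = int(np.ceil(t_total / dt)) + 2
    t = np.arange(n) * dt
    velocity = np.where(
        t < t_ramp,
        a * t,
        np.where(
            t < t_ramp + t_cruise,
            v_pk,
            np.maximum(v_pk - a * (t - t_ramp - t_cruise), 0.0),
        ),
    )
    velocity[t >= t_total] = 0.0
    # sample-and-hold acceleration whose rectangle-rule integral is exactly
    # the sampled velocity
    accel = np.diff(velocity, append=velocity[-1]) / dt

    # rescale so the documented quadrature recovers the displacement exactly
    # (corrects the O(a*dt^2) corner-clipping of the discrete profile; peak
    # acceleration deviates from nominal by <1%)
    d_hat = integrate_platform_motion(accel, fs)
    accel *= d / d_hat
    if direction == "posterior":
        accel = -accel
    return accel


# ---------------------------------------------------------------------------
# PEP waveform
# ---------------------------------------------------------------------------

def simulate_pep_waveform(
    latency_ms: float,
    amplitude: float,
    duration_ms: float = 90.0,
    rng: np.random.Generator | None = None,
    sampling_rate: float = 1000.0,
) -> np.ndarray:
    """Single-channel PEP deflection aligned to perturbation onset (t=0).

    A biphasic atom: a short, sharp negative lobe followed by a broader
    positive lobe (half-sine lobes), starting at ``latency_ms`` and spanning
    ``duration_ms``. The maximum positive excursion equals ``amplitude``
    exactly; the trace is zero before the latency. If ``rng`` is given, lobe
    proportions jitter slightly trial-to-trial (the positive peak is still
    normalized to ``amplitude``).
    """
    if not (0 < latency_ms <= 150):
        raise ValueError("latency_ms must lie in (0, 150]")
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")

    neg_frac, neg_depth = 0.30, 0.90
    if rng is not None:
        neg_frac = rng.uniform(0.25, 0.35)
        neg_depth = rng.uniform(0.85, 0.95)

    dt_ms = 1000.0 / sampling_rate
    n_total = int(np.ceil((latency_ms + duration_ms) / dt_ms)) + 1
    t = np.arange(n_total) * dt_ms
    y = np.zeros(n_total)

    tau = t - latency_ms
    w1 = neg_frac * duration_ms
    w2 = duration_ms - w1
    neg = (tau >= 0) & (tau < w1)
    pos = (tau >= w1) & (tau < duration_ms)
    y[neg] = -neg_depth * np.sin(np.pi * tau[neg] / w1)
    y[pos] = np.sin(np.pi * (tau[pos] - w1) / w2)

    peak = y.max()
    if amplitude == 0.0 or peak <= 0.0:
        return np.zeros(n_total)
    return y * (amplitude / peak)


# ---------------------------------------------------------------------------
# Background noise
# ---------------------------------------------------------------------------

def _pink_noise_batch(
    n_channels: int, n: int, sampling_rate: float, alpha: float,
    band_rms: np.ndarray, band: tuple[float, float], rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian 1/f^alpha noise, one row per channel, scaled so each row's
    (band_lo, band_hi) component has RMS ``band_rms[row]``.

    Frequency-domain synthesis (single-precision draws, batched inverse FFT at
    an FFT-friendly length >= n, then truncated); ``rng`` state fully
    determines the output.
    """
    from scipy.fft import next_fast_len

    m = next_fast_len(n)
    freqs = np.fft.rfftfreq(m, 1.0 / sampling_rate)
    shape = np.zeros_like(freqs)
    f_floor = 0.5  # flat below 0.5 Hz to avoid the 1/f blow-up
    nz = freqs > 0
    shape[nz] = np.maximum(freqs[nz], f_floor) ** (-alpha / 2.0)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    # Var(x_t) restricted to band = (4/m^2) * sum(shape_k^2) for 0<k<m/2
    band_var_unit = 4.0 / m**2 * np.sum(shape[in_band] ** 2)
    unit_scale = 1.0 / np.sqrt(band_var_unit)

    z = rng.standard_normal((n_channels, len(freqs)), dtype=np.float32).astype(
        np.complex64
    )
    z += 1j * rng.standard_normal((n_channels, len(freqs)), dtype=np.float32)
    spec = z * (shape * unit_scale).astype(np.float32)
    spec[:, 0] = 0.0
    x = np.fft.irfft(spec, m, axis=-1)[:, :n]
    return x * np.asarray(band_rms, dtype=float)[:, None]


def _pink_noise(
    n: int, sampling_rate: float, alpha: float, band_rms: float,
    band: tuple[float, float], rng: np.random.Generator,
) -> np.ndarray:
    """Single-channel convenience wrapper around :func:`_pink_noise_batch`."""
    return _pink_noise_batch(
        1, n, sampling_rate, alpha, np.array([band_rms]), band, rng
    )[0]


# ---------------------------------------------------------------------------
# Subject recording and cohort
# ---------------------------------------------------------------------------

def _trial_amplitude(
    subject: SubjectProfile, group: str, label: str, config: GeneratorConfig,
    is_first_trial: bool = False,
) -> float:
    """Deterministic PEP positive-peak amplitude (uV) for one subject/channel/trial.

    The very first perturbation is delivered mid-conversation with no warning
    and evokes a pronounced startle: its amplitude is base x subject gain x
    ``first_trial_gain``, without the condition/age/sex modulators (a ceiling
    response). This is also what makes first-trial normalization behave as in
    the study: it removes individual amplitude scale (electrode impedance,
    anatomy) while group effects on later trials survive.
    """
    amp = config.pep_base_amplitude[group] * subject.subject_gain
    if is_first_trial:
        return amp * config.first_trial_gain
    if label == "unpredictable":
        amp *= config.condition_gain[group]
    if subject.age_group == "elder":
        amp *= config.age_gain[group]
        if subject.sex == "male" and group == "mastoid":
            amp *= config.elder_male_mastoid_gain
    return amp


def simulate_subject_recording(
    subject: SubjectProfile,
    protocol: ProtocolDefinition,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> ContinuousRecording:
    """Simulate one subject's full synchronized session.

    Onsets are evenly spaced ``inter_onset_s`` apart (>= 7 s platform-return
    interval); every trial gets an event marker on the EEG clock and a platform
    acceleration burst at the true onset. EEG is 1/f background + 60 Hz line +
    the gain-scaled PEP of each trial.
    """
    fs = config.eeg_sampling_rate
    fs_acc = config.platform.sampling_rate
    n_trials = len(protocol)

    duration = config.pre_roll_s + (n_trials - 1) * config.inter_onset_s + config.post_roll_s
    n_eeg = int(round(duration * fs))
    n_acc = int(round(duration * fs_acc))

    onsets = config.pre_roll_s + config.inter_onset_s * np.arange(n_trials)

    t_line = np.arange(n_eeg) / fs
    line_phase = rng.uniform(0, 2 * np.pi)
    line = config.line_noise_amplitude * np.sin(
        2 * np.pi * config.line_noise_freq * t_line + line_phase
    )
    band = (2.5, 30.0)
    rms_per_channel = np.array(
        [config.noise_rms[channel_group(ch)] for ch in config.channels]
    )
    eeg = _pink_noise_batch(
        len(config.channels), n_eeg, fs, config.noise_alpha,
        rms_per_channel, band, rng,
    )
    eeg += line

    # platform acceleration: sensor noise + one burst per trial
    accel = config.accel_noise_rms * rng.standard_normal(n_acc)
    burst_cache: dict[str, np.ndarray] = {}

    true_onsets: list[float] = []
    markers: list[tuple[int, int]] = []
    for k, trial in enumerate(protocol.trials):
        onset = float(onsets[k])
        true_onsets.append(onset)
        markers.append((trial.index, int(round(onset * fs))))

        if trial.direction not in burst_cache:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                burst_cache[trial.direction] = simulate_platform_motion(
                    config.platform, trial.direction
                )
        burst = burst_cache[trial.direction]
        i0 = int(round(onset * fs_acc))
        accel[i0 : i0 + len(burst)] += burst[: n_acc - i0]

        latency = rng.uniform(*config.pep_latency_ms)
        unit = simulate_pep_waveform(
            latency, 1.0, config.pep_duration_ms, rng, sampling_rate=fs
        )
        # arousal-like trial-to-trial amplitude jitter, shared across channels;
        # truncated at +-1 sigma: evoked responses vary but never vanish
        sig = config.amplitude_jitter_sigma
        jitter = float(
            np.exp(np.clip(rng.normal(0.0, sig), -sig, sig))
        )
        j0 = int(round(onset * fs))
        seg = slice(j0, min(j0 + len(unit), n_eeg))
        for ci, ch in enumerate(config.channels):
            amp = jitter * _trial_amplitude(
                subject, channel_group(ch), trial.analysis_label, config,
                is_first_trial=(k == 0),
            )
            eeg[ci, seg] += amp * unit[: seg.stop - seg.start]

    return ContinuousRecording(
        subject=subject,
        eeg=eeg,
        channels=tuple(config.channels),
        eeg_sampling_rate=fs,
        acceleration=accel,
        accel_sampling_rate=fs_acc,
        event_markers=markers,
        true_onsets=true_onsets,
        incomplete_trials=set(),
    )


def build_cohort_profiles(config: GeneratorConfig) -> list[SubjectProfile]:
    """Demographic cells (young/elder x male/female, n_per_cell each) with
    lognormal individual gains drawn from the config seed."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    profiles = []
    i = 0
    for age in AGE_GROUPS:
        for sex in SEXES:
            for _ in range(config.n_per_cell):
                i += 1
                # truncated at +-1 sigma: individual scale varies but is bounded
                sig = config.subject_gain_sigma
                gain = float(
                    np.exp(np.clip(rng.normal(0.0, sig), -sig, sig))
                )
                profiles.append(
                    SubjectProfile(
                        subject_id=f"S{i:02d}", age_group=age, sex=sex,
                        subject_gain=gain,
                    )
                )
    return profiles


def assign_dropout(
    config: GeneratorConfig,
    protocol: ProtocolDefinition,
    profiles: Sequence[SubjectProfile],
) -> dict[str, set[int]]:
    """Choose ``dropout_events`` analyzable (subject, trial) slots uniformly at
    random to flag incomplete ('technical issues'); excluded trials never drop."""
    analyzable = [t.index for t in protocol.analyzable_trials]
    slots = [(p.subject_id, ti) for p in profiles for ti in analyzable]
    if config.dropout_events > len(slots):
        raise ValueError(
            f"dropout_events={config.dropout_events} exceeds the "
            f"{len(slots)} analyzable events in the cohort"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    chosen = rng.choice(len(slots), size=config.dropout_events, replace=False)
    out: dict[str, set[int]] = {p.subject_id: set() for p in profiles}
    for idx in chosen:
        sid, ti = slots[int(idx)]
        out[sid].add(ti)
    return out


def cohort_manifest(
    config: GeneratorConfig,
    protocol: ProtocolDefinition,
    profiles: Sequence[SubjectProfile],
    dropout: dict[str, set[int]],
) -> dict:
    """JSON-serializable record of how a cohort was generated."""
    return {
        "seed": config.seed,
        "protocol": protocol.name,
        "n_subjects": len(profiles),
        "config": config.to_dict(),
        "subjects": [
            {
                "subject_id": p.subject_id,
                "age_group": p.age_group,
                "sex": p.sex,
                "subject_gain": p.subject_gain,
                "incomplete_trials": sorted(dropout[p.subject_id]),
            }
            for p in profiles
        ],
    }


def iter_cohort(
    config: GeneratorConfig, protocol: ProtocolDefinition | None = None
) -> Iterator[ContinuousRecording]:
    """Yield cohort recordings one subject at a time (memory-friendly)."""
    if protocol is None:
        protocol = build_default_protocol()
    profiles = build_cohort_profiles(config)
    dropout = assign_dropout(config, protocol, profiles)
    root = np.random.SeedSequence([config.seed, 2])
    children = root.spawn(len(profiles))
    for prof, ss in zip(profiles, children):
        rec = simulate_subject_recording(
            prof, protocol, config, np.random.default_rng(ss)
        )
        rec.incomplete_trials = dropout[prof.subject_id]
        yield rec


def simulate_cohort(
    config: GeneratorConfig, protocol: ProtocolDefinition | None = None
) -> tuple[list[ContinuousRecording], dict]:
    """Simulate the full cohort; returns (recordings, manifest).

    Identical (config, protocol) including seed give bit-identical outputs.
    """
    if protocol is None:
        protocol = build_default_protocol()
    profiles = build_cohort_profiles(config)
    dropout = assign_dropout(config, protocol, profiles)
    manifest = cohort_manifest(config, protocol, profiles, dropout)
    recordings = list(iter_cohort(config, protocol))
    return recordings, manifest
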