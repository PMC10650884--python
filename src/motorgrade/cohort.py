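"""Synthetic wearable-sensor cohort generator.

Emulates the statistical structure of a two-sensor accelerometer study
of repetitive-movement tasks (finger tapping FT, hand movements HM,
pronation-supination PS, toe tapping TT, leg agility LA) in people
with Parkinson's disease (PD) and healthy older adults (HOA): 80 Hz
tri-axial acceleration from two correlated sensors, with MDS-UPDRS
severity labels 0-4 per PD recording.

The movement model is quasi-periodic: an exponentially decaying
cosine (bradykinesia sequence effect) with phase jitter, gated by
Poisson-arriving cosine-tapered hesitation pauses, plus a 4-6 Hz rest
tremor sinusoid and i.i.d. Gaussian sensor noise. Each sensor reads a
static unit gravity offset plus the movement projected on its axis
direction, so the resultant acceleration carries the movement
fundamental linearly (as a real accelerometer does). Severity maps to
movement parameters by linear interpolation between a severity-0 and
a severity-4 anchor, with multiplicative log-normal heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

TASKS = ("FT", "HM", "PS", "TT", "LA")

#: task-specific repetition frequency anchors (Hz)
TASK_BASE_FREQUENCY = {"FT": 3.0, "HM": 2.5, "PS": 2.0, "TT": 2.5, "LA": 2.0}

#: severity anchors: (value at severity 0, value at severity 4)
ANCHORS = {
    "amplitude": (0.70, 0.15),  # g
    "decrement_rate": (0.0, 0.08),  # 1/s
    "tremor_amplitude": (0.0, 0.30),  # g
    "hesitation_rate": (0.0, 0.25),  # events/s
    "phase_jitter_sd": (0.05, 0.45),  # rad/sqrt(s)
}

DEFAULT_SEVERITY_DISTRIBUTION = (0.20, 0.30, 0.20, 0.20, 0.10)


@dataclass
class MovementParams:
    """Generative parameters of one recording's movement signal."""

    base_frequency: float
    amplitude: float
    decrement_rate: float
    tremor_frequency: float
    tremor_amplitude: float
    hesitation_rate: float
    phase_jitter_sd: float
    noise_sd: float
    sensor_axis_directions: tuple = (
        (0.0, 0.0, 1.0),
        (0.0, 0.0, 1.0),
    )
    sensor_gains: tuple = (1.0, 0.9)
    gravity: tuple = (0.0, 0.0, 1.0)  # static offset read by both sensors (g)

    def __post_init__(self):
        for name in (
            "amplitude",
            "decrement_rate",
            "tremor_amplitude",
            "hesitation_rate",
            "phase_jitter_sd",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for v in self.sensor_axis_directions:
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValueError("sensor axis directions must be unit vectors")
        if any(g <= 0 for g in self.sensor_gains):
            raise ValueError("sensor gains must be positive")


@dataclass
class RawRecording:
    """One session x task recording from two tri-axial sensors.

    samples: array (n, 2, 3) — time step, sensor, (ax, ay, az).
    """

    participant_id: str
    session_id: str
    cohort: str  # "PD" | "HOA"
    task: str
    severity: int
    sampling_rate: float
    samples: np.ndarray
    ground_truth_params: MovementParams | None = None

    @property
    def recording_id(self) -> str:
        return f"{self.participant_id}_{self.session_id}_{self.task}"

    def __post_init__(self):
        if self.cohort not in ("PD", "HOA"):
            raise ValueError("cohort must be PD or HOA")
        if self.cohort == "HOA" and self.severity != 0:
            raise ValueError("HOA recordings must have severity 0")
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 3 or self.samples.shape[1:] != (2, 3):
            raise ValueError("samples must have shape (n, 2, 3)")


@dataclass
class CohortSpec:
    """Study-shape parameters for a synthetic cohort."""

    n_pd: int = 20
    n_hoa: int = 8
    retest_fraction: float = 0.68
    tasks: tuple = TASKS
    severity_distribution: tuple = DEFAULT_SEVERITY_DISTRIBUTION
    sampling_rate: float = 80.0
    duration: float = 20.0
    seed: int = 0
    heterogeneity_sd: float = 0.15

    def __post_init__(self):
        p = np.asarray(self.severity_distribution, dtype=float)
        if p.shape != (5,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("severity_distribution must be 5 probabilities summing to 1")
        if not 0 <= self.retest_fraction <= 1:
            raise ValueError("retest_fraction must be in [0, 1]")
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be positive")
        if len(self.tasks) == 0:
            raise ValueError("task set must not be empty")
        for t in self.tasks:
            if t not in TASKS:
                raise ValueError(f"unknown task {t!r}")
        if self.n_pd < 0 or self.n_hoa < 0:
            raise ValueError("participant counts must be non-negative")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def severity_to_params(
    severity: int,
    cohort: str,
    task: str,
    rng: np.random.Generator,
    heterogeneity_sd: float = 0.15,
    noise_sd: float = 0.02,
) -> MovementParams:
    """Map an MDS-UPDRS severity (0-4) to movement-model parameters.

    Linear interpolation between per-field severity-0 and severity-4
    anchors, multiplied by log-normal heterogeneity. All random draws
    happen in a fixed order, so two calls with identically seeded
    generators give parameter sets that preserve the severity ordering
    (amplitude non-increasing; decrement, tremor, hesitation and
    jitter non-decreasing in severity).
    """
    if not (isinstance(severity, (int, np.integer)) and 0 <= severity <= 4):
        raise ValueError("severity must be an integer in 0..4")
    if cohort == "HOA" and severity != 0:
        raise ValueError("HOA implies severity 0")
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")

    # fixed draw order => identical multipliers under identical rng state
    mult = {
        name: float(rng.lognormal(0.0, heterogeneity_sd)) for name in sorted(ANCHORS)
    }
    freq_mult = float(rng.lognormal(0.0, 0.08))
    tremor_frequency = float(rng.uniform(4.0, 6.0))
    gain2 = float(rng.uniform(0.8, 1.0))
    tilt = rng.normal(0.0, 0.15, size=(2, 2))

    s = severity / 4.0
    values = {}
    for name, (lo, hi) in ANCHORS.items():
        values[name] = (lo + s * (hi - lo)) * mult[name]
    axes = tuple(
        tuple(_unit(np.array([tilt[k, 0], tilt[k, 1], 1.0]))) for k in range(2)
    )
    return MovementParams(
        base_frequency=TASK_BASE_FREQUENCY[task] * freq_mult,
        amplitude=values["amplitude"],
        decrement_rate=values["decrement_rate"],
        tremor_frequency=tremor_frequency,
        tremor_amplitude=values["tremor_amplitude"],
        hesitation_rate=values["hesitation_rate"],
        phase_jitter_sd=values["phase_jitter_sd"],
        noise_sd=noise_sd,
        sensor_axis_directions=axes,
        sensor_gains=(1.0, gain2),
    )


def _hesitation_gate(
    n: int, fs: float, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Multiplicative gate in [0,1]: cosine-tapered dips to 0, 0.3-1.0 s long."""
    gate = np.ones(n)
    duration = n / fs
    n_events = rng.poisson(rate * duration)
    for _ in range(n_events):
        start = rng.uniform(0.0, duration)
        length = rng.uniform(0.3, 1.0)
        i0 = int(start * fs)
        i1 = min(n, int((start + length) * fs))
        if i1 <= i0 + 1:
            continue
        u = np.linspace(0.0, 1.0, i1 - i0)
        dip = 0.5 * (1.0 - np.cos(2.0 * np.pi * u))  # 0 -> 1 -> 0
        gate[i0:i1] = np.minimum(gate[i0:i1], 1.0 - dip)
    return gate


def simulate_recording(
    params: MovementParams,
    duration: float,
    sampling_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate two-sensor tri-axial samples, shape (n, 2, 3)."""
    if duration <= 0 or sampling_rate <= 0:
        raise ValueError("duration and sampling_rate must be positive")
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate

    jitter = np.cumsum(
        rng.normal(0.0, params.phase_jitter_sd / np.sqrt(sampling_rate), n)
    )
    phase = 2.0 * np.pi * params.base_frequency * t + jitter
    envelope = params.amplitude * np.exp(-params.decrement_rate * t)
    gate = _hesitation_gate(n, sampling_rate, params.hesitation_rate, rng)
    movement = envelope * np.cos(phase) * gate

    tremor_phase = float(rng.uniform(0.0, 2.0 * np.pi))
    tremor = params.tremor_amplitude * np.sin(
        2.0 * np.pi * params.tremor_frequency * t + tremor_phase
    )

    signal = movement + tremor
    samples = np.empty((n, 2, 3))
    gravity = np.asarray(params.gravity, dtype=float)
    for k in range(2):
        axis = np.asarray(params.sensor_axis_directions[k], dtype=float)
        samples[:, k, :] = gravity[None, :] + params.sensor_gains[k] * np.outer(
            signal, axis
        )
    if params.noise_sd > 0:
        samples += rng.normal(0.0, params.noise_sd, samples.shape)
    return samples


def generate_cohort(spec: CohortSpec) -> tuple[list[RawRecording], pd.DataFrame]:
    """Generate a full synthetic cohort, reproducible from ``spec.seed``.

    Every participant contributes one session plus, with probability
    ``retest_fraction``, one retest session; each session yields one
    recording per task; PD severity is drawn once per
    participant-session-task from ``severity_distribution`` (HOA is
    always severity 0).
    """
    rng = np.random.default_rng(spec.seed)
    recordings: list[RawRecording] = []
    rows = []
    roster = [("PD", f"PD{i + 1:02d}") for i in range(spec.n_pd)]
    roster += [("HOA", f"HOA{i + 1:02d}") for i in range(spec.n_hoa)]
    for cohort, pid in roster:
        n_sessions = 1 + int(rng.random() < spec.retest_fraction)
        for s in range(n_sessions):
            session_id = f"S{s + 1}"
            for task in spec.tasks:
                if cohort == "PD":
                    severity = int(
                        rng.choice(5, p=np.asarray(spec.severity_distribution))
                    )
                else:
                    severity = 0
                params = severity_to_params(
                    severity, cohort, task, rng, spec.heterogeneity_sd
                )
                samples = simulate_recording(
                    params, spec.duration, spec.sampling_rate, rng
                )
                rec = RawRecording(
                    participant_id=pid,
                    session_id=session_id,
                    cohort=cohort,
                    task=task,
                    severity=severity,
                    sampling_rate=spec.sampling_rate,
                    samples=samples,
                    ground_truth_params=params,
                )
                recordings.append(rec)
                rows.append(
                    {
                        "recording_id": rec.recording_id,
                        "participant_id": pid,
                        "session_id": session_id,
                        "cohort": cohort,
                        "task": task,
                        "severity": severity,
                    }
                )
    return recordings, pd.DataFrame(rows)


# -- delimited-text interchange format ---------------------------------


def write_recording_csv(recording: RawRecording, path) -> None:
    """Write long-format CSV: time_s, sensor_id (1|2), ax, ay, az."""
    n = recording.samples.shape[0]
    t = np.arange(n) / recording.sampling_rate
    frames = []
    for k in range(2):
        frames.append(
            pd.DataFrame(
                {
                    "time_s": t,
                    "sensor_id": k + 1,
                    "ax": recording.samples[:, k, 0],
                    "ay": recording.samples[:, k, 1],
                    "az": recording.samples[:, k, 2],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_recording_csv(
    path,
    participant_id: str,
    session_id: str,
    cohort: str,
    task: str,
    severity: int,
    sampling_rate: float = 80.0,
) -> RawRecording:
    df = pd.read_csv(path)
    sensors = []
    for k in (1, 2):
        sub = df[df["sensor_id"] == k].sort_values("time_s")
        sensors.append(sub[["ax", "ay", "az"]].to_numpy())
    if sensors[0].shape != sensors[1].shape:
        raise ValueError("sensors have unequal lengths")
    samples = np.stack(sensors, axis=1)
    return RawRecording(
        participant_id=participant_id,
        session_id=session_id,
        cohort=cohort,
        task=task,
        severity=severity,
        sampling_rate=sampling_rate,
        samples=samples,
    )


def write_cohort(recordings: list[RawRecording], manifest: pd.DataFrame, out_dir) -> Path:
    """Write one CSV per recording plus a manifest CSV; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recordings:
        p = out_dir / f"{rec.recording_id}.csv"
        write_recording_csv(rec, p)
        paths.append(p.name)
    manifest = manifest.copy()
    manifest["sampling_rate"] = [rec.sampling_rate for rec in recordings]
    manifest["file"] = paths
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def read_cohort(manifest_path) -> tuple[list[RawRecording], pd.DataFrame]:
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    recordings = []
    for _, row in manifest.iterrows():
        recordings.append(
            read_recording_csv(
                manifest_path.parent / row["file"],
                participant_id=row["participant_id"],
                session_id=row["session_id"],
                cohort=row["cohort"],
                task=row["task"],
                severity=int(row["severity"]),
                sampling_rate=float(row.get("sampling_rate", 80.0)),
            )
        )
    return recordings, manifest.drop(columns=["file"])
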