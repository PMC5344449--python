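"""Synthetic gesture/color Stroop fNIRS and behavioral data with known truth.

The generator emulates the study design every downstream stage expects:
twelve 15 s task blocks alternating with 15 s rest, four trials per block at
an ISI of 3.75 s (48 trials, 360 s per run), each block dominated by one
congruency with a single randomly placed oddball of the opposite congruency;
98 channels from 30 emitters / 29 detectors at 3 cm spacing sampled every
27 ms at three wavelengths (780/805/830 nm).

Hemodynamics are forward-modeled: condition boxcars convolved with the
canonical HRF scale per-channel effect amplitudes (uM-equivalent units),
on top of shared systemic oscillations (cardiac ~1 Hz, respiratory
~0.25 Hz, Mayer waves ~0.1 Hz) with near-unit per-channel gains, slow
drift, and white noise.  HbR is generated as a scaled mirror of the HbO
response (default -1/3) with its own noise.  Optical densities follow from
the modified Beer-Lambert forward model, so inversion, preprocessing, GLM
and group inference can all be validated against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import glm
from .geometry import ProbeLayout, default_probe_layout
from .hemodynamics import (ExtinctionTable, HemoTimeSeries,
                           OpticalDensityRecording, forward_mbll)

__all__ = [
    "SimulationConfig",
    "RTParams",
    "EventSchedule",
    "SubjectData",
    "generate_event_schedule",
    "generate_hemo_truth",
    "generate_rt_trials",
    "simulate_subject",
    "simulate_cohort",
    "default_active_channels",
]

GESTURE_TYPES = ("head_nod", "head_shake", "thumbs_up", "thumbs_down")
ACTOR_GENDERS = ("female", "male")


@dataclass
class RTParams:
    """Reaction-time distribution for one task (ms).

    Trial RTs are lognormal with the given mean and trial-to-trial SD;
    incongruent trials add ``delta`` to the mean.  Each subject carries a
    normal random offset (SD ``between_sd``) shared by both congruencies,
    so the congruency effect is within-subject.  Responses are correct with
    probability ``accuracy``.
    """

    mean: float = 1365.0
    sd: float = 300.0
    delta: float = 40.0
    between_sd: float = 900.0
    accuracy: float = 0.982

    def validate(self) -> None:
        if self.sd <= 0 or self.between_sd < 0:
            raise ValueError("RT SDs must be positive")
        if not 0 <= self.accuracy <= 1:
            raise ValueError("accuracy must lie in [0, 1]")


@dataclass
class SimulationConfig:
    """Study-design and noise parameters of the synthetic cohort.

    The timing defaults encode the block/trial structure above; run length
    is ``n_blocks * (block_duration + rest_duration)``.  ``active_channels``
    maps 1-based channel numbers to ``(condition, amplitude)`` pairs, where
    the condition is a task name ('gesture', 'color'), a congruency
    ('incongruent', 'congruent'), or an exact condition column such as
    'gesture_incongruent'; amplitudes are uM-equivalent effect sizes.
    """

    n_subjects: int = 31
    seed: int = 0
    sample_period: float = 0.027
    n_blocks: int = 12
    block_duration: float = 15.0
    rest_duration: float = 15.0
    isi: float = 3.75
    trials_per_block: int = 4
    tasks: tuple = ("gesture", "color")
    active_channels: dict = field(default_factory=dict)
    systemic: dict = field(default_factory=lambda: {
        "cardiac": (0.4, 1.0),       # (amplitude uM-equiv, frequency Hz)
        "respiratory": (0.3, 0.25),
        "mayer": (0.3, 0.1),
    })
    drift_sd: float = 0.5            # amplitude of slow per-channel drift
    noise_sd: float = 1.0            # white-noise SD per sample, uM-equiv
    dead_channels: tuple = ()        # 1-based channel numbers
    hbr_to_hbo_ratio: float = -1.0 / 3.0
    hbr_noise_sd: float | None = None  # default: noise_sd * |ratio|
    coord_jitter_mm: float = 2.0     # per-subject probe placement scatter
    trial_duration: float = 1.5      # stimulus boxcar length, s
    rt_params: dict = field(default_factory=lambda: {
        "gesture": RTParams(mean=1365.0, sd=300.0, delta=40.0,
                            between_sd=900.0, accuracy=0.982),
        "color": RTParams(mean=658.0, sd=150.0, delta=106.0,
                          between_sd=800.0, accuracy=0.987),
    })

    def validate(self) -> None:
        if self.trials_per_block * self.isi > self.block_duration:
            raise ValueError(
                f"{self.trials_per_block} trials at ISI {self.isi}s do not "
                f"fit in a {self.block_duration}s block")
        if self.sample_period <= 0:
            raise ValueError("sample_period must be positive")
        for p in self.rt_params.values():
            p.validate()

    @property
    def run_length(self) -> float:
        return self.n_blocks * (self.block_duration + self.rest_duration)

    @property
    def n_samples(self) -> int:
        return int(round(self.run_length / self.sample_period))

    @property
    def trials_per_run(self) -> int:
        return self.n_blocks * self.trials_per_block

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sample_period


@dataclass
class EventSchedule:
    """Trial-level schedule of one run; ``trials`` is a tidy DataFrame with
    onset, task, congruency, is_oddball, block_index, block_dominance, and
    the gesture nuisance attributes (actor gender, gesture type)."""

    trials: pd.DataFrame
    task: str
    run_length: float

    def __len__(self) -> int:
        return len(self.trials)

    def validate(self, config: SimulationConfig) -> None:
        t = self.trials
        if len(t) != config.trials_per_run:
            raise AssertionError("wrong trial count")
        if t["onset"].min() < 0 or t["onset"].max() >= self.run_length:
            raise AssertionError("onsets outside run")
        for b, blk in t.groupby("block_index"):
            if int(blk["is_oddball"].sum()) != 1:
                raise AssertionError(f"block {b} has != 1 oddball")
            dom = blk["block_dominance"].iloc[0]
            dom_congr = dom.split("-")[0]
            odd = blk[blk["is_oddball"]]["congruency"].iloc[0]
            if odd == dom_congr:
                raise AssertionError("oddball congruency matches dominance")
            rest = blk[~blk["is_oddball"]]["congruency"]
            if not (rest == dom_congr).all():
                raise AssertionError("non-oddball trial off-dominance")
        doms = t.groupby("block_index")["block_dominance"].first()
        if (doms == "congruent-dominant").sum() != config.n_blocks // 2:
            raise AssertionError("dominance not balanced across blocks")


def _task_rng(config: SimulationConfig, task: str, subject: int = 0,
              stream: str = "events") -> np.random.Generator:
    """Deterministic per-(seed, subject, task, stream) generator."""
    import zlib
    key = [config.seed, subject,
           config.tasks.index(task) if task in config.tasks else 97,
           zlib.crc32(stream.encode())]
    return np.random.default_rng(np.random.SeedSequence(key))


def generate_event_schedule(
    config: SimulationConfig,
    task: str = "gesture",
    subject: int = 0,
    rng: np.random.Generator | None = None,
) -> EventSchedule:
    """Randomized block/trial schedule for one run of one task.

    Half the blocks are congruent-dominant and half incongruent-dominant
    (random order); each block holds one oddball of the opposite congruency
    at a uniformly random slot.  Gesture runs get randomized actor gender
    and gesture type per trial.
    """
    config.validate()
    rng = rng if rng is not None else _task_rng(config, task, subject)
    half = config.n_blocks // 2
    dominance = np.array(["congruent-dominant"] * half
                         + ["incongruent-dominant"] * (config.n_blocks - half))
    rng.shuffle(dominance)

    rows = []
    for b in range(config.n_blocks):
        block_start = b * (config.block_duration + config.rest_duration)
        dom_congr = dominance[b].split("-")[0]
        other = "incongruent" if dom_congr == "congruent" else "congruent"
        oddball_slot = int(rng.integers(config.trials_per_block))
        for slot in range(config.trials_per_block):
            is_odd = slot == oddball_slot
            congr = other if is_odd else dom_congr
            if task == "gesture":
                gesture = rng.choice(GESTURE_TYPES)
                actor = rng.choice(ACTOR_GENDERS)
            else:
                gesture, actor = "", ""
            rows.append({
                "onset": block_start + slot * config.isi,
                "task": task,
                "congruency": congr,
                "is_oddball": is_odd,
                "block_index": b,
                "block_dominance": dominance[b],
                "actor_gender": actor,
                "gesture_type": gesture,
            })
    schedule = EventSchedule(trials=pd.DataFrame(rows), task=task,
                             run_length=config.run_length)
    schedule.validate(config)
    return schedule


def _amplitude_vector(config: SimulationConfig, names: list[str],
                      n_channels: int) -> np.ndarray:
    """Per-channel, per-regressor truth amplitudes from ``active_channels``."""
    amps = np.zeros((n_channels, len(names)))
    for ch, spec in config.active_channels.items():
        specs = spec if isinstance(spec, (list, tuple)) and spec and \
            isinstance(spec[0], (list, tuple)) else [spec]
        for condition, amplitude in specs:
            for j, name in enumerate(names):
                if name == "constant":
                    continue
                task, congr = name.split("_")
                if condition in (name, task, congr):
                    amps[ch - 1, j] += amplitude
    return amps


def generate_hemo_truth(
    schedule: EventSchedule,
    config: SimulationConfig,
    n_channels: int = 98,
    subject: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[HemoTimeSeries, np.ndarray, glm.DesignMatrix]:
    """Forward-model the hemodynamic ground truth of one run.

    dHbO per channel is the HRF-convolved condition design times the truth
    amplitudes, plus shared systemic oscillations (near-unit channel
    gains), slow drift and white noise; dHbR mirrors the noiseless dHbO
    scaled by ``hbr_to_hbo_ratio`` plus independent noise.

    Returns (series, truth amplitudes (channels x regressors), design).
    """
    rng = rng if rng is not None else _task_rng(config, schedule.task,
                                                subject, "hemo")
    times = config.frame_times()
    design = glm.build_design(schedule.trials, times,
                              trial_duration=config.trial_duration)
    cond = [n for n in design.names if n != "constant"]
    Xc = np.column_stack([design.column(n) for n in cond])
    amps = _amplitude_vector(config, cond, n_channels)

    signal = amps @ Xc.T                                   # (C, T)

    # global systemic oscillations, shared with per-channel gains ~ N(1, 0.1)
    systemic = np.zeros_like(signal)
    for amp, freq in config.systemic.values():
        phase = rng.uniform(0, 2 * np.pi)
        course = amp * np.sin(2 * np.pi * freq * times + phase)
        gains = 1.0 + 0.1 * rng.standard_normal(n_channels)
        systemic += gains[:, None] * course[None, :]

    # slow drift: per-channel linear ramp plus a half-cycle sinusoid
    slopes = config.drift_sd * rng.standard_normal(n_channels)
    bends = config.drift_sd * rng.standard_normal(n_channels)
    tt = times / times[-1]
    drift = slopes[:, None] * (2 * tt - 1)[None, :] \
        + bends[:, None] * np.sin(np.pi * tt)[None, :]

    clean = signal + systemic + drift
    hbo = clean + config.noise_sd * rng.standard_normal(clean.shape)
    hbr_noise = (config.hbr_noise_sd if config.hbr_noise_sd is not None
                 else config.noise_sd * abs(config.hbr_to_hbo_ratio))
    hbr = config.hbr_to_hbo_ratio * clean \
        + hbr_noise * rng.standard_normal(clean.shape)
    series = HemoTimeSeries(hbo=hbo, hbr=hbr,
                            sample_period=config.sample_period)
    return series, amps, design


def generate_recording(
    hemo: HemoTimeSeries,
    config: SimulationConfig,
    ext: ExtinctionTable | None = None,
    rng: np.random.Generator | None = None,
    as_intensity: bool = True,
    baseline_intensity: float = 1.0,
) -> np.ndarray | OpticalDensityRecording:
    """Multi-wavelength raw recording via the Beer-Lambert forward model.

    Dead channels (``config.dead_channels``) are replaced by high-amplitude
    instrument noise so the RMS dead-channel rule has something to catch.
    Returns an intensity array (channels x wavelengths x times) by default,
    or the OD recording with ``as_intensity=False``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    od = forward_mbll(hemo, ext)
    for ch in config.dead_channels:
        scale = 30.0 * max(np.abs(od.od).mean(), 1e-3)
        od.od[ch - 1] = scale * rng.standard_normal(od.od.shape[1:])
    if not as_intensity:
        return od
    return baseline_intensity * 10.0 ** (-od.od)


def generate_rt_trials(
    schedule: EventSchedule,
    config: SimulationConfig,
    subject: int = 0,
    rng: np.random.Generator | None = None,
    subject_offset: float | None = None,
) -> pd.DataFrame:
    """Behavioral trials for one run: lognormal RTs with a congruency delta.

    Incongruent trials draw from a distribution whose mean exceeds the
    congruent mean by ``delta``; a per-subject offset (shared by both
    congruencies) models stable individual speed.  Correctness is Bernoulli
    at the task's accuracy.  Returns trial rows with subject, task,
    congruency, is_oddball, onset, rt_ms and correct.
    """
    params: RTParams = config.rt_params[schedule.task]
    params.validate()
    rng = rng if rng is not None else _task_rng(config, schedule.task,
                                                subject, "rt")
    if subject_offset is None:
        subject_offset = float(params.between_sd * rng.standard_normal())

    trials = schedule.trials
    incong = (trials["congruency"] == "incongruent").to_numpy()
    # lognormal parameterized to hit the requested mean and SD exactly
    means = np.maximum(params.mean + subject_offset
                       + params.delta * incong, 50.0)
    sigma2 = np.log1p(params.sd**2 / means**2)
    mu = np.log(means) - sigma2 / 2
    rts = rng.lognormal(mu, np.sqrt(sigma2))
    correct = rng.random(len(trials)) < params.accuracy
    return pd.DataFrame({
        "subject": f"sub-{subject + 1:02d}",
        "task": trials["task"].to_numpy(),
        "congruency": trials["congruency"].to_numpy(),
        "is_oddball": trials["is_oddball"].to_numpy(),
        "onset": trials["onset"].to_numpy(),
        "rt_ms": rts,
        "correct": correct,
    })


def default_active_channels(
    layout: ProbeLayout | None = None,
    amplitude: float = 1.0,
) -> dict:
    """Planted effects mirroring the study's reported activation loci.

    Five contiguous right-temporal channels (near MNI (70, -30, 10)) carry
    a gesture-task effect, two left-DLPFC channels (near (-54, 24, 28))
    carry a gesture effect, and two right-DLPFC channels (near (50, 25,
    40)) carry an incongruency effect.  Amplitudes are in units of the
    white-noise SD.
    """
    layout = layout if layout is not None else default_probe_layout()
    coords = layout.channel_coordinates()

    def nearest(target, k):
        d = np.linalg.norm(coords - np.asarray(target, float), axis=1)
        return (np.argsort(d)[:k] + 1).tolist()

    active: dict = {}
    for ch in nearest((70.0, -30.0, 10.0), 5):
        active[ch] = [("gesture", amplitude)]
    for ch in nearest((-54.0, 24.0, 28.0), 2):
        active.setdefault(ch, []).append(("gesture", amplitude))
    for ch in nearest((50.0, 25.0, 40.0), 2):
        active.setdefault(ch, []).append(("incongruent", amplitude))
    return active


@dataclass
class SubjectData:
    """Everything simulated for one subject."""

    subject: str
    layout: ProbeLayout                      # per-subject (jittered) montage
    schedules: dict                          # task -> EventSchedule
    hemo: dict                               # task -> HemoTimeSeries
    truth: dict                              # task -> (channels x regressors)
    designs: dict                            # task -> DesignMatrix
    intensity: dict                          # task -> (C, W, T) array
    behavior: pd.DataFrame                   # RT trials, both tasks


def simulate_subject(config: SimulationConfig, subject: int,
                     layout: ProbeLayout | None = None,
                     with_recording: bool = True) -> SubjectData:
    """Simulate all runs of one subject under the shared config."""
    config.validate()
    base = layout if layout is not None else default_probe_layout()
    jrng = _task_rng(config, config.tasks[0], subject, "coords")
    jitter = config.coord_jitter_mm
    sub_layout = ProbeLayout(
        emitters=base.emitters + jitter * jrng.standard_normal(base.emitters.shape),
        detectors=base.detectors + jitter * jrng.standard_normal(base.detectors.shape),
        channel_pairs=base.channel_pairs.copy(),
        fiducials={k: v + jitter * jrng.standard_normal(3)
                   for k, v in base.fiducials.items()},
    )

    schedules, hemo, truth, designs, intensity = {}, {}, {}, {}, {}
    behavior = []
    for task in config.tasks:
        sched = generate_event_schedule(config, task, subject)
        series, amps, design = generate_hemo_truth(
            sched, config, n_channels=base.n_channels, subject=subject)
        schedules[task] = sched
        hemo[task] = series
        truth[task] = amps
        designs[task] = design
        if with_recording:
            intensity[task] = generate_recording(
                series, config, rng=_task_rng(config, task, subject, "dead"))
        behavior.append(generate_rt_trials(sched, config, subject))
    return SubjectData(
        subject=f"sub-{subject + 1:02d}",
        layout=sub_layout,
        schedules=schedules,
        hemo=hemo,
        truth=truth,
        designs=designs,
        intensity=intensity,
        behavior=pd.concat(behavior, ignore_index=True),
    )


def simulate_cohort(config: SimulationConfig,
                    layout: ProbeLayout | None = None,
                    with_recording: bool = True) -> list[SubjectData]:
    """Simulate the full cohort (``config.n_subjects`` subjects)."""
    layout = layout if layout is not None else default_probe_layout()
    return [simulate_subject(config, s, layout, with_recording)
            for s in range(config.n_subjects)]
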