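"""Synthetic two-condition OPM sessions with a known deep theta source.

The generator emulates the study conditions of a wearable OPM experiment:
~21 scalp magnetometers plus a 4-sensor reference array behind the head,
1200 Hz sampling, 3 s epochs in two conditions ("scene" imagery vs "counting"
baseline), and a band-limited 4-8 Hz source at hippocampal depth whose
amplitude is LOWER during scene trials.  Environmental interference is
spatially structured as a time-varying uniform field plus a linear gradient,
seen coherently by the scalp and reference arrays, on top of white sensor
noise.  Three virtual participants differ by small geometry jitter and by
their random streams; everything is reproducible from (config, seed).

Trial accounting mirrors the experimental bookkeeping: per condition a number
of completed trials, of which only self-rated-successful ones survive, minus
artefact removals; trial numbers are then equated across conditions by a
seeded uniform subsample of the larger condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .geometry import (
    SensorArray,
    SphereHeadModel,
    make_reference_array,
    make_scalp_array,
)
from .forward import dipole_field_sphere, tangential_basis

SCENE = "scene"
COUNTING = "counting"
CONDITIONS = (SCENE, COUNTING)

#: Basis for the 3 simulated gradient degrees of freedom: a symmetric traceless
#: diagonal component (dBx/dx = -dBy/dy) and two shear components, mirroring a
#: reference array that reports three field components and three gradients.
GRADIENT_BASIS = np.array(
    [
        [[1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, 0.0]],
        [[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]],
        [[0.0, 0.0, 1.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0]],
    ]
)


@dataclass(frozen=True)
class ConditionCounts:
    """Trial bookkeeping for one condition of one participant."""

    completed: int
    successful: int
    artefact_removed: int = 0

    def __post_init__(self):
        if not (0 <= self.artefact_removed <= self.successful <= self.completed):
            raise ValueError(
                "require 0 <= artefact_removed <= successful <= completed"
            )

    @property
    def usable(self) -> int:
        return self.successful - self.artefact_removed


@dataclass(frozen=True)
class TrialCounts:
    scene: ConditionCounts
    counting: ConditionCounts

    def usable(self) -> dict[str, int]:
        return {SCENE: self.scene.usable, COUNTING: self.counting.usable}


def default_trial_counts() -> tuple[TrialCounts, ...]:
    """Per-participant wearable-session trial counts used as study defaults."""
    return (
        TrialCounts(ConditionCounts(45, 35, 0), ConditionCounts(45, 45, 0)),
        TrialCounts(ConditionCounts(75, 68, 7), ConditionCounts(75, 75, 6)),
        TrialCounts(ConditionCounts(48, 45, 0), ConditionCounts(48, 48, 0)),
    )


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic OPM session generator.

    Amplitudes: ``counting_source_sd`` is the dipole-moment standard deviation
    (A m) of the theta source during counting trials; scene trials are scaled
    by ``scene_counting_ratio`` (< 1: theta decreases during scene imagery).
    Interference SDs are per component (tesla for the uniform field, tesla/m
    for the gradient); ``sensor_noise_sd`` is the white per-sample noise SD.
    """

    sample_rate: float = 1200.0
    epoch_duration: float = 3.0
    head_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    head_radius: float = 0.09
    n_scalp: int = 21
    scalp_standoff: float = 0.0065
    n_ref: int = 4
    ref_offset: float = 0.10
    source_position: tuple[float, float, float] = (0.036, -0.008, -0.016)
    source_band: tuple[float, float] = (4.0, 8.0)
    counting_source_sd: float = 30e-9
    scene_counting_ratio: float = 0.7
    uniform_field_sd: float = 100e-12
    gradient_sd: float = 20e-12
    interference_corner_hz: float = 1.0
    sensor_noise_sd: float = 2.45e-13
    n_participants: int = 3
    geometry_jitter: float = 0.001
    trial_counts: tuple[TrialCounts, ...] = field(default_factory=default_trial_counts)
    n_trials: int | None = None
    dynamic_range: float = 1.5e-9  # hardware clipping check only, not modelled

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        low, high = self.source_band
        nyq = self.sample_rate / 2.0
        if not (0.0 < low < high < nyq):
            raise ValueError("source band must satisfy 0 < low < high < sample_rate/2")
        if not (0.0 < self.scene_counting_ratio < 1.0):
            raise ValueError(
                "scene/counting amplitude ratio must be in (0, 1): "
                "the scene condition shows a theta power decrease"
            )
        for name in ("counting_source_sd", "uniform_field_sd", "gradient_sd",
                     "sensor_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.geometry_jitter < 0:
            raise ValueError("geometry_jitter must be non-negative")
        if self.n_trials is None and self.n_participants > len(self.trial_counts):
            raise ValueError("need trial counts for every participant")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_duration * self.sample_rate))

    @property
    def scene_source_sd(self) -> float:
        return self.counting_source_sd * self.scene_counting_ratio

    def source_sd(self, condition: str) -> float:
        if condition == SCENE:
            return self.scene_source_sd
        if condition == COUNTING:
            return self.counting_source_sd
        raise ValueError(f"unknown condition {condition!r}")

    def head_model(self) -> SphereHeadModel:
        return SphereHeadModel(self.head_center, self.head_radius)

    def usable_counts(self, participant_index: int) -> dict[str, int]:
        if self.n_trials is not None:
            return {SCENE: self.n_trials, COUNTING: self.n_trials}
        return self.trial_counts[participant_index].usable()


@dataclass
class EpochedData:
    """Trials x channels x samples tensor with labels and channel metadata."""

    data: np.ndarray          # (n_trials, n_channels, n_samples) tesla
    labels: np.ndarray        # (n_trials,) "scene" | "counting"
    sfreq: float
    sensors: SensorArray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("epoch tensor must be (trials, channels, samples)")
        if self.data.shape[0] != self.labels.shape[0]:
            raise ValueError("one condition label per trial required")
        if self.data.shape[1] != self.sensors.n_channels:
            raise ValueError("channel count must match the sensor array")
        bad = set(self.labels) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Epoch time axis in seconds (0 to epoch duration)."""
        return np.arange(self.n_samples) / self.sfreq

    def channel_indices(self, role: str) -> np.ndarray:
        return np.flatnonzero(self.sensors.roles == role)

    def pick(self, role: str) -> "EpochedData":
        idx = self.channel_indices(role)
        return EpochedData(self.data[:, idx], self.labels, self.sfreq,
                          self.sensors.select(role))

    def subset_trials(self, trial_idx) -> "EpochedData":
        trial_idx = np.asarray(trial_idx, dtype=int)
        return EpochedData(self.data[trial_idx], self.labels[trial_idx],
                          self.sfreq, self.sensors)

    def condition_trials(self, condition: str) -> np.ndarray:
        return np.flatnonzero(self.labels == condition)

    def with_data(self, data: np.ndarray) -> "EpochedData":
        return EpochedData(data, self.labels, self.sfreq, self.sensors)


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    source_position: np.ndarray        # (3,) m, after participant jitter
    source_orientation: np.ndarray     # (3,) unit tangential vector
    gains: np.ndarray                  # (n_scalp,) sensor gain of a unit dipole
    condition_power: dict[str, float]  # moment variance per condition, (A m)^2
    source_traces: np.ndarray          # (n_trials, n_samples) A m
    interference_components: np.ndarray  # (n_trials, 6, n_samples)
    mixing: np.ndarray                 # (n_channels, 6) channel <- components
    labels: np.ndarray                 # (n_trials,)
    scalp_array: SensorArray
    head: SphereHeadModel

    def interference_traces(self, trial_idx=None) -> np.ndarray:
        """Per-channel interference (trials, channels, samples) from components."""
        comps = self.interference_components
        if trial_idx is not None:
            comps = comps[np.asarray(trial_idx, dtype=int)]
        return np.einsum("cf,tfs->tcs", self.mixing, comps)

    def subset_trials(self, trial_idx) -> "GroundTruth":
        trial_idx = np.asarray(trial_idx, dtype=int)
        return replace(
            self,
            source_traces=self.source_traces[trial_idx],
            interference_components=self.interference_components[trial_idx],
            labels=self.labels[trial_idx],
        )


# --------------------------------------------------------------------------
# elementary generators
# --------------------------------------------------------------------------

def _band_sos(band, sample_rate, order=5):
    return signal.butter(order, band, btype="bandpass", fs=sample_rate, output="sos")


def simulate_source_timecourse(
    condition: str, cfg: SimulationConfig, rng: np.random.Generator,
    n_trials: int = 1,
) -> np.ndarray:
    """Band-limited Gaussian source moment traces, exactly rescaled per trial.

    White noise is zero-phase filtered to the source band and each trial trace
    is rescaled so its sample SD equals the condition's source SD exactly.
    Returns (n_trials, n_samples); a single trace when ``n_trials`` is 1.
    """
    sd = cfg.source_sd(condition)
    n = cfg.n_samples
    white = rng.standard_normal((n_trials, n))
    sos = _band_sos(cfg.source_band, cfg.sample_rate)
    traces = signal.sosfiltfilt(sos, white, axis=-1)
    traces = traces - traces.mean(axis=-1, keepdims=True)
    std = traces.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    traces = traces * (sd / std)
    return traces[0] if n_trials == 1 else traces


def interference_mixing(
    scalp: SensorArray, reference: SensorArray, head: SphereHeadModel
) -> np.ndarray:
    """(n_channels, 6) matrix mapping interference components to channels.

    Columns 0-2 are the uniform-field components; columns 3-5 the gradient
    components, whose channel contribution is orientation . (G_k (p - c)).
    """
    sensors = SensorArray.concat(scalp, reference)
    rel = sensors.positions - head.center_arr
    M = np.empty((sensors.n_channels, 6))
    M[:, :3] = sensors.orientations
    for k, G in enumerate(GRADIENT_BASIS):
        M[:, 3 + k] = np.sum(sensors.orientations * (rel @ G.T), axis=1)
    return M


def simulate_interference(
    scalp: SensorArray,
    reference: SensorArray,
    cfg: SimulationConfig,
    n_samples: int,
    rng: np.random.Generator,
    n_trials: int = 1,
):
    """Structured environmental interference on both arrays.

    Draws a time-varying uniform field vector u(t) and a 3-component linear
    gradient g(t) as low-pass Gaussian processes (2nd-order Butterworth at the
    interference corner frequency, zero phase, each component standardised and
    scaled to its SD), then projects them onto every channel.  Returns
    ``(traces, components, mixing)`` where ``traces`` is
    (n_trials, n_channels, n_samples) and ``components`` (n_trials, 6,
    n_samples); singleton trial axes are squeezed when ``n_trials`` is 1.
    """
    M = interference_mixing(scalp, reference, cfg.head_model())
    white = rng.standard_normal((n_trials, 6, n_samples))
    corner = cfg.interference_corner_hz
    sos = signal.butter(2, corner, btype="lowpass", fs=cfg.sample_rate, output="sos")
    comps = signal.sosfiltfilt(sos, white, axis=-1)
    comps = comps - comps.mean(axis=-1, keepdims=True)
    std = comps.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    comps = comps / std
    scale = np.array([cfg.uniform_field_sd] * 3 + [cfg.gradient_sd] * 3)
    comps = comps * scale[None, :, None]
    traces = np.einsum("cf,tfs->tcs", M, comps)
    if n_trials == 1:
        return traces[0], comps[0], M
    return traces, comps, M


# --------------------------------------------------------------------------
# session assembly
# --------------------------------------------------------------------------

def _participant_streams(seed: int, participant_index: int):
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(participant_index),))
    children = ss.spawn(5)
    names = ("geometry", "source", "interference", "noise", "order")
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def simulate_session(
    cfg: SimulationConfig, participant_index: int, seed: int
) -> tuple[EpochedData, GroundTruth]:
    """One participant's epoched two-condition session plus its ground truth.

    Scalp channels carry lead-field-projected source activity plus structured
    interference plus white noise; reference channels carry interference plus
    noise only (the brain field at ~19 cm is negligible and not simulated).
    Fully reproducible from (cfg, participant_index, seed).
    """
    cfg.validate()
    streams = _participant_streams(seed, participant_index)
    head = cfg.head_model()

    # the base array is shared by all participants (one scanner-cast design);
    # participants differ only through jitter and their random streams
    geom_rng = streams["geometry"]
    scalp = make_scalp_array(cfg.n_scalp, head, seed=int(seed) % 2**31,
                             standoff=cfg.scalp_standoff)
    reference = make_reference_array(head, offset_m=cfg.ref_offset, n_ref=cfg.n_ref)

    # per-participant geometry jitter on the scalp sensors and the source,
    # emulating registration error across participants on the shared grid
    if cfg.geometry_jitter > 0:
        jitter = geom_rng.normal(0.0, cfg.geometry_jitter, size=scalp.positions.shape)
        positions = scalp.positions + jitter
        # keep sensors strictly outside the conductor
        rel = positions - head.center_arr
        dist = np.linalg.norm(rel, axis=1, keepdims=True)
        min_dist = head.radius + 1e-3
        scale = np.maximum(dist, min_dist) / dist
        positions = head.center_arr + rel * scale
        scalp = SensorArray(scalp.names, positions, scalp.orientations, scalp.roles)
        source_pos = np.asarray(cfg.source_position) + geom_rng.normal(
            0.0, cfg.geometry_jitter, size=3
        )
    else:
        geom_rng.normal(size=scalp.positions.shape)  # keep stream alignment
        source_pos = np.asarray(cfg.source_position, dtype=float)
        geom_rng.normal(size=3)

    # fixed tangential source orientation for this participant
    basis = tangential_basis((source_pos - head.center_arr)[None, :])[0]
    angle = geom_rng.uniform(0.0, 2.0 * np.pi)
    orientation = np.cos(angle) * basis[0] + np.sin(angle) * basis[1]

    field = dipole_field_sphere(source_pos, orientation, scalp.positions, head)
    gains = np.sum(field * scalp.orientations, axis=1)   # tesla per (A m)

    usable = cfg.usable_counts(participant_index)
    n_scene, n_counting = usable[SCENE], usable[COUNTING]
    n_trials = n_scene + n_counting
    n_samples = cfg.n_samples

    labels = np.array([SCENE] * n_scene + [COUNTING] * n_counting, dtype=object)
    traces = np.empty((n_trials, n_samples))
    src_rng = streams["source"]
    if n_scene:
        traces[:n_scene] = simulate_source_timecourse(SCENE, cfg, src_rng, n_scene)
    if n_counting:
        traces[n_scene:] = simulate_source_timecourse(COUNTING, cfg, src_rng, n_counting)

    _, comps, M = simulate_interference(
        scalp, reference, cfg, n_samples, streams["interference"], n_trials
    )
    if n_trials == 1:
        comps = comps[None]

    sensors = SensorArray.concat(scalp, reference)
    data = np.einsum("cf,tfs->tcs", M, comps)
    data[:, : scalp.n_channels] += gains[None, :, None] * traces[:, None, :]
    data += streams["noise"].standard_normal(data.shape) * cfg.sensor_noise_sd

    order = streams["order"].permutation(n_trials)
    data, labels = data[order], labels[order]
    traces, comps = traces[order], comps[order]

    epochs = EpochedData(data, labels, cfg.sample_rate, sensors)
    condition_power = {
        cond: float(np.mean(traces[labels == cond].var(axis=-1)))
        if np.any(labels == cond) else 0.0
        for cond in CONDITIONS
    }
    truth = GroundTruth(
        source_position=source_pos,
        source_orientation=orientation,
        gains=gains,
        condition_power=condition_power,
        source_traces=traces,
        interference_components=comps,
        mixing=M,
        labels=labels,
        scalp_array=scalp,
        head=head,
    )
    return epochs, truth


def clipping_fraction(epochs: EpochedData, dynamic_range: float = 1.5e-9) -> float:
    """Fraction of samples outside the hardware dynamic range (should be 0)."""
    return float(np.mean(np.abs(epochs.data) > dynamic_range))


# --------------------------------------------------------------------------
# trial accounting
# --------------------------------------------------------------------------

def select_analysable_trials(
    counts: TrialCounts, seed: int
) -> tuple[int, dict[str, np.ndarray]]:
    """Equate analysable trial numbers across conditions.

    Usable trials per condition are successful minus artefact-removed; the
    analysed count n is the minimum across conditions, and the larger
    condition is reduced to n by a seeded uniform random subsample.  Returns
    ``(n, indices)`` with per-condition indices into that condition's usable
    trials (sorted, 0-based).
    """
    usable = counts.usable()
    if min(usable.values()) == 0:
        raise ValueError("a condition has no usable trials")
    n = min(usable.values())
    rng = np.random.default_rng(seed)
    indices = {}
    for cond in CONDITIONS:
        m = usable[cond]
        if m == n:
            indices[cond] = np.arange(n)
        else:
            indices[cond] = np.sort(rng.choice(m, size=n, replace=False))
    return n, indices


def apply_trial_selection(
    epochs: EpochedData, indices: dict[str, np.ndarray]
) -> np.ndarray:
    """Translate per-condition usable-trial indices into epoch trial indices.

    Within each condition, usable trial k is the k-th trial carrying that
    label in epoch order.  Returns sorted epoch-level indices of retained
    trials.
    """
    keep = []
    for cond, idx in indices.items():
        cond_trials = epochs.condition_trials(cond)
        keep.append(cond_trials[np.asarray(idx, dtype=int)])
    return np.sort(np.concatenate(keep))
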