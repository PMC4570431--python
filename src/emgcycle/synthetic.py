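"""Protocol-driven synthetic data: metabolic trajectories and cyclostationary sEMG.

The generator emulates a constant-cadence cycle-ergometer test in three
constant-load phases (moderate / severe / moderate, expressed as fractions
of the power at VO2max).  Blood lactate follows a linear
accumulation-clearance ODE around a threshold load,

    dL/dt = a * max(0, load - threshold) - c * L,   L(0) = baseline,

which is the simplest mechanism producing the characteristic rise during
the severe phase and washout during recovery.  Oxygen uptake follows a
first-order lag toward a load-proportional setpoint.  Both are observed on
sparse grids (lactate every 60 s, VO2 every 10 s) with truncated Gaussian
noise, matching how these quantities are measured in practice.

The sEMG model places one activity burst per pedal revolution per channel
(cyclic stationarity: each segment repeats the same within-cycle activity
pattern).  A burst is band-limited coloured Gaussian noise (20-400 Hz)
under a Hann envelope, with amplitude driven by a latent exertion
trajectory (load plus a lactate-coupled fatigue term) and an optional
"tail mass" knob that moves spectral power into a high band — useful for
planting recoverable signal in the upper percentiles of the power
distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .physio_io import ChannelLabel, EMGRecording, PhysioSeries

DEFAULT_PHASES = ((360.0, 0.60), (480.0, 0.925), (360.0, 0.60))


@dataclass(frozen=True)
class ProtocolSpec:
    """Constant-cadence, piecewise-constant-load test protocol.

    ``phases`` is a sequence of (duration_s, load_frac) pairs where
    load_frac is the fraction of the power at VO2max.  The default is the
    three-phase template: 6 min at 60%, severe phase at ~92.5%, 6 min at
    60%.
    """

    phases: tuple[tuple[float, float], ...] = DEFAULT_PHASES
    cadence_rpm: float = 90.0
    sampling_rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("protocol needs at least one phase")
        for dur, load in self.phases:
            if dur <= 0:
                raise ValueError("phase durations must be positive")
            if not 0 < load <= 1.2:
                raise ValueError("load_frac must be in (0, 1.2]")
        if self.cadence_rpm <= 0:
            raise ValueError("cadence_rpm must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return float(sum(d for d, _ in self.phases))

    @property
    def cycle_s(self) -> float:
        """Duration of one pedal revolution in seconds."""
        return 60.0 / self.cadence_rpm

    def load_at(self, times_s: np.ndarray) -> np.ndarray:
        """Piecewise-constant load fraction at the given times."""
        t = np.asarray(times_s, dtype=float)
        edges = np.cumsum([d for d, _ in self.phases])
        idx = np.searchsorted(edges, t, side="right")
        idx = np.minimum(idx, len(self.phases) - 1)
        loads = np.array([l for _, l in self.phases])
        return loads[idx]


@dataclass(frozen=True)
class MetabolicParams:
    """Rate constants of the lactate/VO2 generator.

    - ``lactate_threshold``: load fraction above which lactate accumulates.
    - ``accumulation_rate``: mmol/L per second per unit of excess load.
    - ``clearance_rate``: 1/s first-order washout.
    - ``vo2_tau_s``: time constant of the VO2 lag toward its setpoint.
    - ``vo2_rest`` / ``vo2_max``: L/min at rest and at 100% load.
    """

    lactate_baseline: float = 1.0
    lactate_threshold: float = 0.75
    accumulation_rate: float = 0.13
    clearance_rate: float = 0.002
    lactate_noise_sd: float = 0.25
    vo2_rest: float = 0.5
    vo2_max: float = 3.5
    vo2_tau_s: float = 30.0
    vo2_noise_sd: float = 0.06
    lactate_grid_s: float = 60.0
    vo2_grid_s: float = 10.0

    def __post_init__(self) -> None:
        if self.accumulation_rate <= 0 or self.vo2_tau_s <= 0:
            raise ValueError("rate constants must be positive")
        if self.clearance_rate < 0:
            raise ValueError("clearance_rate must be non-negative")


@dataclass
class GroundTruth:
    """Latent state of a synthetic run, kept for oracle-style testing.

    ``exertion`` is the dimensionless drive of EMG amplitude: instantaneous
    load plus a fatigue term proportional to accumulated lactate.
    """

    times_s: np.ndarray
    lactate_dense: np.ndarray
    vo2_dense: np.ndarray
    exertion: np.ndarray
    lactate: PhysioSeries = None
    vo2: PhysioSeries = None
    burst_onsets_s: dict[str, np.ndarray] = field(default_factory=dict)

    def exertion_at(self, times_s: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(times_s, float), self.times_s, self.exertion)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "times_s": self.times_s.tolist(),
            "lactate_dense": self.lactate_dense.tolist(),
            "vo2_dense": self.vo2_dense.tolist(),
            "exertion": self.exertion.tolist(),
            "burst_onsets_s": {k: v.tolist() for k, v in self.burst_onsets_s.items()},
        }
        Path(path).write_text(json.dumps(payload))


def simulate_metabolics(
    protocol: ProtocolSpec,
    params: MetabolicParams = MetabolicParams(),
    seed: int = 0,
    fatigue_gain: float = 0.5,
) -> GroundTruth:
    """Integrate the lactate and VO2 dynamics over the protocol.

    Both ODEs are linear with piecewise-constant input, so each 1-s step is
    advanced with the exact exponential update (no integrator error beyond
    the 1-s discretisation of phase boundaries).  Observation noise is
    additive Gaussian truncated at zero, applied only to the sparse
    sampled series, never to the dense ground-truth curves.
    """
    rng = np.random.default_rng(seed)
    h = 1.0
    t = np.arange(0.0, protocol.duration_s + h / 2, h)
    load = protocol.load_at(t)

    a, c, thr = params.accumulation_rate, params.clearance_rate, params.lactate_threshold
    lact = np.empty_like(t)
    lact[0] = params.lactate_baseline
    for i in range(1, len(t)):
        u = a * max(0.0, load[i - 1] - thr)
        if c > 0:
            decay = np.exp(-c * h)
            lact[i] = lact[i - 1] * decay + (u / c) * (1.0 - decay)
        else:
            lact[i] = lact[i - 1] + u * h
    lact = np.maximum(lact, 0.0)

    setpoint = params.vo2_rest + (params.vo2_max - params.vo2_rest) * load
    vo2 = np.empty_like(t)
    vo2[0] = params.vo2_rest
    decay = np.exp(-h / params.vo2_tau_s)
    for i in range(1, len(t)):
        vo2[i] = vo2[i - 1] * decay + setpoint[i - 1] * (1.0 - decay)
    vo2 = np.maximum(vo2, 0.0)

    exertion = load + fatigue_gain * np.maximum(0.0, lact - params.lactate_baseline) / 10.0

    t_lac = np.arange(0.0, protocol.duration_s + 1e-9, params.lactate_grid_s)
    t_vo2 = np.arange(0.0, protocol.duration_s + 1e-9, params.vo2_grid_s)
    lac_obs = np.interp(t_lac, t, lact) + rng.normal(0.0, params.lactate_noise_sd, len(t_lac))
    vo2_obs = np.interp(t_vo2, t, vo2) + rng.normal(0.0, params.vo2_noise_sd, len(t_vo2))
    lac_obs = np.maximum(lac_obs, 0.0)
    vo2_obs = np.maximum(vo2_obs, 0.0)

    return GroundTruth(
        times_s=t,
        lactate_dense=lact,
        vo2_dense=vo2,
        exertion=exertion,
        lactate=PhysioSeries(t_lac, lac_obs, kind="lactate"),
        vo2=PhysioSeries(t_vo2, vo2_obs, kind="vo2"),
    )


@dataclass(frozen=True)
class SpectralParams:
    """Shape of the per-revolution EMG burst.

    - ``burst_frac``: burst duration as a fraction of the pedal cycle
      (about a third of a revolution of active extensor/flexor drive).
    - ``amplitude_per_exertion``: mV of burst RMS per unit exertion.
    - ``low_band_hz`` / ``high_band_hz``: pass bands of the two coloured
      noise components mixed into a burst.
    - ``tail_mass``: fraction of burst power placed in the high band.
    - ``tail_drift``: added to tail_mass per unit exertion above 0.6 —
      the knob that plants signal in the upper spectral percentiles.
    - ``tail_jitter_sd``: per-burst random wobble of the tail mass.
    - ``noise_level``: baseline (inter-burst) Gaussian noise SD in mV.
    - ``onset_jitter_ms``: uniform jitter of burst onsets around the
      cadence grid, at most +/-10 ms.
    - ``lead_in_s``: recording time before the first pedal stroke (the
      recorder is started before the rider begins pedalling).
    """

    burst_frac: float = 1.0 / 3.0
    amplitude_per_exertion: float = 0.5
    low_band_hz: tuple[float, float] = (20.0, 250.0)
    high_band_hz: tuple[float, float] = (250.0, 400.0)
    tail_mass: float = 0.15
    tail_drift: float = 0.0
    tail_jitter_sd: float = 0.03
    noise_level: float = 0.02
    onset_jitter_ms: float = 5.0
    lead_in_s: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.burst_frac < 1:
            raise ValueError("burst_frac must be in (0, 1): burst shorter than the cycle")
        if self.onset_jitter_ms > 10.0:
            raise ValueError("onset jitter must stay within +/-10 ms of the cadence grid")
        if not 0 <= self.tail_mass <= 1:
            raise ValueError("tail_mass is a power fraction in [0, 1]")


DEFAULT_CHANNELS = tuple(
    ChannelLabel(m, s) for m in ("VL", "RF", "BF", "ST") for s in ("left", "right")
)

# Within-cycle activation phase of each muscle group, as a fraction of the
# pedal revolution (extensors fire on the downstroke, flexors later).
_MUSCLE_PHASE = {"VL": 0.00, "RF": 0.05, "BF": 0.45, "ST": 0.50}


def _bandpass_noise(rng: np.random.Generator, n: int, band: tuple[float, float], fs: float) -> np.ndarray:
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    # pad so the filter transient does not colour the start of the burst
    pad = int(fs * 0.05)
    x = sps.sosfilt(sos, rng.standard_normal(n + pad))[pad:]
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def simulate_emg(
    protocol: ProtocolSpec,
    truth: GroundTruth,
    channels: tuple[ChannelLabel, ...] = DEFAULT_CHANNELS,
    spectral: SpectralParams = SpectralParams(),
    seed: int = 0,
) -> EMGRecording:
    """Synthesize one EMG burst per pedal revolution per channel.

    All randomness is drawn from a single generator seeded with ``seed``;
    identical inputs give bit-identical recordings.  Detected-onset ground
    truth (the jittered onset time of every burst) is stored per channel in
    ``truth.burst_onsets_s``.
    """
    fs = protocol.sampling_rate_hz
    n_total = int(round(protocol.duration_s * fs))
    cycle = protocol.cycle_s
    n_burst = int(round(spectral.burst_frac * cycle * fs))
    if n_burst >= int(cycle * fs):
        raise ValueError("burst duration must be shorter than the pedal cycle")

    rng = np.random.default_rng(seed)
    # Tapered-rectangular envelope: muscle activation rises and falls over
    # ~25 ms, fast enough that the envelope start is a meaningful onset.
    env = sps.windows.tukey(n_burst, alpha=0.25)
    out = np.zeros((len(channels), n_total))

    for ch_i, lab in enumerate(channels):
        if spectral.noise_level > 0:
            out[ch_i] = rng.normal(0.0, spectral.noise_level, n_total)
        phase = _MUSCLE_PHASE.get(lab.muscle, 0.0) * cycle
        onsets = []
        k = 0
        while True:
            t0 = spectral.lead_in_s + phase + k * cycle
            if spectral.onset_jitter_ms > 0:
                t0 = t0 + rng.uniform(-1e-3 * spectral.onset_jitter_ms, 1e-3 * spectral.onset_jitter_ms)
            t0 = max(t0, 0.0)
            i0 = int(round(t0 * fs))
            if i0 + n_burst > n_total:
                break
            exertion = float(truth.exertion_at(t0 + 0.5 * n_burst / fs))
            amp = spectral.amplitude_per_exertion * exertion
            w = spectral.tail_mass + spectral.tail_drift * (exertion - 0.6)
            if spectral.tail_jitter_sd > 0:
                w = w + rng.normal(0.0, spectral.tail_jitter_sd)
            w = float(np.clip(w, 0.0, 0.95))
            low = _bandpass_noise(rng, n_burst, spectral.low_band_hz, fs)
            high = _bandpass_noise(rng, n_burst, spectral.high_band_hz, fs)
            burst = np.sqrt(1.0 - w) * low + np.sqrt(w) * high
            out[ch_i, i0 : i0 + n_burst] += amp * env * burst
            onsets.append(i0 / fs)
            k += 1
        truth.burst_onsets_s[str(lab)] = np.asarray(onsets)

    return EMGRecording(out, sampling_rate_hz=fs, channel_labels=list(channels))


def simulate_dataset(
    protocol: ProtocolSpec = ProtocolSpec(),
    metabolic: MetabolicParams = MetabolicParams(),
    spectral: SpectralParams = SpectralParams(),
    channels: tuple[ChannelLabel, ...] = DEFAULT_CHANNELS,
    seed: int = 0,
) -> tuple[EMGRecording, GroundTruth]:
    """One full synthetic session: metabolics then the coupled EMG."""
    truth = simulate_metabolics(protocol, metabolic, seed=seed)
    rec = simulate_emg(protocol, truth, channels=channels, spectral=spectral, seed=seed + 1)
    return rec, truth


def params_from_config(cfg: dict) -> tuple[ProtocolSpec, MetabolicParams, SpectralParams]:
    """Build parameter objects from the nested config dict (YAML blocks)."""
    proto_cfg = dict(cfg.get("protocol", {}))
    if "phases" in proto_cfg:
        proto_cfg["phases"] = tuple((float(d), float(l)) for d, l in proto_cfg["phases"])
    protocol = ProtocolSpec(**proto_cfg)
    metabolic = MetabolicParams(**cfg.get("metabolic", {}))
    spec_cfg = dict(cfg.get("spectral", {}))
    for key in ("low_band_hz", "high_band_hz"):
        if key in spec_cfg:
            spec_cfg[key] = tuple(float(v) for v in spec_cfg[key])
    spectral = SpectralParams(**spec_cfg)
    return protocol, metabolic, spectral
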