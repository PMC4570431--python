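"""Containers and I/O for sEMG recordings and sparse physiological series.

Surface EMG is stored as a multichannel array with a fixed sampling rate;
physiological measurements (blood lactate, oxygen uptake) are sparse,
irregularly usable time series that must be interpolated to the timestamps
of EMG segments before modelling.  Interpolation uses cubic Hermite splines
with Catmull-Rom tangents, which reproduce linear trends exactly and are C1
at the knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicHermiteSpline

KNOWN_MUSCLES = ("VL", "RF", "BF", "ST")
KNOWN_SIDES = ("left", "right")


@dataclass(frozen=True)
class ChannelLabel:
    """Electrode placement: muscle abbreviation and body side.

    Muscles follow the usual cycling montage: vastus lateralis (VL),
    rectus femoris (RF), biceps femoris (BF) and semitendinosus (ST).
    """

    muscle: str
    side: str

    def __post_init__(self) -> None:
        if self.muscle not in KNOWN_MUSCLES:
            raise ValueError(f"unknown muscle {self.muscle!r}; expected one of {KNOWN_MUSCLES}")
        if self.side not in KNOWN_SIDES:
            raise ValueError(f"unknown side {self.side!r}; expected one of {KNOWN_SIDES}")

    def __str__(self) -> str:
        return f"{self.muscle}_{self.side}"

    @classmethod
    def parse(cls, text: str) -> "ChannelLabel":
        muscle, _, side = text.partition("_")
        return cls(muscle, side)


@dataclass
class EMGRecording:
    """Multichannel sEMG signal with a common sampling rate.

    ``samples`` has shape (n_channels, n_samples); amplitudes are in the
    recorder's native units (typically mV).
    """

    samples: np.ndarray
    sampling_rate_hz: float
    channel_labels: list[ChannelLabel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.channel_labels and len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels length must match number of channels")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def channel(self, label: ChannelLabel | str) -> np.ndarray:
        key = str(label)
        for i, lab in enumerate(self.channel_labels):
            if str(lab) == key:
                return self.samples[i]
        raise KeyError(f"no channel {key!r}")


@dataclass
class PhysioSeries:
    """Sparse physiological time series (lactate in mmol/L or VO2 volume rate)."""

    times_s: np.ndarray
    values: np.ndarray
    kind: str = "lactate"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("lactate", "vo2"):
            raise ValueError("kind must be 'lactate' or 'vo2'")
        if self.times_s.shape != self.values.shape or self.times_s.ndim != 1:
            raise ValueError("times_s and values must be 1-D arrays of equal length")
        if len(self.times_s) >= 2 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times_s must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_s)


def write_emg(rec: EMGRecording, path: str | Path) -> None:
    """Write a recording as CSV: time column plus one column per channel."""
    t = np.arange(rec.n_samples) / rec.sampling_rate_hz
    columns = {"time_s": t}
    for lab, sig in zip(rec.channel_labels, rec.samples):
        columns[str(lab)] = sig
    pd.DataFrame(columns).to_csv(path, index=False, float_format="%.17g")


def read_emg(path: str | Path) -> EMGRecording:
    """Read a recording from CSV written by :func:`write_emg`.

    The sampling rate is recovered from the time column, which must be a
    uniform, strictly increasing grid.  Any NaN sample is rejected.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ValueError("EMG CSV must contain a 'time_s' column")
    if df.isna().any().any():
        raise ValueError("EMG CSV contains missing values")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("EMG CSV must contain at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time column must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("time column must be uniformly sampled")
    labels = [ChannelLabel.parse(c) for c in df.columns if c != "time_s"]
    samples = df.drop(columns="time_s").to_numpy(dtype=float).T
    return EMGRecording(samples, sampling_rate_hz=1.0 / dt[0], channel_labels=labels)


def write_physio(series: PhysioSeries, path: str | Path) -> None:
    pd.DataFrame({"time_s": series.times_s, "value": series.values}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_physio(path: str | Path, kind: str) -> PhysioSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.isna().any().any():
        raise ValueError("physio CSV contains missing values")
    return PhysioSeries(df["time_s"].to_numpy(float), df["value"].to_numpy(float), kind=kind)


def catmull_rom_spline(series: PhysioSeries) -> CubicHermiteSpline:
    """Cubic Hermite spline through the knots with Catmull-Rom tangents.

    Interior tangent at knot i is the centred finite difference
    (v[i+1] - v[i-1]) / (t[i+1] - t[i-1]); the endpoints use one-sided
    differences.  This is the standard generalisation of Catmull-Rom
    splines to non-uniform knot spacing.
    """
    t, v = series.times_s, series.values
    if len(t) < 2:
        raise ValueError("need at least 2 knots to interpolate")
    m = np.empty_like(v)
    m[0] = (v[1] - v[0]) / (t[1] - t[0])
    m[-1] = (v[-1] - v[-2]) / (t[-1] - t[-2])
    if len(t) > 2:
        m[1:-1] = (v[2:] - v[:-2]) / (t[2:] - t[:-2])
    return CubicHermiteSpline(t, v, m, extrapolate=False)


def interpolate_catmull_rom(series: PhysioSeries, query_times_s: np.ndarray) -> np.ndarray:
    """Evaluate the Catmull-Rom interpolant at ``query_times_s``.

    Queries outside [first knot, last knot] raise rather than extrapolate:
    physiology outside the measured span should not be invented silently.
    """
    q = np.asarray(query_times_s, dtype=float)
    t = series.times_s
    if np.any(q < t[0]) or np.any(q > t[-1]):
        raise ValueError(
            f"query times outside the knot range [{t[0]}, {t[-1]}]; "
            "drop out-of-range segments before interpolating"
        )
    return catmull_rom_spline(series)(q)
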