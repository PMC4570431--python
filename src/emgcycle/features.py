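"""Per-segment spectral characterisation: the 36 input variables.

Each 256-sample segment is Hamming-windowed and its one-sided power
spectrum P(f) is normalised to a unit-area power distribution D(f) over
0..Nyquist.  From the segment and D(f) come:

1-3    RMS, dRMS (RMS of the backward difference), IF (zero crossings / 2)
4-8    ModF, MnF, StD, Skew, Kurt — mode, mean, standard deviation,
       skewness and excess kurtosis of D(f)
9-17   q10..q90 — every tenth percentile of D(f); q50 is the median
       power frequency (MPF)
18-36  p23_47..p234_258 — relative power in 23.44 Hz bands (6 DFT bins)
       overlapping by 11.72 Hz (3-bin offsets), first band starting at
       DFT bin 6 (23.44 Hz) and the last ending at bin 66 (257.8 Hz)

Each variable is finally smoothed along the segment axis with an 11-point
running median to suppress revolution-to-revolution variability.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.signal.windows import hamming

from .segmentation import SegmentSet

log = logging.getLogger(__name__)

N_BAND = 19
_BAND_START_BIN = 6
_BAND_WIDTH_BINS = 6
_BAND_STEP_BINS = 3


def band_plan(n: int = 256, fs: float = 1000.0) -> list[tuple[float, float]]:
    """(low, high) Hz edges of the 19 overlapping relative-power bands."""
    df = fs / n
    n_bins = n // 2 + 1
    last_bin = _BAND_START_BIN + _BAND_STEP_BINS * (N_BAND - 1) + _BAND_WIDTH_BINS
    if last_bin > n_bins - 1:
        raise ValueError(
            f"segment length {n} at {fs} Hz cannot host the fixed band plan; "
            "supply an explicit band table"
        )
    return [
        (df * (_BAND_START_BIN + _BAND_STEP_BINS * k),
         df * (_BAND_START_BIN + _BAND_STEP_BINS * k + _BAND_WIDTH_BINS))
        for k in range(N_BAND)
    ]


def _band_names(n: int = 256, fs: float = 1000.0) -> list[str]:
    return [f"p{round(lo)}_{round(hi)}" for lo, hi in band_plan(n, fs)]


FEATURE_NAMES: list[str] = (
    ["RMS", "dRMS", "IF", "ModF", "MnF", "StD", "Skew", "Kurt"]
    + [f"q{10 * i}" for i in range(1, 10)]
    + _band_names()
)
MPF_INDEX = FEATURE_NAMES.index("q50")  # variable 13, median power frequency


class PowerDistribution:
    """Unit-area power density over the one-sided DFT grid."""

    def __init__(self, freqs_hz: np.ndarray, density: np.ndarray):
        self.freqs_hz = np.asarray(freqs_hz, dtype=float)
        self.density = np.asarray(density, dtype=float)
        self.bin_width_hz = float(self.freqs_hz[1] - self.freqs_hz[0])

    @property
    def mass(self) -> np.ndarray:
        """Per-bin probability mass density * bin width (sums to 1)."""
        return self.density * self.bin_width_hz


def power_distribution(segment: np.ndarray, fs: float = 1000.0) -> tuple[PowerDistribution, np.ndarray]:
    """Hamming-windowed one-sided power spectrum, raw and unit-area.

    Returns ``(D, P)`` where P is the raw squared DFT magnitude (needed by
    the relative band powers) and D is P scaled so the Riemann sum
    sum(D) * df equals one.  Raises on an all-zero segment.
    """
    s = np.asarray(segment, dtype=float)
    n = s.size
    if not np.any(s):
        raise ValueError("all-zero segment has no power distribution")
    w = hamming(n, sym=True)
    spec = np.fft.rfft(s * w)
    p = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    df = freqs[1] - freqs[0]
    density = p / (p.sum() * df)
    return PowerDistribution(freqs, density), p


def time_domain_features(segment: np.ndarray) -> tuple[float, float, float]:
    """RMS of the segment, RMS of its backward difference, and IF.

    IF is the zero-crossing count divided by two — a per-segment count,
    reported exactly as defined (not rescaled to Hz; downstream z-scoring
    makes affine units irrelevant).  Crossings are strict sign changes;
    exact zeros are skipped.
    """
    s = np.asarray(segment, dtype=float)
    rms = float(np.sqrt(np.mean(s**2)))
    drms = float(np.sqrt(np.mean(np.diff(s) ** 2))) if s.size >= 2 else 0.0
    nz = s[s != 0]
    if nz.size >= 2:
        crossings = int(np.count_nonzero(np.diff(np.sign(nz))))
    else:
        crossings = 0
    return rms, drms, crossings / 2.0


def distribution_moments(d: PowerDistribution) -> tuple[float, float, float, float, float]:
    """Mode, mean, SD, skewness and excess kurtosis of frequency under D.

    The DC bin is excluded from the mode search (the high-pass stage makes
    it near-zero, but a spurious mode at 0 Hz is ruled out regardless).
    For a degenerate distribution (all mass in one bin) SD is 0 and the
    standardized moments are reported as 0 by convention.
    """
    f, m = d.freqs_hz, d.mass
    mode = float(f[1:][np.argmax(d.density[1:])])
    mean = float(np.sum(f * m))
    var = float(np.sum((f - mean) ** 2 * m))
    sd = float(np.sqrt(max(var, 0.0)))
    if sd <= 0:
        return mode, mean, 0.0, 0.0, 0.0
    z = (f - mean) / sd
    skew = float(np.sum(z**3 * m))
    kurt = float(np.sum(z**4 * m) - 3.0)
    return mode, mean, sd, skew, kurt


def distribution_percentiles(d: PowerDistribution, probs: np.ndarray | None = None) -> np.ndarray:
    """Frequencies where the cumulative distribution first reaches each prob.

    Bin k's mass is treated as uniform over [f_k - df/2, f_k + df/2] and
    the crossing bin is resolved by linear interpolation; results are
    clipped to [0, Nyquist].
    """
    if probs is None:
        probs = np.arange(1, 10) / 10.0
    f, m = d.freqs_hz, d.mass
    df = d.bin_width_hz
    c = np.cumsum(m)
    c_before = np.concatenate(([0.0], c[:-1]))
    out = np.empty(len(probs))
    for i, p in enumerate(probs):
        k = int(np.searchsorted(c, p, side="left"))
        k = min(k, len(f) - 1)
        mk = m[k]
        frac = (p - c_before[k]) / mk if mk > 0 else 0.5
        out[i] = f[k] - df / 2.0 + frac * df
    return np.clip(out, 0.0, f[-1])


def band_powers(p: np.ndarray, n: int = 256, fs: float = 1000.0) -> np.ndarray:
    """Relative power in the 19 overlapping 6-bin bands.

    Band k sums raw one-sided spectrum bins [6+3k, 6+3k+6) and divides by
    the total power over the non-DC bins, so a flat spectrum yields
    6/(n/2) in every band.
    """
    p = np.asarray(p, dtype=float)
    if p.size != n // 2 + 1:
        raise ValueError(f"expected a one-sided spectrum of {n // 2 + 1} bins")
    band_plan(n, fs)  # validates that the fixed bin plan fits
    total = p[1:].sum()
    if total <= 0:
        return np.zeros(N_BAND)
    out = np.empty(N_BAND)
    for k in range(N_BAND):
        lo = _BAND_START_BIN + _BAND_STEP_BINS * k
        out[k] = p[lo : lo + _BAND_WIDTH_BINS].sum() / total
    return out


def segment_features(segment: np.ndarray, fs: float = 1000.0) -> np.ndarray:
    """All 36 variables for one segment, in the canonical order."""
    s = np.asarray(segment, dtype=float)
    if not np.any(s):
        log.warning("all-zero segment: features reported as 0")
        return np.zeros(len(FEATURE_NAMES))
    rms, drms, inst_f = time_domain_features(s)
    d, p = power_distribution(s, fs=fs)
    moments = distribution_moments(d)
    percentiles = distribution_percentiles(d)
    bands = band_powers(p, n=s.size, fs=fs)
    return np.concatenate(([rms, drms, inst_f], moments, percentiles, bands))


def assemble_features(segset: SegmentSet) -> pd.DataFrame:
    """Feature matrix: one row per segment, indexed by onset time (s)."""
    if len(segset) == 0:
        raise ValueError("empty segment set")
    fs = segset.sampling_rate_hz
    rows = np.stack([segment_features(seg, fs=fs) for seg in segset.segments])
    return pd.DataFrame(rows, columns=FEATURE_NAMES,
                        index=pd.Index(segset.onset_times_s, name="time_s"))


def median_smooth(matrix: pd.DataFrame, window: int = 11) -> pd.DataFrame:
    """Centred per-column running median; edge windows shrink symmetrically.

    11 points correspond to roughly 7-10 s of riding at 90-100 rpm.
    """
    if window % 2 == 0:
        raise ValueError("median window must be odd")
    return matrix.rolling(window, center=True, min_periods=1).median()
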