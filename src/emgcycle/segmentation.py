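"""Variability-ratio segmentation of cyclostationary sEMG.

One pedal revolution produces one activity burst per muscle.  Burst onsets
are found by comparing signal variability in windows of N samples before
and after each instant: the windowed variability

    V(t) = sum_{tau=t}^{t+N-1} |dS(tau)|,    dS(t) = S(t) - S(t-1)

and its before/after ratio

    Vcom(t) = V(t - N) / V(t)

reach a local minimum when t is the initial moment of a burst (quiet
window behind, active window ahead) and a local maximum at burst ends.
Fixed windows of N samples of the filtered signal after each detected
minimum form the segments used for spectral characterisation.

The literal signed window sum telescopes to a two-point difference and
does not measure variability; the default therefore sums absolute
backward differences (total variation in the window), with the signed
variant available behind ``mode="signed"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 256


@dataclass
class SegmentSet:
    """Per-channel burst onsets and fixed-length signal windows."""

    channel: str
    onsets: np.ndarray            # sample indices into the filtered signal
    segments: np.ndarray          # (n_segments, N) windows of S(t)
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=int)
        self.segments = np.atleast_2d(np.asarray(self.segments, dtype=float))
        if len(self.onsets) and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if len(self.onsets) != self.segments.shape[0]:
            raise ValueError("one segment per onset required")

    @property
    def onset_times_s(self) -> np.ndarray:
        return self.onsets / self.sampling_rate_hz

    def __len__(self) -> int:
        return len(self.onsets)


def backward_difference(s: np.ndarray) -> np.ndarray:
    """First backward difference dS(t) = S(t) - S(t-1); length n-1."""
    s = np.asarray(s, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 samples")
    return np.diff(s)


def variability(ds: np.ndarray, n: int = DEFAULT_WINDOW, mode: str = "absolute") -> np.ndarray:
    """Windowed variability V(t) over forward windows of ``n`` samples.

    ``mode="absolute"`` (default) sums |dS| — the total variation of the
    window; ``mode="signed"`` computes the literal signed sum, which
    telescopes and is kept only for comparison.
    """
    ds = np.asarray(ds, dtype=float)
    if n < 1:
        raise ValueError("window must be at least 1 sample")
    if ds.size < n:
        raise ValueError("signal shorter than the window")
    if mode == "absolute":
        x = np.abs(ds)
    elif mode == "signed":
        x = ds
    else:
        raise ValueError("mode must be 'absolute' or 'signed'")
    c = np.concatenate(([0.0], np.cumsum(x)))
    return c[n:] - c[:-n]


def variability_ratio(v: np.ndarray, n: int = DEFAULT_WINDOW, eps: float | None = None) -> np.ndarray:
    """Before/after variability ratio Vcom(t) = V(t-N) / V(t).

    Returned array is offset by ``n``: element j is Vcom at position j+n
    of the V array.  ``eps`` guards the division; by default it is scaled
    to the signal (1e-12 of the largest window variability) so that the
    ratio — and hence onset detection — is invariant to amplitude scaling.
    """
    v = np.asarray(v, dtype=float)
    if v.size <= n:
        raise ValueError("V too short for a before/after comparison")
    if eps is None:
        vmax = float(v.max())
        eps = 1e-12 * vmax if vmax > 0 else 1e-300
    return v[:-n] / np.maximum(v[n:], eps)


def detect_onsets(
    vcom: np.ndarray,
    min_separation_samples: int,
    prominence_frac: float = 0.2,
    clip: float = 2.0,
) -> np.ndarray:
    """Local minima of Vcom, filtered by separation and prominence.

    Minima closer than ``min_separation_samples`` keep only the deepest;
    required prominence is ``prominence_frac`` of the range of Vcom after
    clipping at ``clip``.  Vcom is a before/after ratio whose neutral
    value is 1: onset minima lie well below 1, while burst-end maxima can
    be arbitrarily large when the trailing window is near-silent, so
    values above ~2 carry no information about minima and would only
    inflate the prominence reference range.  Indices refer to the Vcom array; on plateaus (exactly flat
    minima in noise-free signals) the right edge — the last quiet sample
    before activity — is returned.
    """
    vcom = np.asarray(vcom, dtype=float)
    if vcom.size < 3 or not np.all(np.isfinite(vcom)):
        raise ValueError("Vcom must be finite with at least 3 samples")
    vc = np.minimum(vcom, clip)
    vrange = float(vc.max() - vc.min())
    if vrange == 0.0:
        return np.array([], dtype=int)
    peaks, props = find_peaks(
        -vc,
        distance=max(int(min_separation_samples), 1),
        prominence=prominence_frac * vrange,
        plateau_size=(1, None),
    )
    return props["right_edges"].astype(int)


def extract_segments(
    s: np.ndarray,
    onsets: np.ndarray,
    n: int = DEFAULT_WINDOW,
    channel: str = "",
    sampling_rate_hz: float = 1000.0,
) -> SegmentSet:
    """Cut ``n``-sample windows of S(t) starting at each onset.

    Onsets whose window would overrun the recording are dropped (logged).
    """
    s = np.asarray(s, dtype=float)
    onsets = np.asarray(onsets, dtype=int)
    keep = onsets + n <= s.size
    if not np.all(keep):
        log.info("dropping %d trailing onset(s) without a full %d-sample window",
                 int(np.sum(~keep)), n)
    kept = onsets[keep]
    segments = (
        np.stack([s[o : o + n] for o in kept]) if len(kept) else np.empty((0, n))
    )
    return SegmentSet(channel=channel, onsets=kept, segments=segments,
                      sampling_rate_hz=sampling_rate_hz)


def segment_channel(
    s: np.ndarray,
    sampling_rate_hz: float,
    cadence_rpm: float,
    n: int = DEFAULT_WINDOW,
    mode: str = "absolute",
    prominence_frac: float = 0.2,
    min_separation_frac: float = 0.7,
    channel: str = "",
) -> SegmentSet:
    """Full onset-detection pipeline for one filtered channel.

    ``min_separation_frac`` scales the expected cycle length (from the
    cadence) into the minimum allowed spacing between detected onsets.
    """
    ds = backward_difference(s)
    v = variability(ds, n=n, mode=mode)
    vcom = variability_ratio(v, n=n)
    cycle_samples = sampling_rate_hz * 60.0 / cadence_rpm
    minima = detect_onsets(
        vcom,
        min_separation_samples=int(min_separation_frac * cycle_samples),
        prominence_frac=prominence_frac,
    )
    # Vcom index j corresponds to position j+n in V, whose window starts at
    # backward-difference index j+n, i.e. signal sample j+n+1.
    onsets = minima + n + 1
    return extract_segments(s, onsets, n=n, channel=channel,
                            sampling_rate_hz=sampling_rate_hz)
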