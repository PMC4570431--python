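"""Band-limiting of raw sEMG: 400 Hz low-pass then 20 Hz high-pass.

Both filters are 10th-order Butterworth designs applied causally as
second-order sections (numerically stable at this order).  The high-pass
(cutoff 20 Hz) attains -60 dB at its 10 Hz stop edge; a 10th-order
Butterworth low-pass with a 400 Hz cutoff cannot reach -60 dB by 450 Hz
(the transition is too narrow for that order), so the design keeps the
printed order and cutoff and the achieved stop-band attenuation is
reported by :func:`stopband_attenuation_db`.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps

from .physio_io import EMGRecording

log = logging.getLogger(__name__)


def design_filters(
    lp_cut_hz: float = 400.0,
    hp_cut_hz: float = 20.0,
    order: int = 10,
    fs: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (low-pass SOS, high-pass SOS) Butterworth cascades."""
    if lp_cut_hz >= fs / 2 or hp_cut_hz >= fs / 2:
        raise ValueError("cutoff frequencies must be below Nyquist")
    sos_lp = sps.butter(order, lp_cut_hz, btype="lowpass", fs=fs, output="sos")
    sos_hp = sps.butter(order, hp_cut_hz, btype="highpass", fs=fs, output="sos")
    return sos_lp, sos_hp


def stopband_attenuation_db(sos: np.ndarray, freq_hz: float, fs: float = 1000.0) -> float:
    """Magnitude response in dB at one frequency (negative = attenuation)."""
    _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=fs)
    return float(20.0 * np.log10(np.abs(h[0])))


def bandpass_filter(
    rec: EMGRecording,
    lp_cut_hz: float = 400.0,
    lp_stop_hz: float = 450.0,
    hp_cut_hz: float = 20.0,
    hp_stop_hz: float = 10.0,
    order: int = 10,
    min_atten_db: float = 60.0,
) -> EMGRecording:
    """Filter every channel: low-pass at ``lp_cut_hz`` then high-pass at ``hp_cut_hz``.

    Causal single-pass filtering; the group delay is identical across
    channels, so between-segment comparisons are unaffected.  If either
    stage misses ``min_atten_db`` at its stop edge the achieved value is
    logged and the design is kept as printed.
    """
    fs = rec.sampling_rate_hz
    if fs <= 2 * lp_stop_hz:
        raise ValueError("sampling rate must exceed twice the low-pass stop edge")
    sos_lp, sos_hp = design_filters(lp_cut_hz, hp_cut_hz, order=order, fs=fs)
    for sos, edge, name in ((sos_lp, lp_stop_hz, "low-pass"), (sos_hp, hp_stop_hz, "high-pass")):
        att = stopband_attenuation_db(sos, edge, fs=fs)
        if att > -min_atten_db:
            log.info(
                "%s stage reaches %.1f dB at %.0f Hz (target -%.0f dB); "
                "order kept at %d as designed", name, att, edge, min_atten_db, order
            )
    filtered = sps.sosfilt(sos_hp, sps.sosfilt(sos_lp, rec.samples, axis=-1), axis=-1)
    return EMGRecording(filtered, sampling_rate_hz=fs, channel_labels=list(rec.channel_labels))
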