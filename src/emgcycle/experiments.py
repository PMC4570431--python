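"""Planted-signal recovery experiments on synthetic data.

These helpers run the real pipeline (simulate -> filter -> segment ->
features -> smooth) on a synthetic channel and then construct a target
with a known dependence on one feature, so that model quality and
variable-importance recovery can be measured against ground truth.  The
canonical experiment makes the target a noisy sigmoid of the segment RMS:
monotone but saturating, i.e. deliberately non-linear, which is the regime
where a forest should beat a linear model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import preprocess, segmentation, synthetic
from .features import FEATURE_NAMES, assemble_features, median_smooth
from .physio_io import ChannelLabel


def simulated_feature_matrix(
    n_cycles: int = 1000,
    seed: int = 0,
    channel: ChannelLabel = ChannelLabel("VL", "left"),
    spectral: synthetic.SpectralParams = synthetic.SpectralParams(),
    cadence_rpm: float = 90.0,
) -> pd.DataFrame:
    """Smoothed 36-variable matrix from one fully pipelined synthetic channel.

    The three-phase load template is rescaled so the session contains
    ``n_cycles`` pedal revolutions, giving RMS a wide, protocol-driven
    dynamic range.
    """
    cycle = 60.0 / cadence_rpm
    total = spectral.lead_in_s + n_cycles * cycle
    protocol = synthetic.ProtocolSpec(
        phases=((0.3 * total, 0.60), (0.4 * total, 0.925), (0.3 * total, 0.60)),
        cadence_rpm=cadence_rpm,
    )
    truth = synthetic.simulate_metabolics(protocol, seed=seed)
    rec = synthetic.simulate_emg(protocol, truth, channels=(channel,),
                                 spectral=spectral, seed=seed + 1)
    filtered = preprocess.bandpass_filter(rec)
    segset = segmentation.segment_channel(
        filtered.channel(channel), filtered.sampling_rate_hz, cadence_rpm,
        channel=str(channel),
    )
    return median_smooth(assemble_features(segset))


RECOVERY_SPECTRAL = synthetic.SpectralParams(tail_mass=0.3, tail_jitter_sd=0.2)
"""Burst spectrum for recovery experiments: substantial burst-to-burst
spectral diversity.  With a near-fixed spectral shape, dRMS is an almost
exact multiple of RMS and "which amplitude proxy drives the target" is
unidentifiable; large per-burst tail-mass jitter decouples the two so a
signal planted in RMS is attributable to RMS."""


def rms_sigmoid_dataset(
    n_cycles: int = 1000,
    seed: int = 0,
    steepness: float = 3.0,
    noise_sd: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix plus a target that is a noisy sigmoid of segment RMS.

    The target is 1 / (1 + exp(-steepness * z)) + Gaussian noise, with z
    the z-scored RMS column; steepness 3 drives the sigmoid well into both
    saturation regions over the protocol's RMS range.  Bursts are drawn
    with :data:`RECOVERY_SPECTRAL` so RMS is identifiable against dRMS.
    """
    fm = simulated_feature_matrix(n_cycles=n_cycles, seed=seed,
                                  spectral=RECOVERY_SPECTRAL)
    x = fm.to_numpy()
    rms = fm["RMS"].to_numpy()
    z = (rms - rms.mean()) / rms.std()
    rng = np.random.default_rng(seed + 10_000)
    y = 1.0 / (1.0 + np.exp(-steepness * z)) + rng.normal(0.0, noise_sd, len(z))
    return x, y


RMS_INDEX = FEATURE_NAMES.index("RMS")
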