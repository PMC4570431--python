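import numpy as np
import pytest

from emgcycle import (
    ChannelLabel,
    ProtocolSpec,
    SpectralParams,
    bandpass_filter,
    simulate_emg,
    simulate_metabolics,
)
from emgcycle.segmentation import segment_channel

VL = ChannelLabel("VL", "left")


def short_protocol(n_cycles: int, cadence_rpm: float = 90.0, load: float = 0.6) -> ProtocolSpec:
    """Single-phase protocol long enough for n_cycles revolutions plus lead-in."""
    dur = SpectralParams().lead_in_s + n_cycles * 60.0 / cadence_rpm
    return ProtocolSpec(phases=((dur, load),), cadence_rpm=cadence_rpm)


@pytest.fixture(scope="session")
def thirty_cycle_run():
    """One filtered channel over 30 jitter-free revolutions, with ground truth."""
    protocol = short_protocol(30)
    spectral = SpectralParams(onset_jitter_ms=0.0)
    truth = simulate_metabolics(protocol, seed=3)
    rec = simulate_emg(protocol, truth, channels=(VL,), spectral=spectral, seed=3)
    return bandpass_filter(rec), truth, protocol


@pytest.fixture(scope="session")
def thirty_cycle_segments(thirty_cycle_run):
    filtered, truth, protocol = thirty_cycle_run
    segset = segment_channel(
        filtered.channel(str(VL)), filtered.sampling_rate_hz,
        protocol.cadence_rpm, channel=str(VL),
    )
    return segset, truth
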