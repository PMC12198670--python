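import numpy as np
import pytest

from cmcpipe import CouplingSpec, WaveletBank, WindowingConfig, make_coupled_trial
from cmcpipe.preprocess import preprocess_trial, segment_trial


@pytest.fixture(scope="session")
def bank():
    return WaveletBank()


@pytest.fixture(scope="session")
def wincfg():
    return WindowingConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_analysis_pair(seed=0, delay_ms=24.0, direction="efferent", snr_db=10.0,
                       center=21.0, bw=10.0, strength=2.0):
    """Generate one coupled trial, preprocess it, and return the (peak, analysis)
    segments of the merged 250-Hz recording."""
    spec = CouplingSpec(
        coupling_center_hz=center,
        coupling_bandwidth_hz=bw,
        delay_ms=delay_ms,
        direction=direction,
        snr_db=snr_db,
        coupling_strength=strength,
        seed=seed,
    )
    trial = make_coupled_trial(spec, include_internals=False)
    merged = preprocess_trial(trial)
    return segment_trial(merged)


@pytest.fixture(scope="session")
def coupled_segments():
    """A single preprocessed high-SNR efferent trial (cached per session)."""
    return make_analysis_pair(seed=11)
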