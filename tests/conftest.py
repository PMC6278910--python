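import numpy as np
import pytest

from fretkin.simulate import SimConfig
from fretkin.traces import FretTrace, IntensityTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_cfg():
    """Noise-free, leakage-free single-state configuration."""
    return SimConfig(
        n_frames=400,
        noise_sd=0.0,
        leakage=0.0,
        fret_states=(0.5,),
        ctmc_rates=np.zeros((1, 1)),
        p_dynamic=0.0,
        seed=7,
    )


def make_fret(values, frame_time=0.08, trace_id="t"):
    values = np.asarray(values, dtype=float)
    return FretTrace(
        time=np.arange(values.size) * frame_time,
        efficiency=values,
        frame_time=frame_time,
        trace_id=trace_id,
    )


def make_intensity(donor, acceptor, frame_time=0.08, corrected=False):
    donor = np.asarray(donor, dtype=float)
    prov = [{"step": "correct_leakage", "leakage": 0.0}] if corrected else []
    return IntensityTrace(
        time=np.arange(donor.size) * frame_time,
        donor=donor,
        acceptor=np.asarray(acceptor, dtype=float),
        frame_time=frame_time,
        trace_id="t",
        provenance=prov,
    )


@pytest.fixture
def fret_factory():
    return make_fret


@pytest.fixture
def intensity_factory():
    return make_intensity
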