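import numpy as np
import pytest

from autonomic import preprocess, synth


@pytest.fixture(scope="session")
def cold_pressor_ibi():
    """One cold-pressor-like recording: rate up 25%, HF modulation down,
    LF modulation up at t = 120 s."""
    cfg = synth.cold_pressor(seed=11)
    return preprocess.build_ibi(synth.ipfm_beats(cfg)), cfg


@pytest.fixture(scope="session")
def stationary_ibi():
    """A stationary modulated recording (no transition)."""
    cfg = synth.ScenarioConfig(duration=300.0, seed=5)
    return preprocess.build_ibi(synth.ipfm_beats(cfg))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def constant_ibi(value: float = 1.0, n: int = 60) -> preprocess.IbiSeries:
    t = value * np.arange(1, n + 1)
    return preprocess.IbiSeries(t=t, ibi=np.full(n, value))


def alternating_ibi(m: float = 0.9, d: float = 0.05, n: int = 400) -> preprocess.IbiSeries:
    vals = m + d * (-1.0) ** np.arange(n)
    t = np.cumsum(vals)
    return preprocess.IbiSeries(t=t, ibi=vals)
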