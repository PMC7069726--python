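import numpy as np
import pytest

from thetagaze.preprocess import extract_epochs
from thetagaze.synth import SimulationConfig, simulate_lfp, simulate_session


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def quiet_session():
    """60 s session with no phase locking or coupling (shared, read-only)."""
    return simulate_session(SimulationConfig(duration_s=60.0, seed=5, p_blink=0.0))


@pytest.fixture(scope="session")
def coupled_epochs():
    """Fixation-style epochs cut from an LFP with strong 5->90 Hz coupling."""
    cfg = SimulationConfig(duration_s=160.0, seed=9, coupling_depth=0.8,
                           coupling_phase=np.pi)
    rec, truth = simulate_lfp(cfg)
    r = np.random.default_rng(3)
    base = np.arange(3.0, 156.0, 2.5)
    onsets = 1000.0 * base + r.uniform(-400, 400, size=len(base))
    return extract_epochs(rec, onsets[:60], window=(-750, 750), buffer_ms=1250)
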