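import numpy as np
import pytest

import pwvkit as pk


@pytest.fixture(scope="session")
def neonate_params():
    return pk.default_params("neonate")


@pytest.fixture(scope="session")
def neonate_hires(neonate_params):
    """Noise-free neonatal waveform at 10,000 timeframes per cycle."""
    return pk.generate_waveform(neonate_params, 10000)


@pytest.fixture(scope="session")
def neonate_curve(neonate_params):
    """Noise-free neonatal waveform at a typical 44-frame acquisition."""
    return pk.generate_waveform(neonate_params, 44)


def xcorr_delay_frames(asc: np.ndarray, desc: np.ndarray) -> int:
    """Independent delay oracle: argmax of the circular cross-correlation."""
    n = asc.size
    scores = [float(np.dot(np.roll(asc, k), desc)) for k in range(n)]
    return int(np.argmax(scores))
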