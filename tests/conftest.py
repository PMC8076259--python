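import numpy as np
import pytest

from rodentsleep import synth
from rodentsleep.types import Hypnogram, LightDarkSchedule


def make_hypnogram(spec: str, epoch_len: float = 4.0, start_zt: float = 0.0) -> Hypnogram:
    """Build a hypnogram from a compact spec like 'W*10 N*3 R*2'."""
    codes = {"W": 0, "N": 1, "R": 2}
    states = []
    for tok in spec.split():
        if "*" in tok:
            s, n = tok.split("*")
            states.extend([codes[s]] * int(n))
        else:
            states.append(codes[tok])
    return Hypnogram(np.array(states, dtype=np.int8), epoch_len=epoch_len,
                     start_zt=start_zt, schedule=LightDarkSchedule())


@pytest.fixture(scope="session")
def short_synth_recording():
    """20 min BL6-like animal with signals at 250 Hz and ground truth."""
    hyp = synth.generate_hypnogram(synth.BL6_LIKE, duration_s=1200.0, seed=42)
    rec, truth = synth.generate_recording(hyp, synth.BL6_LIKE, fs=250.0, seed=42)
    return rec, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240521)
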