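import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from eggpipe import GeneratorParams, generate_recording, preprocess_recording


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def clean_params():
    """Noise- and artifact-free pure-sine generator settings."""
    return GeneratorParams(
        harmonic_weight=0.0,
        freq_jitter_sd_cpm=0.0,
        pink_noise_sd_uv=0.0,
        spike_rate_per_min=0.0,
        motion_artifact_rate_per_min=0.0,
    )


@pytest.fixture
def clean_window(clean_params):
    """One pre-processed window of a clean 10 cpm recording."""
    rec = generate_recording("baseline", clean_params, duration_s=120, fs_hz=2000)
    return preprocess_recording(rec)[0]


def separable_table(n_per_class=50, n_noise=5, shift=3.0, seed=0):
    """Two-class feature table where f0 carries all the signal."""
    r = np.random.default_rng(seed)
    y = np.repeat([0, 1], n_per_class)
    cols = {"f0": r.standard_normal(2 * n_per_class) + shift * y}
    for i in range(1, n_noise + 1):
        cols[f"f{i}"] = r.standard_normal(2 * n_per_class)
    table = pd.DataFrame(cols)
    return table, y
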