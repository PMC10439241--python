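import numpy as np
import pandas as pd
import pytest

from sphereproteo import SimConfig
from sphereproteo.datatypes import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_tmt_config():
    return SimConfig(n_features=120, frac_regulated=0.25, seed=3)


@pytest.fixture
def two_plex_matrix():
    """Tiny noise-free 2-plex, 3-day matrix with +1/-1 plex offsets."""
    days = [0, 3, 6]
    samples, design = [], []
    for p, off in (("plexA", 1.0), ("plexB", -1.0)):
        for ch, d in enumerate(days):
            samples.append(f"{p}_day{d}")
            design.append({"timepoint_days": d, "plex_id": p, "channel": ch})
    base = np.array([20.0, 22.0, 24.0, 26.0])
    day_effect = np.array([0.0, 0.5, 1.0])
    vals = np.empty((4, 6))
    col = 0
    for p, off in (("plexA", 1.0), ("plexB", -1.0)):
        for ch in range(3):
            vals[:, col] = base + day_effect[ch] + off
            col += 1
    return ExpressionMatrix(
        values=pd.DataFrame(vals, index=[f"f{i}" for i in range(4)], columns=samples),
        design=pd.DataFrame(design, index=samples),
    )
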