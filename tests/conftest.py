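import numpy as np
import pandas as pd
import pytest

from snpmeth.simulate import SimulatorConfig, simulate_cohort
from snpmeth.types import MethylationMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic cohort shared by read-only tests."""
    cfg = SimulatorConfig(n_samples=150, n_probes=300, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture
def toy_beta_matrix():
    values = pd.DataFrame(
        {"s1": [0.1, 0.2, 0.3], "s2": [0.4, 0.5, 0.6]},
        index=["p1", "p2", "p3"],
    )
    return MethylationMatrix(values=values, scale="beta")


def make_detection_matrix(pass_fracs_by_sample, n_probes=100, thresh=0.00005):
    """Detection-p matrix where sample j passes in the given fraction of probes."""
    cols = {}
    for j, frac in enumerate(pass_fracs_by_sample):
        n_pass = int(round(frac * n_probes))
        col = np.concatenate(
            [np.full(n_pass, thresh / 2), np.full(n_probes - n_pass, thresh * 2)]
        )
        cols[f"s{j}"] = col
    return pd.DataFrame(cols, index=[f"p{i}" for i in range(n_probes)])
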