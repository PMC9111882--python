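from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from drinkmeta import ChangeScoreEstimate, SyntheticConfig, generate_studies

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")


def make_estimates(d, se, moderators=None):
    """Build a list of ChangeScoreEstimate from parallel value arrays."""
    mods = moderators or [{}] * len(d)
    return [
        ChangeScoreEstimate(
            estimate_id=f"e{i}", study_id=f"s{i}", d=float(di), se=float(si),
            n=1000, moderators=dict(mi),
        )
        for i, (di, si, mi) in enumerate(zip(d, se, mods))
    ]


def random_meta(rng, k, tau_max=0.3):
    """Draw one small random meta-analysis (y, v) with heterogeneity."""
    mu = rng.uniform(-0.2, 0.2)
    tau = rng.uniform(0.0, tau_max)
    se = rng.uniform(0.01, 0.15, size=k)
    y = mu + rng.normal(0.0, tau, size=k) + rng.normal(0.0, se)
    return y, se**2


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def synthetic_records():
    """One default-condition synthetic dataset, shared across tests."""
    return generate_studies(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def synthetic_csv(tmp_path_factory):
    from drinkmeta import write_studies

    path = tmp_path_factory.mktemp("data") / "studies.csv"
    write_studies(generate_studies(SyntheticConfig(seed=11)), path)
    return path
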