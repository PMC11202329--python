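"""Shared fixtures: small hand-built episode tables and fast generator configs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from casemix.config import GeneratorConfig

#: flat demographic profile: every age decade and both sexes cost the same
FLAT_PROFILE = dict(
    age_multipliers={d: 1.0 for d in range(0, 101, 10)},
    sex_multipliers={"male": 1.0, "female": 1.0},
    age_weights={d: 1.0 for d in range(0, 101, 10)},
)


def make_episodes(
    costs,
    base_group=None,
    severity=None,
    qip=None,
    sex=None,
    age=None,
) -> pd.DataFrame:
    """Build a minimal valid episode table around a cost vector."""
    costs = np.asarray(costs, dtype=float)
    n = costs.size
    qip = np.zeros(n) if qip is None else np.asarray(qip, dtype=float)
    table = pd.DataFrame(
        {
            "episode_id": [f"E{i:05d}" for i in range(1, n + 1)],
            "age": np.full(n, 50) if age is None else np.asarray(age),
            "sex": np.full(n, "male") if sex is None else np.asarray(sex),
            "base_group": np.full(n, "G001") if base_group is None else np.asarray(base_group),
            "severity": np.ones(n, dtype=int) if severity is None else np.asarray(severity),
            "qidp": np.zeros(n),
            "qida": np.zeros(n),
            "qidc": np.zeros(n),
            "qipp": qip,
            "qips": np.zeros(n),
            "direct_cost": costs * 0.75,
            "indirect_cost": costs * 0.25,
            "total_cost": costs,
        }
    )
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def random_small_table(rng):
    """A ≤50-episode table with a handful of groups, for oracle comparisons."""
    n = 48
    costs = np.round(np.exp(rng.normal(7.5, 1.0, n)), 2)
    groups = rng.choice(["a", "b", "c", "d"], size=n)
    return make_episodes(costs, base_group=groups)


@pytest.fixture
def fast_config():
    """A small, quick generator config for pipeline-level tests."""
    return GeneratorConfig(n_episodes=8_000, n_base_groups=25, seed=7)
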