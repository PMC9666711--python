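import numpy as np
import pandas as pd
import pytest

from evocomm import ODTable, SyntheticConfig, generate_dataset, \
    paper_like_config
from evocomm.synthetic import CommunityParams

#: canonical factor-level orderings used by the model fits
LEVEL_ORDER = {
    "entity": ["strain1", "strain2", "community"],
    "history": ["ancestor", "evolved_isolation", "evolved_community",
                "mixed1", "mixed2"],
    "environment": ["env1", "env2"],
}


def two_community_config(sigma=0.05, replicates=8,
                         environments=("env1", "env2")) -> SyntheticConfig:
    """Small asymmetric config: X evolves additively, Y not at all."""
    x = CommunityParams(
        baseline={"strain1": 0.60, "strain2": 0.40},
        evo_effect={("strain1", "evolved_community"): 0.10,
                    ("strain1", "evolved_isolation"): -0.05,
                    ("strain2", "evolved_community"): -0.04},
        env_shift={"strain1": 0.30, "strain2": 0.20},
        dominance=0.8,
        interaction={"env1": 0.05, "env2": 0.05},
        interaction_evolution={"env1": 0.0, "env2": 0.0},
        trigger="never")
    y = CommunityParams(
        baseline={"strain1": 0.70, "strain2": 0.30},
        dominance=0.6,
        interaction={"env1": 0.02, "env2": 0.02})
    return SyntheticConfig(communities={"X": x, "Y": y}, sigma=sigma,
                           replicates=replicates, environments=environments)


def null_config(sigma=0.0, replicates=8,
                environments=("env1", "env2")) -> SyntheticConfig:
    """All evolution effects zero: every downstream verdict must be negative."""
    comms = {name: CommunityParams(baseline={"strain1": 0.6, "strain2": 0.4},
                                   dominance=0.7,
                                   interaction={"env1": 0.05, "env2": 0.05})
             for name in ("X", "Y")}
    return SyntheticConfig(communities=comms, sigma=sigma,
                           replicates=replicates, environments=environments)


def single_community_config(delta=0.0, trigger="never", sigma=0.05,
                            replicates=8, evo_effect=None,
                            dominance=0.5) -> SyntheticConfig:
    p = CommunityParams(
        baseline={"strain1": 0.6, "strain2": 0.4},
        evo_effect=dict(evo_effect or {}), dominance=dominance,
        interaction={"env1": 0.0},
        interaction_evolution={"env1": float(delta)}, trigger=trigger)
    return SyntheticConfig(communities={"X": p}, sigma=sigma,
                           replicates=replicates, environments=("env1",))


def manual_table(cells: dict) -> ODTable:
    """Build a table from {(community, entity, history, environment): [od...]}."""
    rows = []
    for (comm, entity, history, env), values in cells.items():
        for i, v in enumerate(values):
            rows.append((comm, entity, history, env, i + 1, float(v)))
    return ODTable(pd.DataFrame(
        rows, columns=["community", "entity", "history", "environment",
                       "replicate", "od"]))


@pytest.fixture(scope="session")
def paper_cfg():
    return paper_like_config()


@pytest.fixture(scope="session")
def paper_table(paper_cfg):
    return generate_dataset(paper_cfg, seed=11)


@pytest.fixture(scope="session")
def small_table():
    return generate_dataset(two_community_config(), seed=3)


@pytest.fixture(scope="session")
def null_table():
    return generate_dataset(null_config(sigma=0.0), seed=0)
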