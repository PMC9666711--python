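"""Synthetic two-strain community OD datasets with known ground truth.

The generator emulates the phenotype-level outcome of a serial-transfer
evolution experiment: each strain of each community has an ancestral
monoculture productivity (mean OD600 at 3.5 days), additive shifts attached
to its evolutionary history (evolved alone vs. evolved within the
community), and an additive environment shift for the novel assay
environment. The co-culture phenotype is a dominance-weighted combination of
its members' monoculture phenotypes plus a baseline interaction offset, and
— crucially — an *interaction-evolution* offset ``delta`` that is switched on
only when the configured trigger condition on the members' versions holds.
``delta`` is the injectable ground truth that the downstream additivity test
is supposed to detect. Replicate noise is Gaussian, truncated at zero.

Mean laws
---------
monoculture  m(c, s, v, e) = b[c,s] + h[c,s,v] + g[c,s,e] (+ per-version
env-2 adjustment, see :class:`CommunityParams.env_version_shift`)

community    M(c, (v1, v2), e) = d_c * m(c,1,v1,e) + (1 - d_c) * m(c,2,v2,e)
                                  + I[c,e] + delta[c,e] * [trigger holds]

with h[.,ancestor] = 0 and g[.,env1] = 0 as identifiability anchors.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .data import (ENVIRONMENTS, ODTable, STRAIN_HISTORIES,
                   COMMUNITY_HISTORIES)

STRAINS = ("strain1", "strain2")
VERSIONS = STRAIN_HISTORIES  # ancestor / evolved_isolation / evolved_community
TRIGGERS = ("strain1_evolved", "strain2_evolved", "both_evolved", "never")

#: community history -> (strain-1 version, strain-2 version)
HISTORY_TO_VERSIONS = {
    "ancestor": ("ancestor", "ancestor"),
    "evolved_isolation": ("evolved_isolation", "evolved_isolation"),
    "evolved_community": ("evolved_community", "evolved_community"),
    "mixed1": ("evolved_community", "ancestor"),
    "mixed2": ("ancestor", "evolved_community"),
}


class ConfigError(ValueError):
    """A synthetic configuration violates its invariants."""


@dataclass
class CommunityParams:
    """Generative parameters of one two-strain community.

    Parameters
    ----------
    baseline
        Ancestral monoculture mean OD per strain, ``{"strain1": b1, ...}``.
    evo_effect
        Additive OD shift per (strain, version); ancestor entries must be 0
        and may be omitted.
    env_shift
        Additive OD shift per strain in environment 2 (environment 1 is the
        reference, shift 0).
    env_version_shift
        Optional extra environment-2 shift per (strain, version): lets the
        evolved phenotype be attenuated or lost in the novel environment,
        which a history-independent shift cannot express. Defaults to 0.
    dominance
        Weight of strain 1 in the community phenotype, in [0, 1].
    interaction
        Baseline co-culture offset I per environment.
    interaction_evolution
        Interaction-evolution offset ``delta`` per environment, applied when
        ``trigger`` is satisfied by the members' versions.
    trigger
        Condition on (strain-1 version, strain-2 version) that switches
        ``delta`` on: ``strain1_evolved`` / ``strain2_evolved`` /
        ``both_evolved`` / ``never``.
    """

    baseline: Mapping[str, float]
    evo_effect: Mapping[tuple[str, str], float] = field(default_factory=dict)
    env_shift: Mapping[str, float] = field(default_factory=dict)
    env_version_shift: Mapping[tuple[str, str], float] = \
        field(default_factory=dict)
    dominance: float = 0.5
    interaction: Mapping[str, float] = field(default_factory=dict)
    interaction_evolution: Mapping[str, float] = field(default_factory=dict)
    trigger: str = "never"

    def validate(self, name: str = "") -> list[str]:
        problems = []
        tag = f"community {name}: " if name else ""
        for s in STRAINS:
            if s not in self.baseline:
                problems.append(tag + f"baseline missing for {s}")
        if not 0.0 <= self.dominance <= 1.0:
            problems.append(tag + f"dominance {self.dominance} outside [0, 1]")
        if self.trigger not in TRIGGERS:
            problems.append(tag + f"unknown trigger {self.trigger!r}")
        for (s, v), val in self.evo_effect.items():
            if v == "ancestor" and val != 0.0:
                problems.append(tag + "evo_effect[ancestor] must be 0 "
                                      "(identifiability anchor)")
        return problems


@dataclass
class SyntheticConfig:
    """Full generator configuration: per-community parameters plus noise.

    ``sigma`` is the replicate (well-to-well) standard deviation of OD,
    shared by all cells; ``replicates`` is the per-cell sample size.
    """

    communities: Mapping[str, CommunityParams]
    sigma: float = 0.05
    replicates: int = 8
    environments: Sequence[str] = ENVIRONMENTS

    def validate(self) -> list[str]:
        problems = []
        if self.sigma < 0:
            problems.append(f"sigma must be >= 0, got {self.sigma}")
        if self.replicates < 2:
            problems.append(f"replicates must be >= 2, got {self.replicates}")
        if not self.communities:
            problems.append("at least one community required")
        for env in self.environments:
            if env not in ENVIRONMENTS:
                problems.append(f"unknown environment {env!r}")
        for name, params in self.communities.items():
            problems.extend(params.validate(name))
        return problems

    def check(self) -> None:
        problems = self.validate()
        if problems:
            raise ConfigError("invalid synthetic config:\n  " +
                              "\n  ".join(problems))

    # -- serialisation -------------------------------------------------------
    def to_dict(self) -> dict:
        def pack_pairs(m):
            return {f"{s}.{v}": float(x) for (s, v), x in m.items()}

        return {
            "sigma": float(self.sigma),
            "replicates": int(self.replicates),
            "environments": list(self.environments),
            "communities": {
                name: {
                    "baseline": {k: float(v) for k, v in p.baseline.items()},
                    "evo_effect": pack_pairs(p.evo_effect),
                    "env_shift": {k: float(v) for k, v in p.env_shift.items()},
                    "env_version_shift": pack_pairs(p.env_version_shift),
                    "dominance": float(p.dominance),
                    "interaction": {k: float(v)
                                    for k, v in p.interaction.items()},
                    "interaction_evolution": {
                        k: float(v)
                        for k, v in p.interaction_evolution.items()},
                    "trigger": p.trigger,
                }
                for name, p in self.communities.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        def unpack_pairs(m):
            out = {}
            for key, val in (m or {}).items():
                s, v = key.split(".")
                out[(s, v)] = float(val)
            return out

        comms = {}
        for name, p in d["communities"].items():
            comms[str(name)] = CommunityParams(
                baseline=dict(p["baseline"]),
                evo_effect=unpack_pairs(p.get("evo_effect")),
                env_shift=dict(p.get("env_shift") or {}),
                env_version_shift=unpack_pairs(p.get("env_version_shift")),
                dominance=float(p.get("dominance", 0.5)),
                interaction=dict(p.get("interaction") or {}),
                interaction_evolution=dict(
                    p.get("interaction_evolution") or {}),
                trigger=p.get("trigger", "never"),
            )
        return cls(communities=comms, sigma=float(d.get("sigma", 0.05)),
                   replicates=int(d.get("replicates", 8)),
                   environments=tuple(d.get("environments", ENVIRONMENTS)))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def trigger_satisfied(trigger: str, version_pair: tuple[str, str]) -> bool:
    v1, v2 = version_pair
    if trigger == "strain1_evolved":
        return v1 == "evolved_community"
    if trigger == "strain2_evolved":
        return v2 == "evolved_community"
    if trigger == "both_evolved":
        return v1 == "evolved_community" and v2 == "evolved_community"
    if trigger == "never":
        return False
    raise ConfigError(f"unknown trigger {trigger!r}")


def expected_monoculture_mean(config: SyntheticConfig, community: str,
                              strain: str, version: str,
                              environment: str) -> float:
    """Noise-free monoculture mean: baseline + history shift + env shift."""
    if version not in VERSIONS:
        raise ValueError(f"{version!r} is not a monoculture version; mixed "
                         "treatments exist only at the community level")
    if strain not in STRAINS:
        raise ValueError(f"unknown strain {strain!r}")
    p = config.communities[community]
    m = float(p.baseline[strain])
    m += float(p.evo_effect.get((strain, version), 0.0))
    if environment == "env2":
        m += float(p.env_shift.get(strain, 0.0))
        m += float(p.env_version_shift.get((strain, version), 0.0))
    elif environment != "env1":
        raise ValueError(f"unknown environment {environment!r}")
    return m


def expected_community_mean(config: SyntheticConfig, community: str,
                            version_pair: tuple[str, str],
                            environment: str) -> float:
    """Noise-free co-culture mean under the dominance-weighted law."""
    p = config.communities[community]
    m1 = expected_monoculture_mean(config, community, "strain1",
                                   version_pair[0], environment)
    m2 = expected_monoculture_mean(config, community, "strain2",
                                   version_pair[1], environment)
    mean = p.dominance * m1 + (1.0 - p.dominance) * m2
    mean += float(p.interaction.get(environment, 0.0))
    if trigger_satisfied(p.trigger, version_pair):
        mean += float(p.interaction_evolution.get(environment, 0.0))
    return mean


def expected_cell_mean(config: SyntheticConfig, community: str, entity: str,
                       history: str, environment: str) -> float:
    """Expected mean of any design cell (dispatches on entity)."""
    if entity == "community":
        return expected_community_mean(
            config, community, HISTORY_TO_VERSIONS[history], environment)
    strain = entity
    return expected_monoculture_mean(config, community, strain, history,
                                     environment)


def _cell_rng(seed: int, community: str, entity: str, history: str,
              environment: str) -> np.random.Generator:
    # per-cell substream derived by hashing the cell coordinates, so the
    # emitted values do not depend on iteration order
    label = f"{community}|{entity}|{history}|{environment}".encode()
    digest = hashlib.sha256(label).digest()
    words = [int.from_bytes(digest[i:i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + words))


def generate_dataset(config: SyntheticConfig, seed: int) -> ODTable:
    """Draw a full factorial OD table from the configured mean laws.

    Every design cell receives ``config.replicates`` records with
    ``od = max(0, Normal(mean, sigma^2))``. The same (config, seed) pair
    always yields a bit-identical table.
    """
    config.check()
    rows = []
    for community in config.communities:
        for environment in config.environments:
            for strain in STRAINS:
                for version in VERSIONS:
                    rows.extend(_emit_cell(config, seed, community, strain,
                                           version, environment))
            for history in COMMUNITY_HISTORIES:
                rows.extend(_emit_cell(config, seed, community, "community",
                                       history, environment))
    df = pd.DataFrame(rows, columns=["community", "entity", "history",
                                     "environment", "replicate", "od"])
    return ODTable(df, provenance=f"synthetic(seed={seed})")


def _emit_cell(config, seed, community, entity, history, environment):
    mean = expected_cell_mean(config, community, entity, history, environment)
    rng = _cell_rng(seed, community, entity, history, environment)
    vals = rng.normal(mean, config.sigma, size=config.replicates)
    vals = np.maximum(vals, 0.0)
    return [(community, entity, history, environment, r + 1, float(v))
            for r, v in enumerate(vals)]


# ---------------------------------------------------------------------------
# A study-shaped default configuration
# ---------------------------------------------------------------------------

def paper_like_config() -> SyntheticConfig:
    """Eight-community configuration shaped like the original study.

    Anchors (environment 1, averaged over communities): ancestral strain-1
    monocultures at 0.62 OD, ancestral strain 2 at 0.34, ancestral co-culture
    at 0.63. Four of the eight communities (A, C, F, H) carry a non-zero
    interaction-evolution effect; C and F carry negative effects, and H's
    trigger fires whenever strain 1 is in its evolved-in-community version
    (so that its mixed-1 community reproduces the evolved phenotype, marking
    strain 1 as the driver). H's effect is confined to environment 1,
    mirroring an evolved interaction whose expression depends on the assay
    conditions; A, C and F express theirs in both environments.

    The remaining communities decompose additively: D and E evolve through
    strain 1 only, B through both strains, and G not at all.
    """
    names = list("ABCDEFGH")
    b1_spread = [-0.10, -0.06, -0.03, 0.00, 0.02, 0.04, 0.06, 0.07]
    b2_spread = [-0.08, -0.04, -0.02, 0.00, 0.01, 0.03, 0.04, 0.06]
    # strain-level history shifts (evolved_community, evolved_isolation)
    h1 = {"A": (0.06, -0.07), "B": (0.08, -0.06), "C": (0.08, -0.07),
          "D": (0.10, -0.05), "E": (0.11, -0.06), "F": (0.08, -0.08),
          "G": (0.00, 0.00), "H": (0.06, -0.07)}
    h2 = {"A": (-0.04, 0.03), "B": (0.06, 0.03), "C": (0.02, 0.03),
          "D": (0.00, 0.00), "E": (0.00, 0.00), "F": (0.02, 0.04),
          "G": (0.00, 0.00), "H": (-0.04, 0.03)}
    delta = {"A": (0.18, 0.18, "both_evolved"),
             "C": (-0.20, -0.20, "both_evolved"),
             "F": (-0.20, -0.20, "both_evolved"),
             "H": (0.18, 0.00, "strain1_evolved")}
    communities = {}
    for i, name in enumerate(names):
        ec1, iso1 = h1[name]
        ec2, iso2 = h2[name]
        d1, d2, trig = delta.get(name, (0.0, 0.0, "never"))
        communities[name] = CommunityParams(
            baseline={"strain1": 0.62 + b1_spread[i],
                      "strain2": 0.34 + b2_spread[i]},
            evo_effect={("strain1", "evolved_community"): ec1,
                        ("strain1", "evolved_isolation"): iso1,
                        ("strain2", "evolved_community"): ec2,
                        ("strain2", "evolved_isolation"): iso2},
            env_shift={"strain1": 0.35, "strain2": 0.25},
            # in the novel environment the evolved-in-community advantage of
            # strain 1 reverses (ancestor > evolved in community > isolation)
            env_version_shift={("strain1", "evolved_community"): -0.10},
            dominance=0.9,
            interaction={"env1": 0.038, "env2": 0.038},
            interaction_evolution={"env1": d1, "env2": d2},
            trigger=trig,
        )
    return SyntheticConfig(communities=communities, sigma=0.05, replicates=8)
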