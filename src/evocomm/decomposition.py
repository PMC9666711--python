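"""Bootstrap decomposition of community evolutionary responses.

The evolutionary response of an entity is the change in its mean OD between
its evolved-in-community version and its ancestor, in the evolution
environment. The community's response is compared with three predictors:

* the response of strain 1 alone,
* the response of strain 2 alone,
* the sum of the two strain responses — the expected community response
  under additivity of the individual responses, i.e. under *no* evolution of
  the interspecific interaction.

Percentile 95% confidence intervals come from resampling replicate wells
within each treatment cell with replacement (cells resampled independently,
to their original size). The community response is deemed *predictable* from
a predictor when the predictor's CI contains the community's point response;
if no predictor qualifies, the community's evolution is attributed to an
evolution of the interaction itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DataError, ODTable

TARGETS = ("community", "strain1", "strain2", "additive_sum")
MODES = ("no_evolution", "single_strain_conditional",
         "both_strains_conditional", "interaction_evolution")


@dataclass(frozen=True)
class ResponseEstimate:
    """A bootstrapped evolutionary response (evolved_community - ancestor)."""

    community_id: str
    target: str
    environment: str
    point: float
    ci_low: float
    ci_high: float
    n_iter: int
    seed: int

    def contains(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high

    def overlaps(self, other: "ResponseEstimate") -> bool:
        return not (self.ci_high < other.ci_low or other.ci_high < self.ci_low)


@dataclass(frozen=True)
class PredictabilityResult:
    """Which predictors explain the community response; empty set means the
    interspecific interaction itself must have evolved."""

    community_id: str
    environment: str
    predictable_from: frozenset[str]
    criterion: str = "containment"

    @property
    def interaction_evolved(self) -> bool:
        return not self.predictable_from


@dataclass(frozen=True)
class ModeLabel:
    """How a community's productivity evolved."""

    community_id: str
    mode: str
    driver: frozenset[str]


def _cell(table: ODTable, community: str, entity: str, history: str,
          environment: str, min_n: int = 1) -> np.ndarray:
    vals = table.cell_values(community, entity, history, environment)
    if len(vals) < min_n:
        raise DataError(
            f"cell {community}:{entity}:{history}:{environment} has "
            f"{len(vals)} replicate(s); need >= {min_n}")
    return vals


def _target_entities(target: str) -> list[str]:
    if target == "additive_sum":
        return ["strain1", "strain2"]
    if target not in TARGETS:
        raise ValueError(f"unknown target {target!r}; expected one of "
                         f"{TARGETS}")
    return [target]


def response_point(table: ODTable, community: str, target: str,
                   environment: str = "env1") -> float:
    """Mean OD difference evolved_community - ancestor for the target.

    ``additive_sum`` is exactly the sum of the two strain responses.
    """
    total = 0.0
    for entity in _target_entities(target):
        anc = _cell(table, community, entity, "ancestor", environment)
        evo = _cell(table, community, entity, "evolved_community", environment)
        total += float(evo.mean() - anc.mean())
    return total


def bootstrap_response(table: ODTable, community: str, target: str,
                       environment: str = "env1", n_iter: int = 1000,
                       seed: int = 0) -> ResponseEstimate:
    """Percentile-bootstrap estimate of an evolutionary response.

    Each contributing cell's replicates are resampled with replacement to the
    original cell size, independently of other cells; for ``additive_sum``
    all four strain cells are resampled independently and the two strain
    responses summed per iteration. Deterministic for a fixed seed.
    """
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    rng = np.random.default_rng(int(seed))
    boot = np.zeros(n_iter)
    point = 0.0
    for entity in _target_entities(target):
        anc = _cell(table, community, entity, "ancestor", environment,
                    min_n=2)
        evo = _cell(table, community, entity, "evolved_community",
                    environment, min_n=2)
        point += float(evo.mean() - anc.mean())
        # fixed resampling order: ancestor cell first, then evolved cell
        anc_means = anc[rng.integers(0, len(anc),
                                     size=(n_iter, len(anc)))].mean(axis=1)
        evo_means = evo[rng.integers(0, len(evo),
                                     size=(n_iter, len(evo)))].mean(axis=1)
        boot += evo_means - anc_means
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return ResponseEstimate(community_id=community, target=target,
                            environment=environment, point=point,
                            ci_low=float(lo), ci_high=float(hi),
                            n_iter=n_iter, seed=int(seed))


def assess_predictability(community_est: ResponseEstimate,
                          predictor_ests: list[ResponseEstimate],
                          criterion: str = "containment"
                          ) -> PredictabilityResult:
    """Decide which predictors explain the community's response.

    ``containment`` (default): a predictor qualifies when its 95% bootstrap
    CI contains the community's point response. ``overlap``: a predictor
    qualifies when its CI overlaps the community's CI.
    """
    if community_est.target != "community":
        raise ValueError("community_est must have target 'community'")
    if criterion not in ("containment", "overlap"):
        raise ValueError(f"unknown criterion {criterion!r}")
    predictable = set()
    for est in predictor_ests:
        if (est.community_id != community_est.community_id or
                est.environment != community_est.environment):
            raise ValueError(
                f"predictor {est.target} belongs to "
                f"{est.community_id}/{est.environment}, not "
                f"{community_est.community_id}/{community_est.environment}")
        if criterion == "containment":
            ok = est.contains(community_est.point)
        else:
            ok = est.overlaps(community_est)
        if ok:
            predictable.add(est.target)
    return PredictabilityResult(
        community_id=community_est.community_id,
        environment=community_est.environment,
        predictable_from=frozenset(predictable), criterion=criterion)


def classify_evolution_mode(predictability: PredictabilityResult,
                            matrix) -> ModeLabel:
    """Label how a community's productivity evolved.

    Order of precedence: if the evolved co-culture does not differ from the
    ancestral co-culture, nothing evolved; otherwise an unexplained response
    is interaction evolution (driver: the strain(s) whose mixed co-culture
    reproduces the evolved phenotype, both strains if neither does); a
    response explained by exactly one strain is a conditional single-strain
    response; a response explained by both strains or only by their sum is a
    conditional two-strain response.
    """
    comm = predictability.community_id
    anc = matrix.verdict(comm, "community", "ancestor")
    if anc == "ns":
        return ModeLabel(comm, "no_evolution", frozenset())
    if predictability.interaction_evolved:
        drivers = {strain
                   for strain, mixed in (("strain1", "mixed1"),
                                         ("strain2", "mixed2"))
                   if matrix.verdict(comm, "community", mixed) == "ns"}
        if not drivers:
            drivers = {"strain1", "strain2"}
        return ModeLabel(comm, "interaction_evolution", frozenset(drivers))
    strains = predictability.predictable_from & {"strain1", "strain2"}
    if len(strains) == 1:
        return ModeLabel(comm, "single_strain_conditional",
                         frozenset(strains))
    return ModeLabel(comm, "both_strains_conditional",
                     frozenset(strains or {"strain1", "strain2"}))


@dataclass
class ChangeSummary:
    """Productivity changes relative to the ancestral co-culture, in percent.

    ``per_community`` has one row per community with its percent response
    (100 x community response / ancestral community mean OD) and percent
    excess over the additive expectation. Aggregates report the mean of the
    *absolute* percent response and the mean percent excess, each with the
    standard deviation and standard error across communities.
    """

    per_community: pd.DataFrame
    environment: str
    mean_abs_percent_response: float
    sd_abs_percent_response: float
    se_abs_percent_response: float
    mean_percent_excess: float
    sd_percent_excess: float
    se_percent_excess: float

    def to_json_dict(self) -> dict:
        return {
            "environment": self.environment,
            "communities": self.per_community.to_dict(orient="records"),
            "mean_abs_percent_response": self.mean_abs_percent_response,
            "sd_abs_percent_response": self.sd_abs_percent_response,
            "se_abs_percent_response": self.se_abs_percent_response,
            "mean_percent_excess": self.mean_percent_excess,
            "sd_percent_excess": self.sd_percent_excess,
            "se_percent_excess": self.se_percent_excess,
        }


def productivity_change_summary(table: ODTable, communities,
                                environment: str = "env1",
                                n_iter: int = 1000,
                                seed: int = 0) -> ChangeSummary:
    """Percent productivity change and percent excess over additivity.

    For each community, the percent response is the community response
    scaled by the ancestral community mean OD; the percent excess is the
    community response minus the additive expectation, on the same scale.
    ``n_iter``/``seed`` drive a bootstrap CI for each community's percent
    response (reported per community, not aggregated).
    """
    communities = sorted(communities)
    if not communities:
        raise ValueError("no communities given")
    rng = np.random.default_rng(int(seed))
    sub_seeds = rng.integers(0, 2 ** 31 - 1, size=len(communities))
    rows = []
    for comm, sub_seed in zip(communities, sub_seeds):
        anc = _cell(table, comm, "community", "ancestor", environment)
        anc_mean = float(anc.mean())
        if anc_mean <= 0:
            raise ArithmeticError(
                f"ancestral community mean OD is {anc_mean} for {comm}; "
                "percent change is undefined")
        resp = response_point(table, comm, "community", environment)
        additive = response_point(table, comm, "additive_sum", environment)
        est = bootstrap_response(table, comm, "community", environment,
                                 n_iter=n_iter, seed=int(sub_seed))
        rows.append({
            "community": comm,
            "ancestral_mean_od": anc_mean,
            "response": resp,
            "additive_response": additive,
            "percent_response": 100.0 * resp / anc_mean,
            "percent_response_ci_low": 100.0 * est.ci_low / anc_mean,
            "percent_response_ci_high": 100.0 * est.ci_high / anc_mean,
            "percent_excess": 100.0 * (resp - additive) / anc_mean,
        })
    df = pd.DataFrame(rows)
    n = len(df)
    abs_resp = df["percent_response"].abs()
    excess = df["percent_excess"]

    def sd(x):
        return float(x.std(ddof=1)) if n > 1 else 0.0

    return ChangeSummary(
        per_community=df, environment=environment,
        mean_abs_percent_response=float(abs_resp.mean()),
        sd_abs_percent_response=sd(abs_resp),
        se_abs_percent_response=sd(abs_resp) / np.sqrt(n),
        mean_percent_excess=float(excess.mean()),
        sd_percent_excess=sd(excess),
        se_percent_excess=sd(excess) / np.sqrt(n),
    )
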