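"""Signed comparison matrices and cross-environment maintenance counts.

The comparison matrix summarises, per community, how the evolved-in-community
version of each entity compares with reference treatments: the co-culture of
strains evolved together against the ancestral co-culture, the co-culture of
strains evolved in isolation and the two mixed co-cultures; and each strain's
evolved-in-community monoculture against its ancestor and its evolved-in-
isolation version. Verdicts (higher / lower / ns) come from the Tukey-adjusted
contrasts of the per-entity fixed-effect models.

A signed significant difference detected in the evolution environment is
*maintained* when the identical verdict recurs in the novel environment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ENTITIES, ODTable
from .inference import per_community_model

logger = logging.getLogger(__name__)

#: references each entity's evolved_community version is compared against
REFERENCES = {
    "community": ("ancestor", "evolved_isolation", "mixed1", "mixed2"),
    "strain1": ("ancestor", "evolved_isolation"),
    "strain2": ("ancestor", "evolved_isolation"),
}
_ALL_REFERENCES = ("ancestor", "evolved_isolation", "mixed1", "mixed2")
VERDICTS = ("higher", "lower", "ns", "not_applicable")


@dataclass
class ComparisonMatrix:
    """Long-format signed verdicts (one row per community/entity/reference).

    ``cells`` columns: community, entity, reference, environment, verdict,
    estimate (evolved_community minus reference mean), p_adj. Mixed-treatment
    references are structurally not applicable for strain entities.
    """

    cells: pd.DataFrame
    environment: str
    alpha: float

    def verdict(self, community: str, entity: str, reference: str) -> str:
        hit = self.cells[(self.cells["community"] == community) &
                         (self.cells["entity"] == entity) &
                         (self.cells["reference"] == reference)]
        if hit.empty:
            return "not_applicable"
        return str(hit["verdict"].iloc[0])

    def estimate(self, community: str, entity: str, reference: str) -> float:
        hit = self.cells[(self.cells["community"] == community) &
                         (self.cells["entity"] == entity) &
                         (self.cells["reference"] == reference)]
        if hit.empty:
            return np.nan
        return float(hit["estimate"].iloc[0])

    @property
    def communities(self) -> list[str]:
        return sorted(self.cells["community"].unique())

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)

    def pivot(self, entity: str) -> pd.DataFrame:
        """Reference x community grid of verdicts for one entity."""
        sub = self.cells[self.cells["entity"] == entity]
        return sub.pivot(index="reference", columns="community",
                         values="verdict")


def comparison_matrix(table: ODTable, environment: str,
                      alpha: float = 0.05) -> ComparisonMatrix:
    """Build the signed comparison matrix for one environment.

    Missing cells (incomplete communities, absent references) propagate as
    ``not_applicable`` with a logged warning instead of failing.
    """
    rows = []
    for entity in ENTITIES:
        _, comparisons = per_community_model(table, entity, environment,
                                             alpha=alpha)
        communities = sorted(
            set(comparisons.rows["community"]) | set(comparisons.unavailable)
        ) if not comparisons.rows.empty else list(comparisons.unavailable)
        for comm in communities:
            for reference in _ALL_REFERENCES:
                if reference not in REFERENCES[entity]:
                    rows.append({"community": comm, "entity": entity,
                                 "reference": reference,
                                 "environment": environment,
                                 "verdict": "not_applicable",
                                 "estimate": np.nan, "p_adj": np.nan})
                    continue
                verdict = comparisons.verdict(comm, "evolved_community",
                                              reference)
                if verdict == "not_applicable":
                    logger.warning(
                        "no %s evolved_community-vs-%s contrast for "
                        "community %s in %s", entity, reference, comm,
                        environment)
                    rows.append({"community": comm, "entity": entity,
                                 "reference": reference,
                                 "environment": environment,
                                 "verdict": "not_applicable",
                                 "estimate": np.nan, "p_adj": np.nan})
                    continue
                sub = comparisons.rows
                hit = sub[(sub["community"] == comm) &
                          (sub[["history_a", "history_b"]]
                           .apply(frozenset, axis=1) ==
                           frozenset(("evolved_community", reference)))]
                est = float(hit["estimate"].iloc[0])
                if hit["history_a"].iloc[0] != "evolved_community":
                    est = -est
                rows.append({"community": comm, "entity": entity,
                             "reference": reference,
                             "environment": environment, "verdict": verdict,
                             "estimate": est,
                             "p_adj": float(hit["p_adj"].iloc[0])})
    return ComparisonMatrix(cells=pd.DataFrame(rows), environment=environment,
                            alpha=alpha)


@dataclass
class MaintenanceSummary:
    """Counts of env-1 signed significant verdicts maintained in env 2.

    ``by_pair`` maps (entity, reference) to (maintained, total); ``sign_only``
    counts cells whose env-2 point estimate merely keeps the env-1 sign,
    regardless of env-2 significance. ``community_signal`` aggregates the
    community entity against the ancestor and evolved-in-isolation
    references — the community-level evolution signal.
    """

    by_pair: dict = field(default_factory=dict)
    sign_only: dict = field(default_factory=dict)

    def _aggregate(self, keys) -> tuple[int, int]:
        num = sum(self.by_pair[k][0] for k in keys if k in self.by_pair)
        den = sum(self.by_pair[k][1] for k in keys if k in self.by_pair)
        return num, den

    @property
    def overall(self) -> tuple[int, int]:
        return self._aggregate(list(self.by_pair))

    @property
    def community_signal(self) -> tuple[int, int]:
        return self._aggregate([("community", "ancestor"),
                                ("community", "evolved_isolation")])

    @property
    def strain_vs_isolation(self) -> tuple[int, int]:
        return self._aggregate([("strain1", "evolved_isolation"),
                                ("strain2", "evolved_isolation")])

    def to_json_dict(self) -> dict:
        return {
            "by_pair": {f"{e}|{r}": list(v)
                        for (e, r), v in self.by_pair.items()},
            "sign_only": {f"{e}|{r}": list(v)
                          for (e, r), v in self.sign_only.items()},
            "overall": list(self.overall),
            "community_signal": list(self.community_signal),
            "strain_vs_isolation": list(self.strain_vs_isolation),
        }


def maintenance_counts(m1: ComparisonMatrix,
                       m2: ComparisonMatrix) -> MaintenanceSummary:
    """Count env-1 signed significant cells that recur identically in env 2.

    The denominator of each (entity, reference) breakdown is the number of
    higher/lower cells in ``m1``; the numerator counts those with the same
    verdict in ``m2``. A secondary sign-only count tracks cells whose env-2
    estimate keeps the env-1 sign without requiring significance.
    """
    if m1.communities != m2.communities:
        raise ValueError(
            f"matrices cover different community sets: {m1.communities} "
            f"vs {m2.communities}")
    summary = MaintenanceSummary()
    for entity in ENTITIES:
        for reference in REFERENCES[entity]:
            num = den = sign_num = 0
            for comm in m1.communities:
                v1 = m1.verdict(comm, entity, reference)
                if v1 not in ("higher", "lower"):
                    continue
                den += 1
                if m2.verdict(comm, entity, reference) == v1:
                    num += 1
                e1 = m1.estimate(comm, entity, reference)
                e2 = m2.estimate(comm, entity, reference)
                if np.isfinite(e2) and np.sign(e2) == np.sign(e1):
                    sign_num += 1
            summary.by_pair[(entity, reference)] = (num, den)
            summary.sign_only[(entity, reference)] = (sign_num, den)
    return summary


def plot_comparison_matrix(matrix: ComparisonMatrix, path,
                           entity: str = "community") -> None:
    """Render the coloured verdict grid for one entity to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    grid = matrix.pivot(entity)
    code = {"higher": 0, "lower": 1, "ns": 2, "not_applicable": 3}
    data = grid.apply(lambda col: col.map(code)).to_numpy(dtype=float)
    cmap = ListedColormap(["#3b6fb6", "#c03a2b", "#d9d9d9", "#222222"])
    fig, ax = plt.subplots(figsize=(1 + 0.6 * grid.shape[1],
                                    1 + 0.6 * grid.shape[0]))
    ax.imshow(data, cmap=cmap, vmin=-0.5, vmax=3.5, aspect="equal")
    ax.set_xticks(range(grid.shape[1]), grid.columns)
    ax.set_yticks(range(grid.shape[0]), grid.index)
    ax.set_title(f"{entity} evolved_community vs references "
                 f"({matrix.environment})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
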