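"""The study's model suite on factorial OD tables.

Three layers of modelling feed the downstream analyses:

* an entity-level mixed model ``od ~ entity * history * environment`` with a
  random intercept per strain/community identity (histories restricted to
  ancestor / evolved in isolation / evolved in community);
* a community-level mixed model ``od ~ history * environment`` over the five
  community histories (including the two mixed co-cultures), random
  intercept per community;
* per-entity fixed-effect models ``od ~ community * history`` within one
  environment, whose Tukey-adjusted history contrasts within each community
  provide the signed verdicts used by the comparison matrices.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._tukey import tukey_pvalue
from .data import (COMMUNITY_HISTORIES, ENTITIES, ENVIRONMENTS, ODTable,
                   STRAIN_HISTORIES, expected_histories)
from .lmm import (AnovaTable, EstimabilityError, ModelFit, anova_type2_wald,
                  anova_wald, fit_lmm)
from .posthoc import EMMTable, emmeans_with_letters

__all__ = ["fit_entity_model", "fit_community_model", "per_community_model",
           "anova_type2_wald", "anova_wald", "emmeans_with_letters",
           "EstimabilityError", "ModelFit", "AnovaTable", "EMMTable",
           "PairwiseComparisons"]

_LEVEL_ORDER = {"entity": list(ENTITIES),
                "history": list(COMMUNITY_HISTORIES),
                "environment": list(ENVIRONMENTS)}


def _check_cells(df: pd.DataFrame, factors: list[str]) -> None:
    """Raise if any fixed-effect factorial cell has no data."""
    counts = df.groupby(factors, observed=False).size() if factors else None
    if counts is None:
        return
    levels = [sorted(df[f].unique()) for f in factors]
    for combo in itertools.product(*levels):
        key = combo if len(combo) > 1 else combo[0]
        if counts.get(key, 0) == 0:
            cell = ":".join(map(str, combo))
            raise EstimabilityError(f"empty design cell {cell} makes the "
                                    "factorial model inestimable")


def fit_entity_model(table: ODTable) -> ModelFit:
    """Mixed model over entities, histories and environments.

    Restricted to the three shared histories (mixed treatments exist only at
    the community level). Random intercept on the strain/community identity
    (community x entity, 24 levels in the full design).
    """
    df = table.subset(history=list(STRAIN_HISTORIES)).df
    if df.empty:
        raise EstimabilityError("no records with strain-level histories")
    df["identity"] = df["community"].astype(str) + ":" + df["entity"]
    if df["identity"].nunique() < 2:
        raise EstimabilityError(
            "the random identity intercept needs >= 2 identity levels")
    factors = [f for f in ("entity", "history", "environment")
               if df[f].nunique() >= 2]
    _check_cells(df, factors)
    return fit_lmm(df, factors, group_col="identity",
                   level_order=_LEVEL_ORDER)


def fit_community_model(table: ODTable) -> ModelFit:
    """Mixed model on community co-cultures over all five histories.

    Random intercept on community identity. Design cells missing for single
    communities (e.g. a community lacking its mixed-2 co-culture) do not
    block the fit; they are reported in the fit's warnings.
    """
    df = table.subset(entity="community").df
    if df.empty:
        raise EstimabilityError("no community records")
    if df["community"].nunique() < 2:
        raise EstimabilityError(
            "the random community intercept needs >= 2 communities")
    factors = [f for f in ("history", "environment") if df[f].nunique() >= 2]
    _check_cells(df, factors)
    warnings = []
    counts = df.groupby(["community", "history", "environment"],
                        observed=False).size()
    for comm in sorted(df["community"].unique()):
        for hist in COMMUNITY_HISTORIES:
            for env in sorted(df["environment"].unique()):
                if counts.get((comm, hist, env), 0) == 0:
                    warnings.append(f"unbalanced: community {comm} has no "
                                    f"{hist} records in {env}")
    return fit_lmm(df, factors, group_col="community",
                   level_order=_LEVEL_ORDER, warnings=warnings)


@dataclass
class PairwiseComparisons:
    """Tukey-adjusted history contrasts within each community.

    ``rows`` has one record per (community, history_a, history_b) with the
    signed estimate (mean_a - mean_b), standard error, adjusted p-value and
    verdict at ``alpha``. Communities whose design was incomplete appear in
    ``unavailable`` instead.
    """

    rows: pd.DataFrame
    alpha: float
    entity: str
    environment: str
    unavailable: list[str] = field(default_factory=list)

    def verdict(self, community: str, history_a: str, history_b: str) -> str:
        """higher / lower / ns for history_a relative to history_b."""
        if community in self.unavailable:
            return "not_applicable"
        r = self.rows
        hit = r[(r["community"] == community) &
                (r["history_a"] == history_a) & (r["history_b"] == history_b)]
        if hit.empty:
            hit = r[(r["community"] == community) &
                    (r["history_a"] == history_b) &
                    (r["history_b"] == history_a)]
            if hit.empty:
                return "not_applicable"
            est = -float(hit["estimate"].iloc[0])
        else:
            est = float(hit["estimate"].iloc[0])
        if float(hit["p_adj"].iloc[0]) >= self.alpha:
            return "ns"
        return "higher" if est > 0 else "lower"


def per_community_model(table: ODTable, entity: str, environment: str,
                        alpha: float = 0.05
                        ) -> tuple[ModelFit, PairwiseComparisons]:
    """Fixed-effects model ``od ~ community * history`` for one entity and
    environment, with Tukey-adjusted history contrasts within each community.

    Communities with an empty history cell are excluded from the fit and
    flagged unavailable rather than failing the whole analysis.
    """
    if entity not in ENTITIES:
        raise ValueError(f"unknown entity {entity!r}")
    sub = table.subset(entity=entity, environment=environment).df
    if sub.empty:
        raise EstimabilityError(
            f"no records for {entity} in {environment}")
    histories = [h for h in expected_histories(entity)
                 if h in set(sub["history"])]
    counts = sub.groupby(["community", "history"], observed=False).size()
    complete, unavailable = [], []
    for comm in sorted(sub["community"].unique()):
        if all(counts.get((comm, h), 0) > 0 for h in histories):
            complete.append(comm)
        else:
            unavailable.append(comm)
    if not complete:
        raise EstimabilityError(
            f"no community has a complete {entity} history design in "
            f"{environment}")
    work = sub[sub["community"].isin(complete)]
    factors = ["community", "history"] if len(complete) > 1 else ["history"]
    fit = fit_lmm(work, factors, group_col=None, level_order=_LEVEL_ORDER)

    # cell means and their covariance via the fitted design
    grid = pd.DataFrame(itertools.product(complete, histories),
                        columns=["community", "history"])
    M = fit.design_rows(grid)
    est = M @ fit.params
    cov = M @ fit.cov_params @ M.T
    records = []
    k = len(histories)
    for comm in complete:
        idx = grid.index[grid["community"] == comm].to_numpy()
        pairs = list(itertools.combinations(range(len(idx)), 2))
        diffs, ses = [], []
        for a, b in pairs:
            ia, ib = idx[a], idx[b]
            diffs.append(est[ia] - est[ib])
            var = cov[ia, ia] + cov[ib, ib] - 2.0 * cov[ia, ib]
            ses.append(np.sqrt(max(var, 0.0)))
        pvals = tukey_pvalue(np.array(diffs), np.array(ses), k=k,
                             df=fit.df_resid)
        for (a, b), d, se, pv in zip(pairs, diffs, ses, pvals):
            verdict = ("ns" if pv >= alpha
                       else ("higher" if d > 0 else "lower"))
            records.append({
                "community": comm,
                "history_a": grid.loc[idx[a], "history"],
                "history_b": grid.loc[idx[b], "history"],
                "estimate": float(d), "se": float(se), "p_adj": float(pv),
                "verdict": verdict})
    comparisons = PairwiseComparisons(rows=pd.DataFrame(records), alpha=alpha,
                                      entity=entity, environment=environment,
                                      unavailable=unavailable)
    return fit, comparisons
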