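"""Estimated marginal means, Tukey pairwise comparisons, letter displays."""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._tukey import tukey_pvalue
from .lmm import ModelFit


def _reference_grid(fit: ModelFit) -> pd.DataFrame:
    combos = itertools.product(*(fit.factor_levels[f]
                                 for f in fit.factor_levels))
    return pd.DataFrame(combos, columns=list(fit.factor_levels))


def estimate_marginal_means(fit: ModelFit, factors: list[str]) -> pd.DataFrame:
    """Marginal means over the reference grid, equal weights on omitted factors.

    Returns one row per combination of ``factors`` with columns ``emmean``
    and ``se``, plus (internally) the contrast matrix rows needed for
    pairwise comparisons.
    """
    for f in factors:
        if f not in fit.factor_levels:
            raise KeyError(f"factor {f!r} is not in the model "
                           f"({list(fit.factor_levels)})")
    grid = _reference_grid(fit)
    M = fit.design_rows(grid)
    rows, labels = [], []
    for combo in itertools.product(*(fit.factor_levels[f] for f in factors)):
        mask = np.ones(len(grid), dtype=bool)
        for f, lv in zip(factors, combo):
            mask &= (grid[f] == lv).to_numpy()
        rows.append(M[mask].mean(axis=0))
        labels.append(combo)
    L = np.vstack(rows)
    est = L @ fit.params
    cov = L @ fit.cov_params @ L.T
    out = pd.DataFrame(labels, columns=factors)
    out["emmean"] = est
    out["se"] = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    out.attrs["L"] = L
    out.attrs["cov"] = cov
    return out


@dataclass
class EMMTable:
    """Marginal means with Tukey-grouped letters; levels sharing no letter
    differ at the family alpha."""

    table: pd.DataFrame
    contrasts: pd.DataFrame
    alpha: float
    factors: list[str]

    def __repr__(self) -> str:
        return self.table.to_string(index=False)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def pairwise_tukey(emm: pd.DataFrame, factors: list[str], df_resid: float,
                   by: list[str] | None = None) -> pd.DataFrame:
    """All pairwise Tukey-adjusted contrasts among EMM rows.

    ``by`` splits the rows into separate families (e.g. one per environment);
    the family size k is the number of rows compared within a family.
    """
    cov = emm.attrs["cov"]
    by = by or []
    key_cols = [f for f in factors if f not in by]
    records = []
    groups = emm.groupby(by, sort=False) if by else [((), emm)]
    for by_vals, sub in groups:
        idx = sub.index.to_numpy()
        k = len(idx)
        if k < 2:
            continue
        pairs = list(itertools.combinations(range(k), 2))
        diffs, ses = [], []
        for a, b in pairs:
            ia, ib = idx[a], idx[b]
            d = emm.loc[ia, "emmean"] - emm.loc[ib, "emmean"]
            var = cov[ia, ia] + cov[ib, ib] - 2.0 * cov[ia, ib]
            diffs.append(d)
            ses.append(np.sqrt(max(var, 0.0)))
        pvals = tukey_pvalue(np.array(diffs), np.array(ses), k=k, df=df_resid)
        if not isinstance(by_vals, tuple):
            by_vals = (by_vals,)
        for (a, b), d, se, pv in zip(pairs, diffs, ses, pvals):
            rec = dict(zip(by, by_vals))
            rec["level_a"] = tuple(emm.loc[idx[a], key_cols])
            rec["level_b"] = tuple(emm.loc[idx[b], key_cols])
            rec.update(estimate=float(d), se=float(se), p_adj=float(pv))
            records.append(rec)
    return pd.DataFrame(records)


def compact_letters(levels: list, sig_pairs: set[frozenset]) -> dict:
    """Insert-and-absorb compact letter display.

    Deterministic in the order of ``levels``; two levels share a letter iff
    their pair is not in ``sig_pairs``.
    """
    columns: list[set] = [set(levels)]
    for a, b in itertools.combinations(levels, 2):
        if frozenset((a, b)) not in sig_pairs:
            continue
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            for drop in (a, b):
                candidate = col - {drop}
                if candidate and not any(candidate <= other
                                         for other in columns):
                    columns.append(candidate)
    # absorb columns that became subsets of later insertions
    columns = [c for c in columns
               if not any(c < other for other in columns)]
    order = {lv: i for i, lv in enumerate(levels)}
    columns.sort(key=lambda c: min(order[lv] for lv in c))
    alphabet = string.ascii_lowercase
    out = {lv: "" for lv in levels}
    for i, col in enumerate(columns):
        letter = alphabet[i % 26] * (1 + i // 26)
        for lv in col:
            out[lv] += letter
    return {lv: "".join(sorted(s)) for lv, s in out.items()}


def emmeans_with_letters(fit: ModelFit, factors: list[str],
                         alpha: float = 0.05,
                         by: list[str] | None = None) -> EMMTable:
    """Marginal means plus Tukey-grouped letters for the requested factors."""
    emm = estimate_marginal_means(fit, factors)
    contrasts = pairwise_tukey(emm, factors, df_resid=fit.df_resid, by=by)
    by = by or []
    key_cols = [f for f in factors if f not in by]
    emm = emm.copy()
    emm["letters"] = ""
    groups = emm.groupby(by, sort=False) if by else [((), emm)]
    for by_vals, sub in groups:
        if not isinstance(by_vals, tuple):
            by_vals = (by_vals,)
        levels = [tuple(r) for r in sub[key_cols].itertuples(index=False)]
        if contrasts.empty:
            sig = set()
        else:
            mask = pd.Series(True, index=contrasts.index)
            for col, val in zip(by, by_vals):
                mask &= contrasts[col] == val
            sig = {frozenset((ra, rb))
                   for ra, rb, pv in zip(contrasts.loc[mask, "level_a"],
                                         contrasts.loc[mask, "level_b"],
                                         contrasts.loc[mask, "p_adj"])
                   if pv < alpha}
        letters = compact_letters(levels, sig)
        emm.loc[sub.index, "letters"] = [
            letters[tuple(r)] for r in sub[key_cols].itertuples(index=False)]
    return EMMTable(table=emm, contrasts=contrasts, alpha=alpha,
                    factors=factors)
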