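"""End-to-end analysis: models, responses, predictability, modes, robustness.

``analyze`` ties the stages together on a validated OD table and returns an
:class:`AnalysisResult` bundle that can be serialised to an output directory
(CSV tables plus a JSON summary and a reproducibility manifest recording
seeds, iteration counts, alpha and the predictability criterion).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import DataError, ODTable, validate_design
from .decomposition import (ChangeSummary, ModeLabel, PredictabilityResult,
                            ResponseEstimate, assess_predictability,
                            bootstrap_response, classify_evolution_mode,
                            productivity_change_summary)
from .inference import (anova_type2_wald, emmeans_with_letters,
                        fit_community_model, fit_entity_model)
from .lmm import AnovaTable, ModelFit
from .posthoc import EMMTable
from .robustness import (ComparisonMatrix, MaintenanceSummary,
                         comparison_matrix, maintenance_counts)

_PREDICTOR_TARGETS = ("strain1", "strain2", "additive_sum")


@dataclass
class AnalysisOptions:
    """Reproducible run configuration for :func:`analyze`."""

    seed: int = 0
    n_iter: int = 1000
    alpha: float = 0.05
    criterion: str = "containment"  # or "overlap"
    response_environment: str = "env1"

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_iter < 1:
            raise ValueError(f"n_iter must be >= 1, got {self.n_iter}")
        if self.criterion not in ("containment", "overlap"):
            raise ValueError(f"unknown criterion {self.criterion!r}")


@dataclass
class AnalysisResult:
    options: AnalysisOptions
    entity_fit: ModelFit
    entity_anova: AnovaTable
    community_fit: ModelFit
    community_anova: AnovaTable
    emm_letters: dict[str, EMMTable]
    responses: list[ResponseEstimate]
    predictability: list[PredictabilityResult]
    modes: list[ModeLabel]
    matrices: dict[str, ComparisonMatrix]
    maintenance: MaintenanceSummary | None
    change_summary: ChangeSummary | None
    manifest: dict = field(default_factory=dict)

    @property
    def mode_by_community(self) -> dict[str, str]:
        return {m.community_id: m.mode for m in self.modes}

    def interaction_evolution_communities(self) -> list[str]:
        return sorted(m.community_id for m in self.modes
                      if m.mode == "interaction_evolution")

    def responses_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.responses])

    def summary_dict(self) -> dict:
        return {
            "modes": {m.community_id: {"mode": m.mode,
                                       "driver": sorted(m.driver)}
                      for m in self.modes},
            "predictability": {
                p.community_id: {
                    "predictable_from": sorted(p.predictable_from),
                    "interaction_evolved": p.interaction_evolved}
                for p in self.predictability},
            "interaction_evolution_communities":
                self.interaction_evolution_communities(),
            "change_summary": (self.change_summary.to_json_dict()
                               if self.change_summary else None),
            "maintenance": (self.maintenance.to_json_dict()
                            if self.maintenance else None),
            "manifest": self.manifest,
        }

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.entity_anova.rows.to_csv(outdir / "anova_entity_model.csv",
                                      index=False)
        self.community_anova.rows.to_csv(outdir / "anova_community_model.csv",
                                         index=False)
        for env, emm in self.emm_letters.items():
            emm.table.to_csv(outdir / f"emmeans_{env}.csv", index=False)
        self.responses_frame().to_csv(outdir / "responses.csv", index=False)
        for env, m in self.matrices.items():
            m.to_csv(outdir / f"comparison_matrix_{env}.csv")
        if self.change_summary is not None:
            self.change_summary.per_community.to_csv(
                outdir / "change_summary.csv", index=False)
        (outdir / "model_summaries.txt").write_text(
            "== entity model ==\n" + self.entity_fit.summary() +
            "\n\n== community model ==\n" + self.community_fit.summary() +
            "\n")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2)


def analyze(table: ODTable,
            options: AnalysisOptions | None = None) -> AnalysisResult:
    """Run the full analysis on a validated OD table.

    Raises :class:`DataError` before any model fit when the design validation
    reports errors.
    """
    options = options or AnalysisOptions()
    options.validate()
    report = validate_design(table)
    if not report.ok:
        raise DataError("design validation failed:\n" + report.to_json())

    entity_fit = fit_entity_model(table)
    entity_anova = anova_type2_wald(entity_fit)
    community_fit = fit_community_model(table)
    community_anova = anova_type2_wald(community_fit)

    # letter displays from per-environment refits of the entity model's
    # fixed structure (entity x history, random identity intercept)
    emm_letters = {}
    for env in table.environments:
        env_fit = fit_entity_model(table.subset(environment=env))
        emm_letters[env] = emmeans_with_letters(
            env_fit, ["entity", "history"], alpha=options.alpha)

    matrices = {env: comparison_matrix(table, env, alpha=options.alpha)
                for env in table.environments}

    env = options.response_environment
    if env not in table.environments:
        raise DataError(f"response environment {env!r} absent from table")
    rng = np.random.default_rng(int(options.seed))
    communities = table.communities
    seeds = rng.integers(0, 2 ** 31 - 1,
                         size=(len(communities), 4))
    responses: list[ResponseEstimate] = []
    predictability: list[PredictabilityResult] = []
    modes: list[ModeLabel] = []
    for ci, comm in enumerate(communities):
        ests = {}
        for ti, target in enumerate(("community",) + _PREDICTOR_TARGETS):
            ests[target] = bootstrap_response(
                table, comm, target, environment=env,
                n_iter=options.n_iter, seed=int(seeds[ci, ti]))
        responses.extend(ests.values())
        pred = assess_predictability(
            ests["community"], [ests[t] for t in _PREDICTOR_TARGETS],
            criterion=options.criterion)
        predictability.append(pred)
        modes.append(classify_evolution_mode(pred, matrices[env]))

    interaction_comms = sorted(m.community_id for m in modes
                               if m.mode == "interaction_evolution")
    change_summary = None
    if interaction_comms:
        change_summary = productivity_change_summary(
            table, interaction_comms, environment=env,
            n_iter=options.n_iter,
            seed=int(rng.integers(0, 2 ** 31 - 1)))

    maintenance = None
    if "env1" in matrices and "env2" in matrices:
        maintenance = maintenance_counts(matrices["env1"], matrices["env2"])

    manifest = {
        "package_version": __version__,
        "seed": options.seed,
        "n_iter": options.n_iter,
        "alpha": options.alpha,
        "criterion": options.criterion,
        "response_environment": options.response_environment,
        "n_records": len(table),
        "communities": communities,
        "provenance": table.provenance,
    }
    return AnalysisResult(options=options, entity_fit=entity_fit,
                          entity_anova=entity_anova,
                          community_fit=community_fit,
                          community_anova=community_anova,
                          emm_letters=emm_letters, responses=responses,
                          predictability=predictability, modes=modes,
                          matrices=matrices, maintenance=maintenance,
                          change_summary=change_summary, manifest=manifest)
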