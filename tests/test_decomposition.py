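import numpy as np
import pandas as pd
import pytest

from evocomm import (DataError, assess_predictability, bootstrap_response,
                     classify_evolution_mode, generate_dataset,
                     productivity_change_summary, response_point)
from evocomm.decomposition import PredictabilityResult, ResponseEstimate
from evocomm.robustness import ComparisonMatrix
from conftest import manual_table, null_config, single_community_config


def _est(community="X", target="community", point=0.0, lo=-1.0, hi=1.0,
         env="env1"):
    return ResponseEstimate(community_id=community, target=target,
                            environment=env, point=point, ci_low=lo,
                            ci_high=hi, n_iter=10, seed=0)


def _matrix(verdicts, env="env1"):
    """verdicts: {(community, entity, reference): verdict}"""
    rows = [{"community": c, "entity": e, "reference": r, "environment": env,
             "verdict": v, "estimate": np.nan, "p_adj": np.nan}
            for (c, e, r), v in verdicts.items()]
    return ComparisonMatrix(cells=pd.DataFrame(rows), environment=env,
                            alpha=0.05)


class TestResponsePoint:
    def test_identical_histories_give_zero(self):
        t = manual_table({
            ("X", "community", "ancestor", "env1"): [0.5, 0.7],
            ("X", "community", "evolved_community", "env1"): [0.5, 0.7]})
        assert response_point(t, "X", "community") == 0.0

    def test_hand_arithmetic(self):
        t = manual_table({
            ("X", "community", "ancestor", "env1"): [0.5, 0.7],
            ("X", "community", "evolved_community", "env1"): [0.8, 0.8]})
        assert response_point(t, "X", "community") == pytest.approx(0.2)

    def test_additive_sum_is_exact_sum(self):
        t = manual_table({
            ("X", "strain1", "ancestor", "env1"): [0.60, 0.62],
            ("X", "strain1", "evolved_community", "env1"): [0.67, 0.67],
            ("X", "strain2", "ancestor", "env1"): [0.34, 0.34],
            ("X", "strain2", "evolved_community", "env1"): [0.31, 0.29]})
        s1 = response_point(t, "X", "strain1")
        s2 = response_point(t, "X", "strain2")
        assert response_point(t, "X", "additive_sum") == s1 + s2
        assert s1 == pytest.approx(0.06)
        assert s2 == pytest.approx(-0.04)

    def test_empty_cell_raises_with_name(self):
        t = manual_table({
            ("X", "community", "ancestor", "env1"): [0.5, 0.7]})
        with pytest.raises(DataError, match="evolved_community"):
            response_point(t, "X", "community")


class TestBootstrapResponse:
    def test_degenerate_cells_give_zero_width_ci(self):
        t = manual_table({
            ("X", "community", "ancestor", "env1"): [0.5, 0.5, 0.5],
            ("X", "community", "evolved_community", "env1"): [0.8, 0.8]})
        est = bootstrap_response(t, "X", "community", n_iter=200, seed=1)
        assert est.ci_low == est.ci_high == pytest.approx(est.point)
        assert est.point == pytest.approx(0.3)

    def test_same_seed_is_deterministic(self, small_table):
        a = bootstrap_response(small_table, "X", "additive_sum", seed=7)
        b = bootstrap_response(small_table, "X", "additive_sum", seed=7)
        c = bootstrap_response(small_table, "X", "additive_sum", seed=8)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert (a.ci_low, a.ci_high) != (c.ci_low, c.ci_high)

    def test_invalid_n_iter(self, small_table):
        with pytest.raises(ValueError, match="n_iter"):
            bootstrap_response(small_table, "X", "community", n_iter=0)

    def test_ci_width_shrinks_with_replicates(self):
        widths = {}
        for reps in (4, 16):
            cfg = single_community_config(sigma=0.05, replicates=reps)
            ws = []
            for seed in range(30):
                t = generate_dataset(cfg, seed=seed)
                est = bootstrap_response(t, "X", "community", n_iter=400,
                                         seed=seed)
                ws.append(est.ci_high - est.ci_low)
            widths[reps] = np.mean(ws)
        assert widths[16] < widths[4]

    def test_ci_ordering_invariant(self, small_table):
        for target in ("community", "strain1", "strain2", "additive_sum"):
            est = bootstrap_response(small_table, "X", target, seed=3)
            assert est.ci_low <= est.ci_high


class TestAssessPredictability:
    def test_containment_includes_predictor(self):
        comm = _est(point=0.10)
        s1 = _est(target="strain1", lo=0.05, hi=0.15)
        res = assess_predictability(comm, [s1])
        assert "strain1" in res.predictable_from
        assert not res.interaction_evolved

    def test_exclusion_flags_interaction(self):
        comm = _est(point=0.10)
        preds = [_est(target=t, lo=-0.2, hi=0.04)
                 for t in ("strain1", "strain2", "additive_sum")]
        res = assess_predictability(comm, preds)
        assert res.interaction_evolved
        assert res.predictable_from == frozenset()

    def test_mismatched_community_rejected(self):
        comm = _est(community="X")
        with pytest.raises(ValueError, match="belongs to"):
            assess_predictability(comm, [_est(community="Y",
                                              target="strain1")])

    def test_overlap_criterion_differs_from_containment(self):
        comm = _est(point=0.10, lo=0.02, hi=0.18)
        s1 = _est(target="strain1", lo=-0.05, hi=0.05)  # overlaps CI, not point
        assert assess_predictability(comm, [s1]).interaction_evolved
        assert not assess_predictability(comm, [s1],
                                         criterion="overlap"
                                         ).interaction_evolved

    def test_detection_is_deterministic_function_of_delta_at_sigma_zero(self):
        for delta, expect in ((0.0, False), (0.15, True)):
            cfg = single_community_config(delta=delta, trigger="both_evolved",
                                          sigma=0.0)
            t = generate_dataset(cfg, seed=0)
            ests = {tg: bootstrap_response(t, "X", tg, n_iter=50, seed=1)
                    for tg in ("community", "strain1", "strain2",
                               "additive_sum")}
            res = assess_predictability(
                ests["community"],
                [ests["strain1"], ests["strain2"], ests["additive_sum"]])
            assert res.interaction_evolved is expect


class TestClassifyEvolutionMode:
    def _pred(self, predictable, community="X"):
        return PredictabilityResult(community_id=community,
                                    environment="env1",
                                    predictable_from=frozenset(predictable))

    def test_ns_vs_ancestor_is_no_evolution(self):
        m = _matrix({("X", "community", "ancestor"): "ns"})
        label = classify_evolution_mode(self._pred([]), m)
        assert label.mode == "no_evolution"
        assert label.driver == frozenset()

    def test_single_strain_conditional(self):
        m = _matrix({("X", "community", "ancestor"): "higher"})
        label = classify_evolution_mode(self._pred(["strain1"]), m)
        assert label.mode == "single_strain_conditional"
        assert label.driver == frozenset({"strain1"})

    def test_additive_only_is_both_strains(self):
        m = _matrix({("X", "community", "ancestor"): "higher"})
        label = classify_evolution_mode(self._pred(["additive_sum"]), m)
        assert label.mode == "both_strains_conditional"
        assert label.driver == frozenset({"strain1", "strain2"})

    def test_interaction_driver_from_mixed_cocultures(self):
        m = _matrix({("X", "community", "ancestor"): "higher",
                     ("X", "community", "mixed1"): "ns",
                     ("X", "community", "mixed2"): "lower"})
        label = classify_evolution_mode(self._pred([]), m)
        assert label.mode == "interaction_evolution"
        assert label.driver == frozenset({"strain1"})

    def test_interaction_driver_defaults_to_both(self):
        m = _matrix({("X", "community", "ancestor"): "lower",
                     ("X", "community", "mixed1"): "higher",
                     ("X", "community", "mixed2"): "higher"})
        label = classify_evolution_mode(self._pred([]), m)
        assert label.driver == frozenset({"strain1", "strain2"})


class TestProductivityChangeSummary:
    def test_hand_arithmetic(self):
        t = manual_table({
            ("X", "community", "ancestor", "env1"): [0.5, 0.5],
            ("X", "community", "evolved_community", "env1"): [0.6, 0.6],
            ("X", "strain1", "ancestor", "env1"): [0.5, 0.5],
            ("X", "strain1", "evolved_community", "env1"): [0.54, 0.54],
            ("X", "strain2", "ancestor", "env1"): [0.2, 0.2],
            ("X", "strain2", "evolved_community", "env1"): [0.21, 0.21]})
        cs = productivity_change_summary(t, ["X"], n_iter=50, seed=0)
        row = cs.per_community.iloc[0]
        assert row["percent_response"] == pytest.approx(20.0)
        assert row["percent_excess"] == pytest.approx(10.0)
        assert cs.mean_abs_percent_response == pytest.approx(20.0)

    def test_null_generator_gives_exactly_zero_excess(self):
        t = generate_dataset(null_config(sigma=0.0), seed=0)
        cs = productivity_change_summary(t, ["X", "Y"], n_iter=10, seed=0)
        assert (cs.per_community["percent_excess"] == 0.0).all()
        assert cs.mean_percent_excess == 0.0

    def test_zero_ancestral_mean_rejected(self):
        t = manual_table({
            ("X", "community", "ancestor", "env1"): [0.0, 0.0],
            ("X", "community", "evolved_community", "env1"): [0.6, 0.6],
            ("X", "strain1", "ancestor", "env1"): [0.5, 0.5],
            ("X", "strain1", "evolved_community", "env1"): [0.5, 0.5],
            ("X", "strain2", "ancestor", "env1"): [0.2, 0.2],
            ("X", "strain2", "evolved_community", "env1"): [0.2, 0.2]})
        with pytest.raises(ArithmeticError, match="ancestral"):
            productivity_change_summary(t, ["X"], n_iter=10, seed=0)
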