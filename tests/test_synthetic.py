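import numpy as np
import pytest

from evocomm import (ConfigError, SyntheticConfig, expected_community_mean,
                     expected_monoculture_mean, generate_dataset,
                     paper_like_config)
from evocomm.synthetic import (CommunityParams, expected_cell_mean,
                               trigger_satisfied)
from conftest import null_config, single_community_config


def _one_community(**kw):
    defaults = dict(baseline={"strain1": 0.62, "strain2": 0.34})
    defaults.update(kw)
    return SyntheticConfig(communities={"A": CommunityParams(**defaults)},
                           sigma=0.05)


class TestExpectedMeans:
    def test_zero_effects_identity(self):
        cfg = _one_community()
        for version in ("ancestor", "evolved_isolation", "evolved_community"):
            for env in ("env1", "env2"):
                assert expected_monoculture_mean(
                    cfg, "A", "strain1", version, env) == 0.62

    def test_history_shift_added(self):
        cfg = _one_community(
            evo_effect={("strain1", "evolved_community"): 0.06})
        assert expected_monoculture_mean(
            cfg, "A", "strain1", "evolved_community", "env1") == \
            pytest.approx(0.68)

    def test_environment_shift_added(self):
        cfg = _one_community(
            evo_effect={("strain2", "evolved_isolation"): 0.03},
            env_shift={"strain2": 0.50})
        assert expected_monoculture_mean(
            cfg, "A", "strain2", "evolved_isolation", "env2") == \
            pytest.approx(0.87)

    def test_mixed_version_rejected_for_monoculture(self):
        cfg = _one_community()
        with pytest.raises(ValueError, match="mixed"):
            expected_monoculture_mean(cfg, "A", "strain1", "mixed1", "env1")

    def test_dominance_limit(self):
        cfg = _one_community(dominance=1.0)
        for pair in (("ancestor", "ancestor"),
                     ("evolved_community", "ancestor"),
                     ("evolved_community", "evolved_community")):
            assert expected_community_mean(cfg, "A", pair, "env1") == \
                expected_monoculture_mean(cfg, "A", "strain1", pair[0],
                                          "env1")

    def test_weighted_sum_with_interaction_and_delta(self):
        cfg = _one_community(
            baseline={"strain1": 0.62, "strain2": 0.30},
            evo_effect={("strain1", "evolved_community"): 0.06},
            dominance=0.9,
            interaction={"env1": 0.05},
            interaction_evolution={"env1": 0.10},
            trigger="both_evolved")
        got = expected_community_mean(
            cfg, "A", ("evolved_community", "evolved_community"), "env1")
        assert got == pytest.approx(0.9 * 0.68 + 0.1 * 0.30 + 0.05 + 0.10)

    def test_trigger_unsatisfied_excludes_delta(self):
        cfg = _one_community(
            baseline={"strain1": 0.62, "strain2": 0.30},
            evo_effect={("strain1", "evolved_community"): 0.06},
            dominance=0.9, interaction={"env1": 0.05},
            interaction_evolution={"env1": 0.10}, trigger="both_evolved")
        got = expected_community_mean(
            cfg, "A", ("evolved_community", "ancestor"), "env1")
        assert got == pytest.approx(0.9 * 0.68 + 0.1 * 0.30 + 0.05)

    @pytest.mark.parametrize("trigger,pair,expected", [
        ("strain1_evolved", ("evolved_community", "ancestor"), True),
        ("strain1_evolved", ("ancestor", "evolved_community"), False),
        ("strain2_evolved", ("ancestor", "evolved_community"), True),
        ("both_evolved", ("evolved_community", "evolved_community"), True),
        ("both_evolved", ("evolved_community", "evolved_isolation"), False),
        ("never", ("evolved_community", "evolved_community"), False),
    ])
    def test_trigger_logic(self, trigger, pair, expected):
        assert trigger_satisfied(trigger, pair) is expected


class TestGenerateDataset:
    def test_noise_free_limit_reproduces_means_exactly(self):
        cfg = single_community_config(delta=0.1, trigger="both_evolved",
                                      sigma=0.0,
                                      evo_effect={("strain1",
                                                   "evolved_community"): 0.05})
        table = generate_dataset(cfg, seed=5)
        for _, row in table.df.iterrows():
            assert row["od"] == expected_cell_mean(
                cfg, row["community"], row["entity"], row["history"],
                row["environment"])

    def test_same_seed_bit_identical(self):
        cfg = single_community_config(sigma=0.05)
        assert generate_dataset(cfg, seed=9) == generate_dataset(cfg, seed=9)
        assert generate_dataset(cfg, seed=9) != generate_dataset(cfg, seed=10)

    def test_insertion_order_does_not_change_values(self):
        cfg = null_config(sigma=0.04)
        reordered = SyntheticConfig(
            communities=dict(reversed(list(cfg.communities.items()))),
            sigma=cfg.sigma, replicates=cfg.replicates,
            environments=cfg.environments)
        a = generate_dataset(cfg, seed=2).df
        b = generate_dataset(reordered, seed=2).df
        key = ["community", "entity", "history", "environment", "replicate"]
        merged = a.merge(b, on=key, suffixes=("_a", "_b"))
        assert len(merged) == len(a)
        assert (merged["od_a"] == merged["od_b"]).all()

    def test_cell_means_track_expected_means(self):
        """Monte-Carlo: cell sample means stay within 3 sigma/sqrt(n) of the
        configured means in at least 99% of cells over 200 seeds."""
        cfg = single_community_config(
            sigma=0.05, evo_effect={("strain1", "evolved_community"): 0.08})
        tol = 3 * 0.05 / np.sqrt(8)
        ok = total = 0
        for seed in range(200):
            table = generate_dataset(cfg, seed=seed)
            g = table.df.groupby(["entity", "history", "environment"],
                                 sort=False)["od"].mean()
            for (entity, history, env), m in g.items():
                mu = expected_cell_mean(cfg, "X", entity, history, env)
                ok += abs(m - mu) <= tol
                total += 1
        assert ok / total >= 0.99

    def test_truncation_never_negative(self):
        cfg = single_community_config(sigma=0.5)
        table = generate_dataset(cfg, seed=1)
        assert (table.df["od"] >= 0).all()
        # means at ~0.5 with sigma 0.5: truncation must actually fire
        assert (table.df["od"] == 0).any()

    @pytest.mark.parametrize("bad,msg", [
        (dict(sigma=-0.1), "sigma"),
        (dict(replicates=1), "replicates"),
    ])
    def test_invalid_config_rejected(self, bad, msg):
        cfg = single_community_config()
        for k, v in bad.items():
            setattr(cfg, k, v)
        with pytest.raises(ConfigError, match=msg):
            generate_dataset(cfg, seed=0)

    def test_bad_dominance_and_anchor_rejected(self):
        cfg = single_community_config()
        cfg.communities["X"].dominance = 1.5
        assert any("dominance" in p for p in cfg.validate())
        cfg2 = single_community_config(
            evo_effect={("strain1", "ancestor"): 0.1})
        assert any("ancestor" in p for p in cfg2.validate())


class TestPaperLikeConfig:
    def test_ancestral_anchors(self, paper_cfg):
        names = sorted(paper_cfg.communities)
        s1 = np.mean([expected_monoculture_mean(paper_cfg, c, "strain1",
                                                "ancestor", "env1")
                      for c in names])
        s2 = np.mean([expected_monoculture_mean(paper_cfg, c, "strain2",
                                                "ancestor", "env1")
                      for c in names])
        comm = np.mean([expected_community_mean(paper_cfg, c,
                                                ("ancestor", "ancestor"),
                                                "env1")
                        for c in names])
        assert s1 == pytest.approx(0.62, abs=0.02)
        assert s2 == pytest.approx(0.34, abs=0.02)
        assert comm == pytest.approx(0.63, abs=0.02)

    def test_exactly_four_interaction_evolving_communities(self, paper_cfg):
        with_delta = [name for name, p in paper_cfg.communities.items()
                      if any(v != 0 for v in p.interaction_evolution.values())]
        assert sorted(with_delta) == ["A", "C", "F", "H"]

    def test_config_is_valid_and_roundtrips_yaml(self, paper_cfg, tmp_path):
        assert paper_cfg.validate() == []
        path = tmp_path / "cfg.yaml"
        paper_cfg.to_yaml(path)
        back = SyntheticConfig.from_yaml(path)
        assert generate_dataset(back, seed=4) == \
            generate_dataset(paper_cfg, seed=4)
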