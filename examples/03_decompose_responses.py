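"""Bootstrap additivity test: is a community's response explained by its
members' responses?

For one community the evolutionary response (evolved-in-community minus
ancestor, env 1) is bootstrapped for the co-culture, each strain, and the
sum of the strain responses (the additive expectation). If no predictor's
95% CI covers the community's point response, the interspecific interaction
itself must have evolved.
"""

from evocomm import (assess_predictability, bootstrap_response,
                     generate_dataset, paper_like_config)

table = generate_dataset(paper_like_config(), seed=1)

for community in ("A", "D", "G"):
    ests = {}
    for i, target in enumerate(("community", "strain1", "strain2",
                                "additive_sum")):
        ests[target] = bootstrap_response(table, community, target,
                                          environment="env1", n_iter=1000,
                                          seed=100 + i)
    pred = assess_predictability(
        ests["community"],
        [ests["strain1"], ests["strain2"], ests["additive_sum"]])
    print(f"community {community}:")
    for target, est in ests.items():
        print(f"  {target:13s} response {est.point:+.3f} OD  "
              f"[{est.ci_low:+.3f}, {est.ci_high:+.3f}]")
    verdict = ("interaction evolved" if pred.interaction_evolved else
               f"predictable from {', '.join(sorted(pred.predictable_from))}")
    print(f"  -> {verdict}\n")

print("A carries an injected interaction-evolution effect (+0.18 OD): its "
      "response escapes every predictor CI. D evolves only through strain 1 "
      "and G not at all, so their responses stay explainable.")
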