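"""Generate a study-shaped synthetic OD dataset and inspect its design.

Eight two-strain communities (A-H), each measured as two monocultures and as
a co-culture, across evolutionary-history treatments and two environments,
with eight replicate wells per cell. Four communities (A, C, F, H) carry an
injected interaction-evolution effect — the ground truth the analysis is
supposed to recover.
"""

from evocomm import generate_dataset, paper_like_config, validate_design

config = paper_like_config()
table = generate_dataset(config, seed=1)

print(table)
report = validate_design(table)
print(f"design valid: {report.ok}")

cells = table.df.groupby(["entity", "history", "environment"])["od"]
print("\nGrand cell means across communities (OD600 at 3.5 days):")
print(cells.mean().round(3).unstack("environment"))

print("\nEach row above is the average over 8 communities x 8 replicate "
      "wells; env1 is the evolution environment, env2 the novel one.")
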