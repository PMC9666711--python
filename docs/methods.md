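# Methods

## Data model

The unit of observation is one replicate well's OD600 at 3.5 days, indexed
by community, entity (`strain1`, `strain2`, `community`), evolutionary
history (`ancestor`, `evolved_isolation`, `evolved_community`, and for
co-cultures the two `mixed` treatments), environment (`env1` = evolution
conditions, `env2` = novel conditions) and replicate number. Within each
community, strain 1 is by convention the more productive ancestral
monoculture. OD values are stored raw — no blank subtraction or
transformation — because the analysis operates on endpoint OD as the
productivity proxy. The canonical file format is a headered CSV; foreign
layouts are adapted by an explicit `Dialect` (column-name and factor-label
mapping) rather than by guessing. Enum labels are case-insensitive on input
and canonical lower-snake on output. Design validation reports (rather than
raises) missing cells, duplicates, under-replicated cells (< 2 replicates,
the minimum the bootstrap can resample) and mixed treatments attached to
strain entities.

## Synthetic generator

The generator emulates the phenotype-level outcome of serial-transfer
evolution; it does not simulate transfers, mutation or selection. Mean laws:

* monoculture: m(c,s,v,e) = b[c,s] + h[c,s,v] + g[c,s,e], with
  h[·, ancestor] = 0 and g[·, env1] = 0 as identifiability anchors;
* co-culture: M = d·m₁ + (1−d)·m₂ + I[c,e] + δ[c,e]·[trigger satisfied],
  where the trigger is a condition on the members' versions
  (`strain1_evolved`, `strain2_evolved`, `both_evolved`, `never`).

Replicates are Normal(mean, σ²) truncated at zero; truncation is inert
whenever means exceed 5σ, which holds for every default configuration.
Noise is homoscedastic within a configuration — real plate data are
somewhat heteroscedastic across entities, so calibration results here speak
to the homoscedastic case. Mixed co-cultures reuse the constituent strains'
version effects with no extra parameters. Per-cell random substreams are
derived by hashing the cell coordinates together with the top-level seed,
so emitted values are independent of iteration order and any (config, seed)
pair is bit-reproducible.

One deliberate extension: the environment shift is allowed an optional
per-(strain, version) adjustment in env 2 (`env_version_shift`, default 0).
A shift constant across histories cannot alter any history contrast, so
without this term the generator could not express an evolved phenotype that
is attenuated or lost in the novel environment — the very phenomenon the
maintenance analysis quantifies.

`paper_like_config()` is an eight-community configuration anchored to the
pooled ancestral means of the motivating study system (strain 1 ≈ 0.62 OD,
strain 2 ≈ 0.34, co-culture ≈ 0.63 in env 1), with dominance d = 0.9,
replicate σ = 0.05 and 8 replicates per cell. Interaction-evolution effects
are injected into four of the eight communities: δ = +0.18 (A, H) and
−0.20 (C, F), magnitudes chosen on the scale of the observed community
responses (|Δ| ≈ 0.1–0.25 OD). H's trigger fires whenever strain 1 is in
its evolved-in-community version, so its mixed-1 co-culture reproduces the
evolved phenotype and the driver attribution points to strain 1; H's δ is
also confined to env 1, modelling an evolved interaction whose expression
depends on the assay conditions. These are generator conventions for
testing recovery, not a reconstruction of the real per-community values,
which the study reports only as pooled means.

## Model fitting

Both mixed models have a single random intercept (strain/community
identity), so REML reduces to a one-dimensional profiled likelihood in
λ = σ²ᵤ/σ²ₑ, with (I + λZZ′)⁻¹ block-diagonal and explicit per group. The
criterion is minimised on a coarse log grid refined by a bounded scalar
search; the λ = 0 boundary is always compared directly, making the
zero-variance limit exact (fixed effects then equal OLS to machine
precision). The engine is cross-checked in the test suite against
statsmodels MixedLM and against variance components and type-II Wald
chi-squares frozen from R (lme4/lmerTest, car) on a regenerable fixture.
The REML criterion is nearly flat near its optimum, so the located λ is
reproducible only to ~1e-5 relative under permutations of the input rows;
Wald statistics inherit that (tested) tolerance.

Fixed effects use sum-to-zero coding. Type-III Wald tests each term's
coefficients directly; type-II orthogonalises each term, in the metric of
the coefficient covariance, against all terms containing it (the standard
marginality-respecting construction); on balanced designs the two coincide
to numerical precision. Wald (not likelihood-ratio) statistics are used
throughout. Marginal and conditional R² follow the variance-partition
definition: var(Xβ̂) over var(Xβ̂) + σ²ᵤ + σ²ₑ, adding σ²ᵤ to the numerator
for the conditional version.

Marginal means average the reference grid with equal weights over omitted
factor levels (the design is balanced or nearly so). All-pairwise families
are Tukey-adjusted; for speed, studentized-range tail probabilities are
computed by a vectorised Gauss–Legendre quadrature of the classical double
integral, accurate to ~1e-8 against scipy's implementation (spot-checked in
tests). Mixed-model contrasts use the residual degrees of freedom n − p;
Satterthwaite/Kenward–Roger approximations are out of scope. Letter
displays use the insert-and-absorb algorithm; sharing a letter is (by
tested invariant) exactly equivalent to an adjusted p ≥ α. Degenerate
zero-variance cells are resolved by convention: a zero difference with zero
SE is p = 1, a non-zero difference with zero SE is p = 0, which makes σ = 0
synthetic data behave as exact oracles.

Per-community verdicts come from fixed-effects-only fits of
`od ~ community * history` within one entity and environment — not from the
pooled mixed model — so each community's contrasts are driven by its own
cells; Tukey families are the history levels within one community (k = 3
for strains, k = 5 for co-cultures). Communities with an empty history cell
are excluded from the fit and flagged unavailable instead of failing the
analysis. Letter displays in the pipeline come from per-environment refits
of the entity model's fixed structure; whether pooled-model letters would
be preferable is genuinely open, and the per-environment refit was chosen
because letters are displayed within an environment.

## Bootstrap decomposition

The evolutionary response is the plug-in difference of cell means
(evolved-in-community minus ancestor), computed in the evolution
environment by default. Resampling draws replicate wells within each
treatment cell with replacement, to the original cell size, independently
across cells — the well is the experimental unit. For the additive target
the four strain cells are resampled independently and the two strain
responses summed per iteration, so `additive_sum` is exactly the sum of the
strain responses at the point level. CIs are percentile 2.5/97.5 with no
bias correction; 1000 iterations by default; all draws are seeded.

Predictability uses CI containment: the community is predictable from a
predictor iff the predictor's 95% CI contains the community's *point*
response. An alternative CI-overlap rule is available behind
`criterion="overlap"` but is not the default; containment matches the
way the response plots are read (a dashed line at the community mean
against predictor CIs). Mode classification then proceeds in order:
`no_evolution` if the evolved co-culture does not differ from the ancestral
co-culture (Tukey verdict ns); `interaction_evolution` if no predictor
qualifies, with driver strains attributed to whichever mixed co-culture is
indistinguishable from the evolved co-culture (both strains if neither is);
`single_strain_conditional` if exactly one strain qualifies; otherwise
`both_strains_conditional`. The productivity-change summary scales each
community's response, and its excess over the additive expectation, by that
community's ancestral co-culture mean OD, and reports means with both SD
and SE across communities (the appropriate dispersion for a four-community
set is arguable, so both are given).

## Robustness across environments

The comparison matrix holds the signed Tukey verdict of every
evolved-in-community column against its references (ancestor, evolved in
isolation, and for co-cultures the two mixed treatments). A signal is
*maintained* when a higher/lower verdict in env 1 recurs with the identical
verdict in env 2 (significance and sign); a secondary count relaxes this to
sign agreement of the env-2 point estimate. Counts are reported per
(entity, reference) pair, so any inventory of contrasts can be aggregated.

## Calibration: what the tests establish

On generator data (σ = 0.05, 8 replicates/cell), measured over fixed seed
protocols:

* With no interaction evolution the additivity test flags ~4–6% of
  communities (the containment rule is conservative because the additive
  CI is the widest).
* Detection rises monotonically with δ and is essentially certain by
  δ ≈ 12·σ/√8 ≈ 0.21 OD. Detection is limited by the width of the additive
  predictor's CI (≈ ±1.96·σ·√(4/8)), so effects of order 4·σ/√8 sit near
  50% power: the additivity test resolves only interaction effects clearly
  larger than the additive expectation's own sampling noise.
* The percentile bootstrap CI for a response of two 8-replicate cells
  covers the true value ≈ 90–91% of the time, not 95%: with n = 8 the
  bootstrap SD uses the within-cell MLE variance (factor √(7/8)) and the
  percentile interval ignores the t₁₄-like tail, giving asymptotic coverage
  ≈ P(|t₁₄| < 1.96·√(7/8)) ≈ 0.91. This is a property of the prescribed
  interval, reported as measured; studentised or BCa intervals would fix it
  but would be a different method.
* End-to-end on `paper_like_config()` data, the exact set of four injected
  interaction-evolving communities is recovered in ~86% of seeds; misses
  are dominated by ≥2σ excursions of a community's observed response into a
  predictor CI.

Passing these tests shows the pipeline is correctly calibrated for
Gaussian, homoscedastic, balanced data of this size. They do not establish
behaviour under heteroscedasticity, non-normal plate effects, or missing
cells beyond the flagged-unavailable paths.

## Numerical conventions

Zero-width bootstrap CIs arise from constant cells and are legal; percent
changes require a positive ancestral mean (else an error); all public
randomness flows from integer seeds through numpy Generators; CSV output
writes OD at full `repr` precision and reading uses round-trip float
parsing, so write→read is bit-exact.
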