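# Methods

## Assay data model

The reverse-time-course assays score progeny in timepoint windows measured in
hours post heat shock. The four canonical windows are half-open intervals —
[10, 22), [22, 34), [34, 46), [46, 58) — tiling the assay span; half-open
because the protocol transfers parents to fresh plates at 22, 34 and 46 h and
discards them at 58 h, so a transfer at hour 22 begins the next window.
Windows at 22 h and later form the *interhomolog window* (the homolog is
available as a repair template); [10, 22) is the *non-interhomolog window*.
The brood-viability protocol transfers at 10, 22 and 46 h instead, so brood
tables carry free-form window labels ("10-22", "22-46", "46-58") while
progeny tables use the canonical four.

Phenotype classes per plate are mutually exclusive: noncrossover recombinant,
crossover recombinant, mutant, undetermined recombinant (recombinant-looking
progeny whose repair product could not be sequenced), nonrecombinant, dead
egg, unfertilized. Undetermined and mutant progeny stay in plate totals but
are excluded from crossover-proportion denominators, which count only
recombinants of known class. The plate is the atomic unit (`parent_id`); for
assay variants run with three hermaphrodites per plate the counts are still
per plate.

## Frequency statistics

Binomial proportions carry **Wilson score** intervals (the default of the
DescTools R package, which reproduces all published interval endpoints here);
Clopper-Pearson is available behind `method="beta"`. At k = 0 and k = n the
analytic Wilson bounds are exactly 0 and 1 and are pinned to those values so
floating-point round-off cannot cross the point estimate.

Group comparisons are two-sided **Fisher exact tests** with the
point-probability criterion (the R `fisher.test` convention): p is the sum of
hypergeometric probabilities, over all tables with the observed margins, of
tables no more probable than the observed one. Degenerate margins make the
conditional distribution a point mass and return p = 1. Replicates are
pooled before testing, matching the source data's "combined sums of multiple
replicates" convention; stratified per-replicate testing is out of scope.

Reporting convention: percentages to one decimal; p-values to three decimals
(two significant figures below 0.01).

## Conversion tracts

A tract is a vector of calls (converted / unconverted / heteroduplex /
unreadable) over a ladder of polymorphism positions 3′ of the excision site.
Choices that matter:

- **Heteroduplex counts as converted** for tract extent and for the
  short-noncrossover single-site rule, since heteroduplex points fall inside
  tract spans.
- **Unreadable is non-informative**: it neither extends a tract nor bounds
  one.
- **Minimum tract** = (most distal − most proximal converted position) + 1,
  so a single converted site scores 1 bp. **Maximum tract** extends
  symmetrically to the nearest flanking *unconverted* polymorphism on each
  side, falling back to position 0 proximally and one past the ladder end
  distally. Only the distal extension is forced by the definition of the
  measurement; the symmetric proximal rule is this package's choice. max_bp
  is reported but never used for classification, so the choice cannot affect
  any headline statistic.
- Short noncrossover = converted/heteroduplex only at the most proximal
  (12 bp) site. Short crossover = minimum tract ≤ 198 bp, inclusive — the
  threshold is the wild-type median crossover tract length.
- The **default ladder** (12, 77, 142, 209, 284, 352, 424, 495, 567 bp) fixes
  only the assay's true endpoints (12 and 567); the interior positions are a
  representative synthetic set, configurable per dataset. Classification
  depends only on position 12 and the 198 bp threshold.
- A recombinant carrying two distinguishable repair products is flagged
  `ambiguous` and excluded from summaries.

Junction microhomology of a deletion [s, e) is the largest m with
`ref[s-m:s] == ref[e-m:e]` — identical sequence abutting both junction sides,
exact matches only, with an empty deletion scoring 0. A mutation is
TMEJ-like when its deletion is under 50 bp and either the junction shows
microhomology (m ≥ 1) or the insertion is templated from nearby sequence.

## Beta-Binomial brood-viability model

Per group (genotype, window, dose), each hermaphrodite draws
p ~ Beta(λφ, λ(1−φ)) and hatches Binomial(brood, p) eggs, brood = hatched +
dead. The fitted likelihood marginalizes p (beta-binomial), so λ is the
inter-hermaphrodite overdispersion scale: λ → ∞ recovers Binomial(n, φ).
A literal reading with a single shared p per group is unidentifiable jointly
with a free (φ, λ); the marginal form is the identifiable interpretation and
gamma is computed on the group *mean* viability φ = E[p]. Zero-brood
hermaphrodites contribute no likelihood term (viability is undefined) but are
counted in reports.

**Priors** (configurable): φ ~ Uniform(0, 1); λ ~ Exponential(mean 1000) —
weakly informative with support for heavy overdispersion. A Half-Normal
alternative (`Priors(lam_dist="halfnormal", lam_scale=500)`) is built in for
prior-sensitivity refits.

**Sampler**: groups are a priori independent, so fitting is per group, and
each group's chain seeds derive from (seed, group key) — a group's posterior
is bit-identical whether fitted alone or with others, and identical seed +
data + configuration reproduces identical draws. The sampler is an adaptive
random-walk Metropolis on the unconstrained (logit φ, log λ) scale, updating
each coordinate in turn with its own Gaussian step; step scales adapt in
blocks of 50 warmup iterations toward 37.5% acceptance (mid
0.3–0.45 band) and freeze for sampling. Defaults: 4 chains, 2000 warmup +
2000 retained draws. Split R-hat and effective sample size (arviz) are
attached per parameter; any R-hat > 1.01 flags the group as non-converged on
the results object and raises a warning — never silently.

**Gamma** is the per-draw ratio φ_{g,t,i} / φ_{g,t,0}, paired by draw index
(generated-quantities semantics, preserving posterior correlation with the
denominator), summarized by the median and central 95% credible interval.
Two groups "differ" when their gamma intervals do not overlap.

**Posterior predictive simulation** draws, per simulated hermaphrodite, a
posterior (φ, λ) index, brood ~ Poisson(group mean brood), p ~ Beta(λφ,
λ(1−φ)) and hatched ~ Binomial(brood, p); 1500 hermaphrodites per group by
default, zero-brood parents reported with missing viability.

## RAD-51 focus profiling

Nuclei are modelled as spheres (center + radius); the imaging software's
arbitrary surface meshes are out of scope, but the threshold semantics are
preserved: a focus counts toward a nucleus when its distance to the surface —
|center distance − radius|, 0 for interior points — is at most 0.4 μm, and a
focus within threshold of several nuclei counts only toward the nearest
(ties to the lowest nucleus index), so no focus is double-counted.

Positions along the linearized gonad are normalized affinely so pachytene
spans [0, 1] (transition-zone end ↦ 0, pachytene end ↦ 1); the transition
zone maps to negative positions. Sliding windows are closed intervals of
width 0.1 stepped by 0.01 across (−0.25, 1], reporting mean, SEM (sample
SD/√n) and n, omitting empty windows; SEM pools nuclei across germlines.
Stage bins are half-open (low, high] — TZ (−0.25, 0], EP (0, 0.2],
E/MP (0.2, 0.4], MP (0.4, 0.6], M/LP (0.6, 0.8], LP (0.8, 1] — so position 0
falls in the transition zone and 1.0 in late pachytene; the convention only
affects boundary nuclei.

Per bin, genotype pairs are compared with two-sided Mann-Whitney U tests —
exact enumeration for small untied samples (combined n ≤ 20), otherwise the
tie-corrected normal approximation, the usual path since focus counts are
heavily tied — with Holm-Bonferroni adjustment within each bin over the
testable pairs. Pairs with an empty group in a bin are reported missing.

## Synthetic data

Generators emulate the input tables' statistical structure: multinomial
phenotype-class counts over Poisson broods; tracts drawn as an interval
(0, L] anchored at the excision site with configurable length distribution
(default exponential, mean 120 bp) and heteroduplex flips; beta-binomial
broods (the model's own generative process, n = 15 hermaphrodites per
condition matching the study design, broods ~ Poisson with the posterior
simulation's convention); nuclei uniform along (−0.25, 1] with
position-dependent Poisson focus counts; and deletion junctions with exactly
planted microhomology, verified against the maximal-m definition before
emission. Each generator draws from a named stream derived from (seed,
generator name), so outputs are bit-reproducible and adding a generator
never perturbs the others.

What the generators do **not** emulate: transgenerational sterility
dynamics, Mos1 excision efficiency, realistic 3-D gonad geometry, linkage
between windows within a parent, or stage-dependent brood-size trends.
Passing tests therefore demonstrate correctness of the statistics and
recovery of generating parameters under the model's own assumptions — not
robustness to model misspecification in real data.

## Validation scale and numerical choices

Parameter-recovery checks run at the study's design sizes (15 hermaphrodites
per group, broods ~ Poisson(200)): 95% posterior intervals cover the
generating φ in at least 17 of 20 seeded datasets across φ ∈ {0.3, 0.6, 0.9}
× λ ∈ {10, 100}, and a true gamma of 0.5 (φ 0.45 vs 0.9, λ = 50) is
recovered within ±0.07. The replicated gamma-overlap property (two genotypes
with equal true dose effects overlap in ≥ 95% of 50 replicates) uses a
reduced sampler configuration (2 chains, 1000 + 500 draws) chosen for the
suite's turnaround; all other fits use the defaults. Mann-Whitney power for
a twofold focus-rate difference (4 vs 2, 200 nuclei per genotype,
mid-pachytene bin) is estimated from 500 seeded replicates. The Fisher-vs-
enumeration equivalence is exhaustive over all 2×2 tables with total ≤ 24
plus 300 sampled tables with totals 25–40; tract classification is
exhaustive over all 4^5 call vectors on a five-site ladder.

Degenerate inputs: empty broods have likelihood 1; all-hatched groups
produce boundary-concentrated posteriors (the sampler may flag elevated
R-hat there, which is reported, and the posterior median still exceeds
0.95); gamma with a near-zero denominator stays finite via a guarded
division and simply yields a wide interval; all-unreadable tracts raise a
data-quality warning.

## Known limitations

- The sampler is tuned for the 2-parameter per-group posterior; it is not a
  general-purpose MCMC and has no NUTS-style adaptation.
- Mann-Whitney "exact" mode requires untied data; tied small samples fall
  back to the asymptotic approximation.
- The maximum-tract proximal extension and the stage-bin boundary convention
  are documented choices where the measurement definitions are one-sided or
  ambiguous; both are confined to reporting (max_bp) or boundary nuclei.
- Published gamma values are figure-only, so gamma is validated by parameter
  recovery on synthetic data rather than by numeric reproduction.
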