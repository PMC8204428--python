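# Methods

## The generative model

A DNAm site across *n* samples is a vector of DNAm points, each a pair
(methylated reads, read depth). The simulators factor this as:

1. **Depth.** Read depth per point ~ NB(μ_RD, r), parameterised by mean
   and dispersion with variance μ + μ²/r. Depth 0 means the point does
   not exist, so site-level simulation conditions on depth ≥ 1 — and,
   in the filtered-study setting, on depth ≥ the read-depth filter for
   points that must survive it. Truncation is implemented by rejection
   (redraw until the condition holds): a shifted draw (+1) would change
   the mean and distort the shape near the cut, whereas rejection yields
   the exact conditional distribution.
2. **Methylation.** Given depth *d* and site methylation probability
   *p*, methylated reads ~ Binomial(d, p); the observed value is the
   proportion. Group A uses p = μ_DNAm; group B uses
   p = clamp(μ_DNAm + Δ, 0, 1). The model has no extra-binomial
   (biological) overdispersion; power estimates are therefore for the
   measurement process itself.
3. **Testing.** A two-sided Welch (unequal-variance) t-test compares
   the groups' proportions; an equal-variance mode exists behind a
   flag. Power is the exact fraction of simulated sites with p below
   the significance threshold.

Degenerate sites are resolved by convention, never dropped (dropping
would inflate power): both groups constant and equal → p = 1; zero
variance in both groups with different means → p = 0 (perfect
separation); fewer than two usable points in a group → non-significant.

## Dispersion estimation

r is recovered from pooled depths by the method of moments,
r = (μ²/σ²)/(1 − μ/σ²) ≡ μ²/(σ² − μ), with the unbiased (n−1) variance.
This is exact algebra on the NB moments, so the fitted model reproduces
the sample variance identically. When σ² ≤ μ the NB dispersion is
undefined; the estimator raises a dispersion error carrying (μ, σ²),
with an opt-in fallback that caps r at a large value (default 10⁶,
effectively Poisson) and warns. Estimation pools depths across all
sites and samples of the chosen subset — one global (μ, r) — and
excludes depth-0 cells, which denote absent points rather than observed
zeros. Pooling across heterogeneous depth strata attenuates r (mixture
variance exceeds within-stratum variance); this is inherent to pooled
moment estimation and mirrors what happens on real data, where deep
enrichment-core sites coexist with shallow ones.

## Key parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| μ_RD | NB mean read depth | user/estimated | site-level sims explore 1–50+ |
| r | NB dispersion | 1.5 | heavy-tailed depth typical of RRBS |
| p-value threshold | site significance cut | 5×10⁻⁶ | genome-wide scale for sequencing studies |
| n_sites | simulated sites per power estimate | 10,000 | binomial SE ≤ 0.5 pp |
| rd_filter | minimum depth for a point to survive | user | points are KEPT iff depth ≥ rd_filter |
| min_points | minimum surviving points per group per site | user (≥ 2) | a t-test needs 2 per group |
| α (study level) | Bonferroni numerator | 0.05 | conventional family-wise rate |
| n_sim_sites | simulated filtered sites per iteration | 40,000 | stabilises the p-value pool |
| r_subset / prior_subset | sites subsampled for (μ, r) / priors | 60,000 / 100,000 | estimates stabilise well below these sizes |
| n_iterations | independent repeats, median reported | 5 | single runs occasionally produce outliers |

The filter comparison is **≥ rd_filter** (keep iff depth ≥ threshold)
everywhere — filtering, estimation and simulation use one shared
convention. The minimum-points rule is applied per comparison group by
default (a site that cannot field two points per group cannot be
tested); an all-samples mode is available by omitting the group labels.

## Unbalanced designs

For a fixed total sample size, power is maximised by equal groups; when
a ratio such as 60:40 or 80:20 is imposed, the remaining freedom is
which group receives the majority. The two groups have unequal outcome
variance (binomial variance p(1−p) differs between μ_DNAm and
μ_DNAm + Δ), and two-sample power at fixed total n is maximised by
allocating more samples to the higher-variance group (Neyman
allocation). `allocate_groups` therefore assigns the majority share to
the group whose methylation probability is closer to 0.5, and the
sample-size sweep (`minimum_total_sample_size`) walks totals upward in
steps of 2 until the simulated power reaches the target. Under this
allocation a 60:40 design at mean depth 20 (0.25 vs 0.45, Δ = 0.20)
needs ~94–96 samples in total for 80% power, and an 80:20 design
~154–158, versus 92 when balanced.

## Accuracy profiling

With true methylation uniform on [0, 1] and binomial estimation at depth
*d*, the law of total variance gives closed forms

    corr(d) = √(d/(d+2)),      RMSE(d) = √(1/(6d)),

used as the oracle for the Monte-Carlo routines (agreement within 0.01
at 10⁵ points). The truth series itself is the reference for
correlation/RMSE; profiling against an independently measured reference
with matched methylation would shift these statistics by roughly 0.01
(the closed forms bound the difference), which is within the tolerance
of every check performed here.

## Study-level power prediction

Per iteration: (1) estimate (μ_RD, r) from a random site subset and the
site-mean methylation priors — the probabilities that a *filtered*
site's mean lies in [0, 0.05), [0.05, 0.95] or (0.95, 1] — from an
independent subset run through the configured filter; (2) simulate
filtered sites: each group's first `min_points` depths come from
NB(max(μ_RD, rd_filter), r) conditioned ≥ rd_filter (the filtered data
must contain them), the remaining depths from NB(μ_RD, r) masked below
the filter; site means are drawn by picking a range with the prior
probabilities and then uniformly within it; (3) Welch-test every site,
bootstrap the p-values (sampling with replacement) up to the number of
real sites surviving the filter, and take the fraction below
α / n_sites_remaining. The median across iterations is reported (the
mean is also exposed). Site means for the priors are the unweighted
average of a site's unmasked proportions; a read-pooled alternative is
available behind a flag.

## The synthetic cohort generator

The generator emulates the statistical structure of a large RRBS cohort
so that every routine is testable without external data: a
three-component site-mean mixture (49% uniform on [0, 0.05), 1% on
[0.05, 0.95], 50% on (0.95, 1] — the bimodality of genome-wide DNAm),
NB(30, 1.5) depths, a 20% "core" of enrichment-favoured sites covered
in every sample at doubled mean depth (the signature of MspI
enrichment), 30% point dropout elsewhere, and an optional spiked-in
group difference with a retained truth record. Defaults: 50,000 sites ×
125 samples, generated in ~2 s.

What the generator does *not* reproduce: per-site dispersion structure,
correlated methylation between neighbouring sites, batch effects, and
the exact depth-tail fractions of any particular real cohort (with the
default NB(30, 1.5), 8% of points have ≤ 5 reads and 6% have > 100). A
consequence worth noting: because the synthetic matrix is deeper and
denser than typical real RRBS data, aggressive read-depth filters
remove almost no *sites* from it (only points), so filtering shows up
as a power cost rather than the Bonferroni relief that sparse real
datasets can experience. Passing tests on synthetic data therefore
validate the machinery and the qualitative relationships (power
monotone in depth, sample size and effect; U-shaped in mean
methylation; extreme-call inflation at low depth), not any particular
real dataset's magnitudes.

## Numerical notes

- All randomness flows through `numpy.random.Generator`; sweeps derive
  independent child seeds from the caller's generator, so curves are
  reproducible and their points independent. Identical seed + config →
  bit-identical results.
- Truncated sampling refuses to run when the acceptance probability is
  below 10⁻⁶ (estimated from the NB CDF) rather than looping forever.
- Ratio splits round the majority share to the nearest integer and give
  the remainder to the minority, preserving the total exactly.
- Simulation sizes in the test suite are scaled to keep the full run
  fast (5,000–10,000 sites per power estimate, 3 study iterations);
  these sizes put the Monte-Carlo error well inside every asserted
  tolerance.
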