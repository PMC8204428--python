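# rrbspower

Power analysis and simulation for bisulfite-sequencing studies of
differential DNA methylation.

Bisulfite sequencing (RRBS, WGBS, targeted/amplicon assays) measures DNA
methylation at single cytosines as a proportion: methylated reads over
total reads. Two experimental realities limit what such a study can
detect. First, at a read depth of *d* the estimated proportion can only
take *d* + 1 values, so shallow points are coarse and noisy. Second,
coverage is uneven — many (site, sample) cells have few or no reads — so
filtering by minimum read depth and by minimum observations per site
trades accuracy against effective sample size and multiple-testing
burden. `rrbspower` is for researchers planning or filtering such
studies: it quantifies these trade-offs by simulation and predicts the
statistical power of a specific study design under specific filtering
choices.

## Model

A *DNAm site* is a genomic cytosine; a *DNAm point* is one sample's
measurement there, the pair (methylated reads *m*, read depth *rd*),
with methylation value *m*/*rd*. A point with *rd* = 0 does not exist.

Read depth is over-dispersed count data, modelled as negative binomial
with mean μ_RD and dispersion *r*:

    σ² = μ + μ²/r,    and inversely    r = (μ²/σ²) / (1 − μ/σ²)

so *r* is recovered from pooled depths by the method of moments.
Simulated depths are drawn from NB(μ_RD, r) conditioned on surviving the
relevant depth cut (rejection sampling, preserving the NB shape).

A simulated two-group site draws, per sample, a depth and then
methylated reads ~ Binomial(depth, p), with p = μ_DNAm in group A and
p = clamp(μ_DNAm + Δμ_DNAm, 0, 1) in group B. Groups are compared with a
two-sided Welch t-test on the methylation proportions, and **power** is
the fraction of simulated sites with p below the chosen threshold.

The study-level predictor estimates μ_RD, *r*, the group sizes, and the
distribution of site-mean methylation (probabilities of the ranges
[0, 0.05), [0.05, 0.95], (0.95, 1]) from the user's own unfiltered data,
simulates tens of thousands of *filtered* sites — each group's first
`min_points` points are guaranteed to survive the read-depth filter,
the rest are masked when they fall below it — bootstraps the resulting
p-values up to the number of real sites surviving the same filter, and
reports power at the Bonferroni threshold α / n_sites_remaining (median
over several iterations).

## Worked example

Power of a 30-vs-30 comparison to detect a methylation difference of
0.20 (group means 0.25 vs 0.45) at mean read depth 37:

```sh
$ rrbspower power-site --n1 30 --n2 30 --mu-rd 37 --r 1.5 \
    --mu-dnam 0.25 --delta 0.2 --n-sites 10000 --p-value 5e-6 \
    --seed 1 --out power.tsv
wrote 1 power row(s) to power.tsv
$ cat power.tsv
n1  n2  mu_rd  delta  mu_dnam  power   n_sites  threshold  seed
30  30  37.0   0.2    0.25     0.8162  10000    5e-06      1
```

The `power` column is the fraction of 10,000 independently simulated
sites whose Welch p-value fell below 5×10⁻⁶ — this design sits right at
the 80%-power crossing. How estimation accuracy depends on read depth:

```sh
$ rrbspower accuracy --depths 1,5,10,22,50 --n 10000 --seed 1 --out acc.tsv
$ cat acc.tsv
read_depth  pearson_correlation  rmse    n_points
1           0.5812               0.4069  10000
5           0.8465               0.1811  10000
10          0.9125               0.1305  10000
22          0.9580               0.0866  10000
50          0.9812               0.0570  10000
```

Correlation between true and estimated methylation jumps from ~0.58 at
one read to ~0.91 at ten, with diminishing gains after — most of the
accuracy is bought by the first few reads.

For study-level prediction, point `predict-power` at your depth and
methylation matrices (or start from `simulate-data`, which writes a
synthetic cohort with realistic RRBS structure):

```sh
rrbspower simulate-data --seed 1 --out-prefix sim
rrbspower predict-power --depth sim.depth.tsv --meth sim.meth.tsv \
    --delta 0.06 --min-points 2 --rd-filter 10 --seed 1 --out power.json
```

Every command writes a `.run.json` provenance sidecar (parameters and
seed) so any output can be regenerated exactly. All subcommands accept a
YAML config file (`rrbspower --config settings.yaml <subcommand> ...`);
explicit flags win.

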