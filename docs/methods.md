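# Methods

This note documents the statistical procedures implemented in `spiderpref`,
the assumptions behind them, and the design choices made where the
underlying analysis left details open.

## Data model

A cohort pairs a participant table (id, SPQ score 0–30, inclusion flag,
optional age/sex) with a trial table: one row per customization trial with
the instruction (*dangerous* / *harmless*), the spider's orientation
(*approaching* / *withdrawing* / *lateral*) and three feature settings.
Features live on a 10-level grid; files store integer levels 0–9 and the
in-memory representation is `k/9 ∈ [0, 1]`, so both extremes are attainable
and round-trips are bit-exact. A complete session is 24 trials — 12 per
instruction, 8 per orientation, 4 per instruction × orientation cell.
`validate_design` reports deviations without rejecting them; incomplete
participants remain usable downstream.

## Preference summaries

Per participant, feature and instruction, the 12 trial values (pooled
across orientations) are summarized by the mean, the median (midpoint
convention for even counts), or the **MMPD** — mean of the modal part of
the distribution: values strictly above and strictly below 0.5 are counted
(exact 0.5 values are ignored in the count); the side with the larger count
is averaged, re-including the 0.5 values. The MMPD damps occasional slips
on the minority side but polarizes mid-range distributions, which is why
all three statistics are reported side by side. When the two sides tie,
all values are averaged (equivalent to the mean); the tie rule is a package
decision — the procedure's source description is silent — chosen to avoid
an arbitrary side preference.

The **incoherency index** is `x = |p^D + p^H − 1|`: zero when the harmless
setting mirrors the dangerous one (`p^H = 1 − p^D`), one only when both sit
at the same extreme. The grand-average table reports, across participants,
mean and SD of all three statistics per (feature, instruction) cell plus
one incoherency row per feature (computed from the MMPD summaries by
default; configurable).

## Association and power

The correlation matrix uses Spearman's rank correlation with average-rank
tie handling on the participants × 7 matrix (SPQ + six preference
summaries; listwise-complete rows), with two-sided p-values from the
t-approximation on n − 2 degrees of freedom. p-values are reported raw —
no multiple-testing correction — mirroring how such matrices are usually
displayed.

`correlation_power(rho, n, alpha, reps, seed)` simulates bivariate-normal
samples, applies the two-sided correlation test (Pearson by default;
Spearman behind a flag) and reports the rejection fraction with its
Monte-Carlo SE, alongside the Fisher-z closed form
`Φ(√(n−3)·atanh(ρ) − z_{1−α/2}) + Φ(−√(n−3)·atanh(ρ) − z_{1−α/2})`.
At ρ = 0.4, n = 56, α = 0.05 the closed form gives 0.87, consistent with a
recruitment designed for power 0.8. Whether such a design statement refers
to the recruited or the analyzed sample size is ambiguous; the utility
takes `n` as an argument.

## Heteroskedastic spline regression

For response `y` (a preference summary or incoherency index, one value per
participant) and SPQ score `s`:

    y_i ~ Normal(μ(s_i), σ²(s_i)),  μ(s) = B(s)·β,  log σ²(s) = B(s)·γ.

`B(s)` is a natural cubic spline design with one internal knot at the
empirical median of SPQ and boundary knots at the observed extremes: with
one internal knot, three columns (intercept, linear, one curvature term
built from truncated cubic powers), hence six free parameters per fit. The
natural boundary condition makes every fitted curve linear outside the
boundary knots. Any full-rank natural-spline parameterization spans the
same function space, so fitted curves are parameterization-invariant
(verified against an independent basis construction in the tests).

Estimation is joint maximum likelihood: deterministic initialization (β
from OLS on the mean basis; γ intercept at the log ML residual variance,
other entries 0) followed by L-BFGS-B on the analytic gradient, so the
optimizer can only improve on the homoskedastic least-squares start; a
`homoskedastic=True` flag restricts γ to the intercept, which reduces the
mean fit exactly to OLS. Numerical choices: basis columns are rescaled to
unit max-magnitude before optimization (the raw curvature column spans
hundreds of cubic units and ruins quasi-Newton conditioning), the
log-variance is clipped at ±60 to keep line-search probes finite, and
convergence requires optimizer success plus a scaled gradient max-norm
below 1e−4. Display bands are normal quantiles of the fitted distribution:
quartiles μ ± 0.6745σ, deciles μ ± 1.2816σ, so the decile/quartile width
ratio is constant by construction.

Caveat: responses live on [0, 1] but the likelihood is an unbounded
normal, with no truncation correction — faithful to the analysis being
reproduced, but fitted bands can cross the response bounds for extreme
dispersion.

## Clustering and model selection

Responses are z-scored (n − 1 denominator), then clustered agglomeratively
with centroid linkage (inter-cluster distance = Euclidean distance between
centroids, via `scipy.cluster.hierarchy`). Centroid linkage can invert
merge heights; cuts are therefore taken by merge order — undoing the last
k − 1 merges — which is always well-defined (a height-based cut is not,
and scipy's own `cut_tree` mislabels inverted trees). The tree is cut at
k = 2, 3, 4 (k = 1 is deliberately not a candidate) and the partition
minimizing

    BIC = −2 log L + m·log n,
    log L = Σ_k [ n_k log(n_k/n) + Σ_{i∈k} log N(x_i; μ_k, Σ_k) ]

is selected, ties resolving toward smaller k. The default covariance
structure is **tied diagonal** (per-cluster means, one pooled within-cluster
variance per dimension; m = (k−1) + kd + d). This choice matters: with
per-cluster variances, hard-splitting a genuinely homogeneous Gaussian
group always gains about `n_k·log(1/0.36)/2` log-likelihood — more than the
BIC penalty — so the criterion over-splits pathologically; pooling the
variance removes that gain while still detecting well-separated groups.
Per-cluster `diagonal` and `spherical` structures remain available via a
flag. ML variances are floored at 1e−6 per dimension so degenerate
clusters stay finite. Distance ties in agglomeration follow scipy's
deterministic ordering; label numbering is by each cluster's smallest row
index, making results invariant to row order up to relabeling.

Criterion presets mirror the analysis variants: one (feature, instruction)
response at a time, all six, the dangerous or harmless triplet, or all six
plus SPQ.

## Synthetic cohort generator

The generator emulates the study's design and its qualitative findings so
every stage is testable without the original data. Per participant: an SPQ
draw (uniform integers 0–26, matching a cohort "continuously spread" over
that range), a balanced cluster assignment, per-(feature, instruction)
latent means, and 24 trials in pseudo-randomized order; trial values are
latent mean + normal noise, clipped to [0, 1] and snapped to the grid.

Defaults (the reference configuration) and their rationale:

- **Condition means** — the grand-average MMPD row of the study being
  emulated: hairiness 0.33 / 0.75, body/leg 0.34 / 0.71, locomotion
  0.77 / 0.40 (dangerous / harmless).
- **Dispersion** — trial noise `0.08·exp(0.03·SPQ)` and participant-level
  scatter `0.05·exp(0.03·SPQ)`. Both components grow with fear (the
  generalization effect makes fearful participants less consistent); the
  between-participant component exists because the fear-dependent fan-out
  of the real data is visible across participants, and within-person noise
  large enough to carry the whole effect would distort the MMPD grand
  averages through its polarization bias. Magnitudes are a calibration
  choice (the source reports no dispersion figures), set so that grand
  averages stay within ±0.06 of the condition means at n = 45 while the
  variance trend remains detectable by the spline model.
- **Incoherency mechanism** — the dangerous-hairiness latent mean drifts
  by `0.004·(SPQ − 13)`: fearful participants accept less hairy
  "dangerous" spiders, so their settings become less specular and the
  hairiness incoherency rises with SPQ, matching the positive
  SPQ–dangerous-hairiness association of the emulated study. Centering at
  the SPQ midpoint preserves the condition mean. (A drift of the
  *harmless* mean toward the dangerous one cannot reproduce the rising
  incoherency: it first passes through the coherence point, making the
  index non-monotone in fear.)
- **Clusters** — two equal-weight groups with mirrored dangerous/harmless
  offsets (∓0.20 on body/leg, ±0.15 on locomotion), i.e. polarized
  subgroups whose harmless settings are specular to their dangerous ones;
  mirroring means cluster membership cancels out of the incoherency index.
  Hairiness is left unclustered — it is the feature with the smallest
  between-cluster differences in the emulated study — which also keeps one
  response free of cluster-induced spread. Assignment is an exactly
  balanced split (largest-remainder rounding) to keep grand averages
  stable at n = 45.
- **Orientation effect** — dangerous-hairiness trials with an approaching
  spider are shifted by −0.05 (approaching spiders are made hairier).
- **Composition** — 45 participants, 33 women / 12 men (the analyzed
  cohort of the emulated study: 56 recruited − 10 screening exclusions −
  1 drop-out).

What the generator does *not* emulate: trial-order or learning effects
(order is randomized and never analyzed), reaction times, non-normal
response shapes beyond clipping + snapping, and any real-data correlation
between SPQ and cluster membership. Passing tests therefore demonstrate
that the pipeline recovers structure *of the kind assumed here*, not that
the original data satisfy these assumptions.

## Reproducibility

A single pipeline seed drives every stochastic stage through stage-keyed
substream seeds (`stage_seed(seed, name)`), so adding a stage never
perturbs earlier draws. Identical config + seed reproduces the report
bundle byte for byte; the bundle carries a provenance block (config hash,
seed, package version). Bundle writes are staged and moved into place only
when every artifact serialized, so a failed run leaves no partial output.

## Problem sizes used by the test suite

Monte-Carlo checks run at: 20,000 replicates for the power estimate;
100 replicates of n = 450 for spline mean-curve recovery (mean RMSE
< 0.05) and 100 reference cohorts (n = 45) for the variance-trend sign;
100 seeds per blob scenario for BIC model selection; 50-point inputs for
the naive-linkage cross-check; 100 reference cohorts for the qualitative
preference ordering; 40–100 cohorts for the generator's dispersion and
incoherency properties. The full suite completes in well under a minute
per heavy test on a single CPU.

## Known limitations

- The normal likelihood ignores the bounded, gridded nature of the
  response; bands are display approximations.
- The MMPD is biased toward the heavier side of mid-range distributions;
  comparisons across the three statistics are part of the design.
- BIC cluster counts on small cohorts are descriptive, not inferential:
  singleton "outlier" clusters can be selected, and the covariance
  structure is an interpretation (see above), not something the emulated
  analysis specifies.
- The power utility assumes bivariate normality of the correlated pair.
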