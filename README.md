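# spiderpref

Analysis pipeline for **spider-customization preference experiments**: studies
in which participants tune perceptual features of a virtual spider —
hairiness, body/leg proportions, locomotion pattern — to make it look *as
dangerous* or *as harmless* as possible, while their spider fear is measured
with the Spider Phobia Questionnaire (SPQ, 0–30). The package is aimed at
behavioral researchers who want to re-run or extend this analysis on their
own trial-level data, and at methodologists interested in the robust summary
statistic and the fear-dependent dispersion model it implements.

Each feature is set on a 10-level grid mapped to [0, 1]
(0 = hairy / thick / butterfly-like, 1 = hairless / slim / spider-like). A
complete session is 24 trials per participant: 12 per instruction and 8 per
spider orientation (approaching / withdrawing / lateral).

## What it computes

- **MMPD** (*mean of the modal part of the distribution*) — a robust
  per-participant preference summary: count trial values strictly above and
  strictly below 0.5 (exact 0.5 ignored in the count), then average only the
  majority side, re-including the 0.5 values; compared side by side with the
  mean and median.
- **Incoherency index** `x = |p^D + p^H − 1|` for a participant's summarized
  dangerous (`p^D`) and harmless (`p^H`) preferences: 0 when harmless
  settings exactly mirror dangerous ones, 1 when both sit at the same
  extreme.
- **Spearman correlation matrix** of SPQ and the six preference variables,
  with two-sided p-values, plus a Monte-Carlo / Fisher-z **power utility**
  for correlation designs.
- **Heteroskedastic spline regression**: for a response `y` (a preference
  summary or an incoherency index) and SPQ score `s`,

  ```
  y ~ Normal(μ(s), σ²(s)),   μ(s) = B(s)·β,   log σ²(s) = B(s)·γ,
  ```

  where `B(s)` is a natural cubic spline basis with one internal knot at the
  empirical SPQ median; β and γ are estimated jointly by maximum likelihood,
  and quartile/decile display bands are normal quantiles of the fit.
- **Hierarchical clustering** of standardized responses with centroid
  linkage, cut at k = 2, 3, 4; k is chosen by minimizing the BIC of a
  Gaussian partition model (`BIC = −2 log L + m log n`).
- A **synthetic cohort generator** reproducing the study design (45
  participants × 24 trials, SPQ spread 0–26, condition means, SPQ-dependent
  dispersion, polarized subgroups), so the whole pipeline runs with no
  external data.

## Worked example

```python
import spiderpref as sp

cohort = sp.generate_cohort(sp.reference_config(seed=1))
grand = sp.grand_average_table(cohort)
```

Running `python examples/01_simulate_and_summarize.py` prints:

```
cohort: 45 participants, 1080 trials
balanced 24/12/8 design: ok

Grand averages (mean across participants, SD in brackets):
    mean: body-dang 0.35 (0.23)  body-harm 0.72 (0.19)  hair-dang 0.32 (0.08)  hair-harm 0.74 (0.08)  loco-dang 0.76 (0.16)  loco-harm 0.40 (0.17)
  median: body-dang 0.34 (0.22)  body-harm 0.73 (0.21)  hair-dang 0.31 (0.09)  hair-harm 0.74 (0.09)  loco-dang 0.77 (0.17)  loco-harm 0.40 (0.19)
    mmpd: body-dang 0.35 (0.24)  body-harm 0.73 (0.20)  hair-dang 0.31 (0.09)  hair-harm 0.75 (0.07)  loco-dang 0.78 (0.14)  loco-harm 0.41 (0.20)
  incoherency: bodyleg 0.12 (0.11)  hairiness 0.09 (0.08)  locomotion 0.19 (0.12)
```

Dangerous spiders come out hairy, thick and spider-like (cells near 0, 0 and
1 respectively), harmless spiders the mirror image, and incoherency is small
— the qualitative structure the generator is calibrated to. The other
examples fit the fear regression (`03`, showing dispersion bands that widen
with SPQ), compute the correlation matrix and design power (`02`: Monte-Carlo
power 0.875 ± 0.002 vs Fisher-z 0.870 for ρ = 0.4 at n = 56), cluster
participants (`04`) and run the full pipeline (`05`).

The same stages are available from the shell:

```bash
spiderpref simulate --seed 1 --out data/
spiderpref run --out report/        # simulate → summarize → correlate → splinefit → cluster
```

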