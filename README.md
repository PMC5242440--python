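# catfda

Functional data analysis of collar-mounted accelerometer activity in cats,
built for studying how degenerative joint disease (DJD) and its associated
pain reshape the daily activity pattern.

Accelerometers on cat collars report unit-less activity "counts" per
one-minute epoch — 1440 values per day. Classical analyses collapse these to
a single mean per period and discard the *pattern* of activity: the overnight
trough, the sharp morning peak, the broad evening peak, and the way weekends,
age and joint pain deform them. This package treats each cat's day as a
curve and provides the complete functional-data workflow for such studies:
preprocessing, functional principal components analysis (FPCA),
function-on-scalar regression with time-varying coefficients, and two
families of functional hypothesis tests — together with a seeded synthetic
cohort generator that emulates the data structure of a real case-control
study (cats with and without DJD), so the entire chain is testable end to
end without any data download.

## The model

Counts are transformed to `ln(1 + x)` per minute and averaged over 5-minute
intervals, giving each cat a 288-point daily curve. Per cat `i` in group `G`,
daily curves from 7 baseline days are averaged within day type (5 weekdays, 2
weekend days) into activity profiles `Y_Gi(t)`, and intensity profiles

    I_Gi(t) = Y_Gi(t) − Ave(Y_Gi)

subtract the cat's scalar 7-day grand mean, removing cat- and
device-specific level effects.

**FPCA** decomposes curve variability as

    Y_i(t) = μ(t) + Σ_k φ_k(t) ξ_ik + ε_it

with orthonormal eigenfunctions `φ_k`, eigenvalues `λ_k` and per-cat scores
`ξ_ik`; modes of variation `μ(t) ± 2√λ_k φ_k(t)` visualize each component,
and score correlations link a cat's weekend and weekday behavior.

**Function-on-scalar regression** models covariate effects that vary over
the day,

    Y_i(t) = β_0(t) + Age_i β_1(t) + BCS_i β_2(t) + (Age·BCS)_i β_3(t)
             [+ TDJD_i β_4(t) + TPain_i β_5(t)] + ε_i(t),

with standardized covariates, penalized-spline coefficient curves (cubic
B-splines, difference penalty, GCV smoothing), and 95% pointwise confidence
bands from a subject-level bootstrap.

**Inference** offers (1) simulation-based likelihood-ratio tests of
mean-curve equality — two-group with optional covariate adjustment, and
paired weekend-vs-weekday — whose null distributions come from resampling
whole residual curves or sign-flipping difference curves; and (2) the
projection-based two-sample Anderson–Darling test of whether two groups'
curve *distributions* (not just means) coincide, applied to FPCA scores with
Bonferroni control across components.

## Worked example

```python
import numpy as np
from catfda import GeneratorConfig, generate_cohort, fit_fpca
from catfda.preprocessing import profile_from_series
from catfda.fpca import score_correlation
from catfda.inference import lrt_paired_daytype

config = GeneratorConfig(seed=42, n_per_group=(("Normal", 15), ("DJD", 25)))
series, covariates, truth = generate_cohort(config)

by_cat = {}
for day in series:
    by_cat.setdefault(day.cat_id, []).append(day)
profiles = {cid: profile_from_series(days) for cid, days in sorted(by_cat.items())}

djd = [cid for cid, g in zip(covariates.cat_id, covariates.group) if g == "DJD"]
weekday = fit_fpca(np.array([profiles[c].I_weekday for c in djd]), k_select=3)
weekend = fit_fpca(np.array([profiles[c].I_weekend for c in djd]), k_select=3)
print("weekday variance explained:",
      ", ".join(f"{v:.2%}" for v in weekday.var_explained))
print("FPC1 weekend-weekday score correlation:",
      round(score_correlation(weekend.scores, weekday.scores, 1), 2))

test = lrt_paired_daytype(
    np.array([profiles[c].Y_weekday for c in djd]),
    np.array([profiles[c].Y_weekend for c in djd]),
    n_sim=500, seed=0,
)
print(f"weekend vs weekday LRT: statistic={test.statistic:.1f}, p={test.p_value:.4f}")
```

prints

```
weekday variance explained: 43.73%, 22.66%, 14.42%
FPC1 weekend-weekday score correlation: 0.59
weekend vs weekday LRT: statistic=1064.4, p=0.0020
```

The first three principal components capture ~81% of the DJD cats' weekday
intensity variability; a cat loaded positively on FPC1 on weekends tends to
load positively on weekdays too (r = 0.59); and the weekend activity pattern
differs significantly from the weekday one (the planted weekend morning-peak
delay is detected at p = 0.002, the resolution limit of 500 simulations).

## Command line

The same workflow is scriptable via the `catfda` CLI:

```sh
catfda simulate --seed 1 --outdir cohort          # synthetic cohort CSVs
catfda run-all  --seed 1 --outdir results         # the full analysis
catfda report   --outdir results                  # plots + summary tables
```

`run-all` executes, in order: cohort generation or ingest, preprocessing,
the pooling check between the two DJD sub-studies, pooled group profiles,
FPCA per group and day type, both regression models with bootstrap bands,
the Normal-vs-DJD likelihood-ratio test table, paired weekend-vs-weekday
tests, and the distribution tests — every artifact a CSV plus a JSON run
manifest, byte-identical on rerun with the same seed. Resampling sizes
default to desk-scale values (`n_sim=200`, `n_boot=200`, `n_perm=499`);
`--headline` switches to 10,000 simulations / 2,000 bootstrap draws.

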