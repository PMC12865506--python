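# vocalphen

Vocal phenology from passive acoustic monitoring.

Autonomous recording units paired with AI species classifiers (BirdNET and
kin) produce enormous streams of confidence-scored species labels, but
turning those label streams into defensible statements about *when* birds
are vocally active — onset, peaks, decline, duration of the vocal season —
requires a chain of statistical steps that is easy to get subtly wrong.
`vocalphen` implements that chain end to end for ecologists working with
classifier output tables:

1. **Precision calibration** — fit `logit pr(TP) = b0 + b1·CS` to manually
   reviewed clips sampled over two confidence-score ranges, solve the
   species-specific score threshold where fitted precision reaches a target
   (`CS* = (logit 0.95 − b0)/b1`), and discard labels below it.
2. **Call density** — convert retained labels plus a recording-effort
   inventory into a daily binomial success rate per species × site × day
   (labels ÷ analyzed 3-s segments), which normalizes unequal effort.
3. **Hierarchical smooth** — for each species × elevation stratum with ≥ 5
   detected sites, fit a binomial GAM: a rank-7 penalized spline of ordinal
   day plus Gaussian site random intercepts,

       k_sd ~ Binomial(n_sd, p_sd),  logit p_sd = a + f(day) + b_site,

   with smoothing and random-effect variance chosen by a restricted-
   likelihood criterion, and predict the population-level daily curve.
4. **Phenometrics** — extract qualifying peaks (≥ 30% of the seasonal
   maximum), half-rises, half-declines, and the phenoperiod (first half-rise
   to last half-decline, with boundary fallback when the season window
   truncates the curve), then summarize by migratory strategy × stratum.

A synthetic-data module generates complete study datasets — sites,
staggered deployments, effort, score-dependent true and false labels,
validation outcomes, and known truth curves — so every stage is testable
without field data. See `docs/methods.md` for the model details and design
choices.

## Worked example

Simulate a six-species community (30 sites per stratum, 120-day season,
2800 analyzed segments per site-day) and run the full pipeline:

```python
import vocalphen as vp
from vocalphen import synthetic

cfg = synthetic.make_paper_like_community(seed=11)
study = synthetic.simulate_study(cfg)
res = vp.run_frames(study.detections, study.sites, study.effort,
                    study.validation, synthetic.community_traits(cfg))

print(res.thresholds[["species_code", "cs_threshold", "fraction_retained"]])
print(res.phenometrics[["species_code", "stratum", "peak_days",
                        "start_day", "duration_days", "start_is_boundary"]])
print(res.lags.peak_lag_days.mean())
```

The calibration stage solves one retention threshold per species, e.g.

```
species_code  cs_threshold  n_total  n_retained  fraction_retained
        IRRA         0.616    33848       17673              0.522
        LDMA         0.209    55719       47229              0.848
        RBIM         0.567    92295       74211              0.804
```

— the irruptive species needs a 0.616 score floor to reach 95% precision
and keeps 52% of its labels. The extracted phenometrics read:

```
species_code stratum peak_days  start_day  duration_days  start_is_boundary
        RBIM     Low   123;169        106             79              False
        RBIM     Mid   138;185        119             82              False
        REAR     Low       116         92             46               True
        LDMA     Low       156        142             30              False
```

RBIM is bimodal (second vocal peak 46 days after the first, in both
strata); the early resident REAR is already within 30% of its seasonal
maximum on the first modeled day, so its Low-stratum onset is a flagged
boundary date rather than a half-rise; the long-distance migrant rises late
and briefly. The mean Mid-minus-Low peak lag across species prints `17.0`
days, recovering the elevational delay built into the community truth.

The same stages are available from the shell:

```
vocalphen simulate --seed 11 --out data/
vocalphen calibrate --validation data/validation.csv --target 0.95 --out thresholds.csv
vocalphen run-all --config pipeline.yaml
```

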