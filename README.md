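# emocascade

Cascade-level analysis of how emotions in social-media posts relate to
their propagation through reshares, built for researchers studying
emotional contagion after shocking public events (the motivating case is
celebrity suicides and the associated copycat risk).

A post and all of its reshares within a 21-day post-event window form a
**cascade** (size = reshares + 1; only posts reshared at least once
qualify). Each cascade is scored on five propagation measures — size,
lifetime, median inter-reshare delay, time to the fifth reshare, and
burstiness as the coefficient of variation σ/μ of inter-event gaps
(CV > 1 means bursts beyond a memoryless process) — and labelled with a
**dominant emotion**, the argmax of its root post's 7-way probability
vector over {anger, disgust, fear, joy, sadness, surprise, neutral}.
The regression layer then fits, for every measure DV,

    DV = β0 + β1a·Anger + β1b·Fear + β1c·Sadness + β1d·Joy
       + β1e·Surprise + β1f·Disgust + β2·Event + β3·CONTROLS + ε

with neutral as the base emotion, event fixed effects, and author/text
controls — negative-binomial (dispersion profiled by ML) for size, OLS
for the rest — and reports both model-based and CR1 cluster-robust
standard errors clustered on the event (t reference with G−1 df; a
warning is emitted when clusters are few). A per-emotion (+)/(−)/(0)
sign-pattern table summarizes the battery.

Because reshare logs of this kind are proprietary, the package ships a
seeded synthetic generator (`ScenarioConfig` + `gen_event_stream`) that
emulates their structure — right-skewed NB sizes with ~67% size-two
cascades, regular and bursty (Markov-modulated exponential) delay
regimes, Dirichlet emotion vectors, heavy-tailed author covariates —
and returns the generating parameters, so every estimator is testable
by parameter recovery. See `docs/methods.md` for the model and its
assumptions.

## Worked example

```python
import emocascade as ec

config = ec.ScenarioConfig.corpus_like(n_cascades=5000, seed=7)
events, authors, truth = ec.gen_event_stream(config)
cascades = ec.build_cascades(events, event_start_s=0.0, window_days=21)
features = ec.summarize_features(cascades, authors)

print("share of size-two cascades: %.3f" % (features["size"] == 2).mean())
print(ec.emotion_frequency_table(features)["ALL"].round(1))

fits = ec.run_model_battery(features)
print(ec.sign_pattern(fits))
```

prints

```
share of size-two cascades: 0.666
emotion
anger        4.0
disgust      2.0
fear        40.4
joy          4.2
neutral     11.5
sadness     33.2
surprise     4.8
Name: ALL, dtype: float64

         size lifetime speed burstiness
emotion
anger       0        -     +          +
disgust     0        0     0          +
fear        0        0     -          0
joy         0        0     -          0
sadness     0        0     0          0
surprise    0        -     0          0
```

Two-thirds of the cascades are a single original post plus one reshare,
and the emotion mix is dominated by fear and sadness — the structure
the generator is calibrated to. In the sign table, read "speed +" as
*faster* resharing (a negative median-delay coefficient): at this
moderate sample size, anger shows fast, bursty, short-lived cascades
while most other effects are not separable from neutral under
event-clustered inference with only four events; effects sharpen as
`n_cascades` grows.

The same pipeline runs from the shell:

```
emocascade simulate --preset corpus_like --n-cascades 5000 --seed 7 --out sim/
emocascade analyze --events sim/events.jsonl --authors sim/authors.csv --out out/
emocascade report --analysis-dir out/
emocascade recover --preset recovery --reps 100 --seed 1 --out rec/
```

`analyze` writes the feature table, emotion frequency/intensity tables,
the cohort summary, all 14 regression fits (CSV + JSON), the
sign-pattern table, an observation-count funnel and a manifest carrying
the seed, config hash and any warnings. Real data can be supplied in
the same JSONL/CSV schemas (`emocascade.ingest` documents the columns;
emotion scores must sum to one, with `--score-policy renormalize`
available for near-misses).

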