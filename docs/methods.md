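# Methods

## The analysis

`emocascade` studies how the emotional content of a social-media post
relates to the way it propagates through reshares after a shocking
public event (the motivating case is celebrity suicides, where emotional
amplification is a public-health concern — the "Werther effect").

The unit of analysis is the **cascade**: an original post plus the full
time-ordered series of its reshares within a fixed observation window
after the event (21 days by default; post-event activity typically
decays within two to three weeks). Only posts reshared at least once
form a cascade, so every cascade has size ≥ 2. Reshare-graph edges (who
reshared from whom) are treated as unobserved; all temporal structure
comes from the timestamp sequence alone.

Each cascade is reduced to five propagation measures:

| measure | definition | unit |
|---|---|---|
| size | number of reshares + 1 | posts |
| lifetime | last reshare time − root time | s (min in summaries) |
| median delay | median gap between consecutive events | s |
| time to 5th reshare | 5th reshare time − root time; defined iff ≥ 5 reshares (size ≥ 6) | s |
| burstiness CV | σ/μ of inter-event gaps (sample SD, ddof = 1) | — |

CV > 1 indicates temporal clustering beyond a memoryless (Poisson)
process; CV < 1 indicates regular spacing. The CV is scale-invariant;
lifetime and median delay scale linearly with time units.

Each post carries a 7-way probability vector over {anger, disgust, fear,
joy, sadness, surprise, neutral} produced by an upstream classifier
(consumed, never run here); the cascade's **dominant emotion** is the
root's argmax label, with exact ties broken by the fixed alphabetical
order so assignment is deterministic.

## The regression layer

Every propagation measure is regressed on the same specification:

    DV = β0 + β1a·Anger + β1b·Fear + β1c·Sadness + β1d·Joy
       + β1e·Surprise + β1f·Disgust + β2·Event + β3·CONTROLS + ε

with neutral as the base emotion, event fixed effects (first sorted
label as base), and controls log(1+followers), log(1+friends),
log(1+statuses), log(1+likes), verified, word count, hashtag. Durations
enter as log(1+x) — lifetime in minutes, delays in seconds, matching the
summary-table units — because their minima are zero; CV enters raw.

Size is a count and is fit by **negative-binomial (NB2)** regression
with log link; the dispersion θ (variance μ + μ²/θ) is profiled by
maximum likelihood: each profile point is an IRLS fit with α = 1/θ held
fixed, and a bounded 1-D search over log α picks the optimum, so NB
nests Poisson as α → 0. Reported NB standard errors condition on the
profiled dispersion (the convention of standard NB implementations).
A Poisson fit is available for comparison. All other measures are fit
by OLS.

The **model battery** comprises 14 fits: NB size and OLS log-lifetime at
size thresholds {≥2, ≥3}, and OLS log median delay, log time-to-fifth
and CV at ≥6 (the "at least five reshares" regime), each with and
without the emotion dummies. Rows with an undefined DV are dropped
listwise per model.

### Cluster-robust inference

Errors are allowed to correlate within an event: a CR1 sandwich
clusters scores on the event label, with small-sample factor
G/(G−1)·(n−1)/(n−k). For OLS the scores are xᵢeᵢ with bread (X'X)⁻¹;
for the count models the estimating-equation scores are
xᵢ(yᵢ−μᵢ)/(1+αμᵢ) (α = 0 for Poisson) with the model-based covariance
as bread. With a handful of events (G = 4 in the headline design) the
estimator is noisy, so a small-G warning is emitted and all cluster
inference — p-values, sign-pattern significance, recovery confidence
intervals — uses a t reference with G−1 degrees of freedom; the normal
critical value is known to undercover badly at G = 4 (we measure ~81%
for nominal 95% in the recovery experiment, vs ~93% with t₃).

The **sign pattern** summary reduces the with-emotions fits to a
per-emotion (+)/(−)/(0) table over {size, lifetime, speed, burstiness}
at α = 0.05 on the cluster-robust p-values. "Speed" is read off the
median-delay model with the sign inverted: a negative delay coefficient
means faster resharing.

## The synthetic generator

Real reshare logs of this kind are proprietary, so the generator
emulates their statistical structure and every claim the tests make is
a claim about recovery of known ground truth. Per cascade:

1. an event stratum, root author, dominant emotion and text features
   are drawn;
2. the reshare count is 1 + NB(mean = exp(x·β_size), θ), so sizes start
   at 2 — matching the analysis universe of posts reshared at least
   once (a hurdle for "ever reshared" is deliberately not modelled);
3. reshare offsets have mean gap exp(x·β_delay) seconds, drawn either
   i.i.d. exponential ("regular", CV ≈ 1) or from a two-state
   Markov-modulated exponential ("bursty": a slow and a fast state with
   rate ratio r, switching between gaps with probability p from a
   symmetric start). The MME preserves the mean gap while pushing the
   inter-event CV above one; it was chosen over a Hawkes process
   because two parameters suffice for the property under study and the
   draw is exactly reproducible. There is no canonical generative
   model for reshare delays — this regime structure is the package's
   own stand-in, and it is configurable;
4. one root record plus one record per reshare are emitted, reshares
   carrying the root's scores and text features.

Emotion score vectors are Dirichlet draws with unit concentration
except the dominant label (concentration 8 by default, → 1 as it grows);
draws whose argmax disagrees are rejected, so the dominant label holds
by construction. Author covariates are floors of log-normals with point
mass at the legal minimum (zeros attainable), verified ~ Bernoulli(0.04);
word counts ~ round N(16.3, 7.2) clipped to [3, 37], hashtags ~
Bernoulli(0.28). Randomness is counter-based: every cascade derives its
own substream from (master seed, cascade index), so streams are
reproducible and order-independent.

Named scenarios (frozen study conditions):

* **`corpus_like`** — four event strata; emotion frequencies fear 40.3%,
  sadness 33.1%, neutral 11.1%, surprise 5.0%, anger 4.4%, joy 4.0%,
  disgust 2.0%; emotion/event/covariate effects at empirically realistic
  magnitudes. The size intercept (0.3575) and dispersion (θ = 0.143)
  were calibrated once, by simulating the covariate mixture, so that
  P(size = 2) ≈ 0.67 and mean size ≈ 5.4; they are frozen constants.
  Limitation: an NB2 around mean 3.36 cannot simultaneously match that
  mean, the 67% zero-excess share and a marginal SD of ~40 — the
  generator's size SD is ~14, so the extreme tail is thinner than real
  streams.
* **`recovery`** — uniform emotion frequencies (every emotion ~1/7), so
  all six emotion coefficients are well identified at moderate n;
  effects of comparable magnitude, θ = 0.8. Used for bias/coverage
  experiments: skewed real-world frequencies would leave rare emotions
  (disgust at 2%) with ~100 cascades per 5,000-cascade replicate and
  per-coefficient bias estimates dominated by Monte-Carlo noise.
* **`disgust_positive`** — disgust prevalence raised to 10% and effects
  (+1.2 on log mean reshare count, −0.25 on log mean gap, bursty with
  rate ratio 6) calibrated jointly by simulating the generative
  channels so the *implied* ground truth is (+size, +lifetime, faster,
  burstier). Lifetime is not a free parameter — it emerges from size ×
  delay, and the bursty regime, though mean-preserving, lowers
  E[log gap] by ½·log(4r/(r+1)²) (≈ −0.85 at r = 20, ≈ −0.29 at r = 6),
  which is why a naive parameterization can silently flip the lifetime
  sign.

What passing tests show — and do not show. Recovery and sign-pattern
results demonstrate that the pipeline's estimators are consistent and
its inference calibrated *under the generator's assumptions*
(independent cascades, NB sizes, MME gaps, emotion scores independent
of covariates). Real streams have features the generator omits:
follower-graph topology, circadian and news-cycle rhythms, author
self-selection into emotions, retweet-of-retweet dynamics, and far
heavier size tails. Results on real data inherit none of the
synthetic guarantees.

## Numerical choices and degenerate inputs

* Timestamp ties are legal (zero gaps occur); ordering ties break on
  event id, so assembly is deterministic.
* A CV is undefined (NaN) with fewer than two gaps or zero mean gap;
  time-to-fifth is undefined below size 6. Undefined metrics propagate
  as NaN and are dropped listwise per model with a logged count.
* Inter-event gaps include the root→first-reshare gap by default
  (`include_root=True`), so gaps telescope exactly to the lifetime;
  the reshare-only convention is a flag, since "delay between
  consecutive retweets" is also defensible. Summaries and regressions
  use the default.
* Orphan reshares (root absent or outside the window) are dropped, not
  promoted to roots — a cascade requires its original post.
* The dispersion profile searches log α ∈ [−12, 5] with xatol 1e-6; at
  the lower boundary θ ≈ 1.6·10⁵, numerically Poisson.
* All-zero design columns (e.g. emotion dummies on a neutral-only
  subset) are dropped with a log note; genuine collinearity raises an
  error naming the columns.
* Generator cascades whose drawn offsets would overrun the observation
  window are rescaled into it (multiplicatively); this touches only the
  extreme tail and keeps every timestamp inside the window, at the cost
  of slightly distorting the delay channel there.
* The battery's NB size models use the full size as the response
  (matching the analysis convention of counting the root); the recovery
  harness instead fits size − 2, the generator's own NB channel, so the
  ground-truth coefficients are identified. `build_design` exposes
  both, plus reshare counts (size − 1).

## Problem sizes

Default experiment sizes were chosen to make Monte-Carlo error small
relative to the effects under study: 20,000 cascades for the
distribution-matching and sign-pattern checks (binomial SE of the
size-two share ≈ 0.3%), and 100 replicates × 5,000 cascades for
recovery (SE of a mean bias ≈ 0.008 per coefficient). The acceptance
script runs a 40 × 3,000 recovery, which keeps its runtime at a few
minutes while leaving bias noise well under the 0.05 criterion.

## Known limitations

* Four clusters is few; CR1 + t₃ is a pragmatic choice and a wild
  cluster bootstrap would be the next step (out of scope here).
* The generator draws emotions independently of author covariates, so
  it cannot exercise confounding between emotion and authorship.
* Weighted precision/recall/F1 validates a scorer against human labels
  only when such labels are supplied; the package ships no classifier.
* Structural virality, cascade depth and who-reshared-whom inference
  are out of scope (edges unobserved).
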