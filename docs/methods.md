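# Methods

This note documents the models implemented in `cpuerecon`, the synthetic
data they are exercised on, and the numerical and design choices made where
the procedures admit more than one reasonable reading.

## 1. Fish-number estimation (`fishnum`)

**Model.** Landing records of 80–350 kg are taken to represent single fish
(`build_wpf`), giving an empirical weight-per-fish (WPF) sample. The
normal-vs-lognormal diagnostic (`choose_wpf_model`) fits both families by
moment matching (the lognormal on log weights) and picks the family with
the smaller two-sample KS D against the data; the comparison sample is an
equal-sized quantile grid from the fitted law, which makes the diagnostic
deterministic. The Monte Carlo table (`simulate_weight_by_count`) sums k
draws with replacement from the *empirical* WPF sample (k = 1…50, 10,000
replicates by default): bootstrap rather than fitted-model sampling keeps
the step faithful to the record-constructed distribution; the fitted model
is only a diagnostic. Count assignment (`assign_fish_counts`) bins each
record's weight into a 10-kg window and draws k with probability
proportional to the frequency of simulated k-fish totals in the window,
optionally reweighted by a prior over counts.

**Choices.**
- Window width 10 kg, configurable; the weight bands are realized as
  histogram bins of the simulated totals.
- Records whose window contains no simulated total for any k (e.g. a
  weight below one minimum fish) are flagged `unassignable` and kept, not
  dropped.
- KS p-values are asymptotic (`scipy.stats.ks_2samp`, `method="asymp"`).
- Within-bin selection is frequency-proportional (an implicit uniform
  prior over counts); a count prior can be supplied but is not defaulted,
  since the generating count distribution is unknown for real data. On
  the synthetic fishery this choice recovers annual totals to within a
  few percent with 30% of counts masked.

## 2. Fishing-day classification (`tracks`)

Days are vessel-by-local-calendar-date partitions of hourly track points
(UTC+8 boundary; the fishery operates in a single time zone; at least 3
points to classify). Distances are haversine on a 6371-km sphere; headings
are forward azimuths between consecutive positions, because a recorded
heading field may be absent.

The three criterion families:

- **speed** — fishing iff any hourly speed ≤ x kn (x = 1…7). "At x knots"
  is read as ≤ x: slow reports signal hook retrieval, and an equality test
  would be measure-zero. The comparison is configurable.
- **distance** — fishing iff the cumulative within-day path length
  (sum of consecutive segments, not net displacement) < x km
  (x = 70…190 by 10).
- **direction** — positions resampled at 1–6 h (earliest point plus the
  point nearest each successive offset), heading changes folded to
  [0°, 180°], fishing iff the maximum change ≥ x° (x = 5…180 by 5).
  The literal phrasing "change within x degrees" would classify straight
  transits (change ≈ 0°) as fishing; a turn detector is the reading
  consistent with the retrieval turn-around and with an optimal angle near
  90°. A `rule="within"` flag restores the literal comparison for
  fidelity experiments. Segments shorter than 50 m are skipped when
  computing azimuths — a stationary vessel's GPS jitter carries no heading
  information.

Criteria are scored against labelled days by TP/FN/FP/TN and the derived
TPR (sensitivity), TNR (specificity), SSS = TPR + TNR and
DSS = |TPR − TNR|. `grid_search` evaluates every cell, takes the largest
SSS, and resolves ties within an SSS tolerance of 0.01 ("similar" SSS) by
the smallest DSS, then by grid order.

## 3. Effort reconstruction (`effort`)

At-sea days are the number of distinct local calendar dates intersected by
[depart, return] — matching port-log granularity rather than duration/24.
Screening (invented where the source procedure says only "screened for
accuracy"): unparseable rows, return ≤ depart, durations over 60 days, and
overlapping same-vessel trips are moved to a rejects report.

Per (port, vessel class) the through-origin slope is b = Σxy/Σx²; both
R² conventions are reported because the uncentered one
(1 − SSE/Σy²) is never below the centered one (1 − SSE/Σ(y−ȳ)²) and can
materially overstate the fit. The supporting ANOVA is sequential (type I)
in the order at-sea days, port, class, computed from nested OLS fits.
Predictions are fractional (slope × at-sea days, clipped to at-sea days);
rounding is deferred to wherever effort is summed. A trip whose group was
not fitted falls back to the pooled port-level slope, with a logged count.

## 4. Delta-lognormal standardization (`standardize`, `mixedglm`)

The trip-level CPUE series is modelled in two parts: a binomial GLMM on
the positive-catch indicator (ZPM) and a Gaussian mixed model on log CPUE
over positive trips (PCM). Fixed factors are treatment-coded year (always
included), month, vessel size class, and — in the area-combined design —
fishing area; random terms are year-by-month and year-by-class interaction
cells as iid N(0, σ²_f) intercepts with one variance per term.

**Estimation.** Both components maximize the *marginal* likelihood:

- PCM: the random effects integrate analytically; β and σ² are profiled
  in closed form and only the log variance ratios are optimized
  (Nelder–Mead over at most two parameters, Woodbury identities on the
  q ≤ 60-dimensional random-effect space). The fit agrees with
  `statsmodels` MixedLM under ML to numerical precision (tested).
- ZPM: a Laplace approximation. Bernoulli responses are first aggregated
  to covariate cells; for given (β, log σ) the random-effect mode is found
  by Newton steps with the exact dense Hessian, and the outer parameters
  are optimized by BFGS. The reported log-likelihood is on the Bernoulli
  scale (no binomial coefficients) so AIC/BIC are directly comparable with
  a plain logistic fit of the same records. A variance driven to the
  lower bound is reported as a converged boundary fit — it is the fixed-
  effects model plus one wasted parameter, and model selection discards it
  on the criterion.

AIC = −2ℓ + 2k and BIC = −2ℓ + k log n with k = fixed effects + one
variance per random term (+ the residual variance for the PCM). Candidates
that fail to converge are skipped with a warning, mirroring the practice of
discarding nonconvergent interaction runs.

**Selection** (`stepwise_select`): backward elimination over fixed mains
from the full main-effects model (year protected), then forward addition
over the random interaction candidates, each step keeping the move that
lowers the chosen criterion. Selection runs under plain maximum
likelihood throughout so criteria are comparable; no restricted-likelihood
refit is applied, since every reported quantity (year LSmeans, variances)
comes from the same ML fit being selected.

**Index.** Year least-squares means average the model's cell predictions
(including random-effect BLUPs) over the non-year factor levels with
weights proportional to those levels' observation counts, the same margins
for every year — the count-weighted margin is the declared reading of the
"weighted factor proportional to the number of observations". ZPM means
are averaged on the probability scale. The annual index is

  Index_y = p̂_y · exp(μ̂_y + σ̂²/2),

with σ̂² the PCM residual variance — the standard first-order lognormal
back-transform correction; the finite-sample refinement of this correction
is not implemented, as the simple form is exact in the limit the tests
operate in and the relative index is insensitive to a year-constant
factor. Confidence intervals combine the LSmean variance with the
binomial part by the delta method on the log scale:
Var(log Index) ≈ Var(μ̂) + Var(p̂)/p̂². Residual diagnostics report
standardized PCM residuals, a QQ slope, and a KS comparison against a
matched-moments normal quantile sample.

## 5. Cross-validated design comparison (`evaluate`)

Each replicate: (i) every record joins the build set iff an independent
U(0,1) draw < 0.5 (the split probability is not stated by the source
procedure; 0.5 is the natural two-way split), reproducibly under the
replicate seed, with a warning when a year × month × area × class stratum
falls entirely on one side; (ii) the pre-chosen final models for south,
north and combined are refitted on the build half; (iii) validation
records are predicted stochastically — indicator = 1 iff U(0,1) < fitted
positive probability, times the bias-corrected PCM back-transform; records
with unseen factor levels are skipped and counted; (iv) the overall R² is
the squared Pearson correlation of observed and predicted CPUE, pooling
south+north pairs for the area-separated design. 200 replicates by default
give the mean and a percentile (2.5/97.5) interval; replicates with failed
fits are dropped, and more than 10% dropped is an error. Note the
stochastic zero/positive draw bounds the attainable R² well below 1 even
for a perfect mean model.

## 6. The synthetic fishery (`simulate`)

The generator encodes the study conditions all recovery tests run under:

- **WPF**: lognormal with median 190 kg and log-SD 0.25, truncated to
  80–350 kg; counts per landing truncated-geometric on 1…50 with
  P(k) ∝ 0.45^(k−1) (single fish most common); 30% of counts masked.
- **Tracks** (hourly, one local day each): fishing days hold a 5-h
  deployment leg at 6 kn, a 2-h slow reposition toward the line start, an
  11-h retrieval leg at 2.5 kn on the reversed heading (turn 120–180°),
  and evening drift; transit days are straight 9-kn legs, of which 15%
  steam slowly (~2.8 kn, defeating the speed criterion) and 15% stop dead
  after a short steam (defeating it differently). Headings jitter by 2°
  (SD), speeds by 0.15 kn. These confounders are what give the three
  criterion families their distinct performance ranking.
- **Trips**: scheduled sequentially per vessel with 1–3 day port gaps;
  fishing days = slope(port, class) × at-sea days + N(0, 0.5) noise
  clipped to [0, at-sea]; the default slope table spans 0.69–0.83 across
  the eleven port × class groups.
- **CPUE**: 15 years of multiplicative year effects (declining with
  bumps, geometric mean 1), month effects {1.2, 1.0, 0.8}, area effects
  {south 1.2, north 0.8}, unit class effects (so class is a null factor
  for selection tests), zero probability 0.3, lognormal error SD 0.6, 80%
  of trips southern. An optional year×month lognormal deviate
  (`ym_effect_logsd`) switches on a true random interaction. Catch is kept
  as cpue × days (fractional) so the generating effects are exact.

**What the generator does not emulate:** spatial autocorrelation and
ocean currents, within-day set-level effort, vessel-targeting behaviour,
inter-annual drift in the weight-per-fish distribution, reporting errors
other than missingness, and integer catches. Passing recovery tests
therefore demonstrates the correctness of the estimators under the stated
generative assumptions, not robustness to every failure mode of real
fishery data.

## Problem sizes

The test suite and acceptance script run the stages at 2,000 landings
(10,000 Monte Carlo replicates), 500 labelled vessel-days, 5,000 trips,
10,000 CPUE records, and 20 seeds × 50 replicates for the cross-validation
comparison — sizes at which every recovery tolerance above has comfortable
margin while the full suite completes in about a minute.
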