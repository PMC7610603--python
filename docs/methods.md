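# Methods

## 1. The hazard model

For each outcome (any clinical fracture, osteoporotic fracture, major
osteoporotic fracture [MOF], hip fracture, first reported fall, death) the
cause-specific hazard of a participant at time `t` since baseline is

    h(t) = exp(β₀ + β₁·t + β₂·(age₀ + t) + β₃·x + γ'c)

with `x` the standardized exposure (ALM/height² by default; ALM or ALM/BMI
selectable) and `c` the adjustment covariates. Follow-up is divided into
intervals of 1 month (1/12 year exactly, configurable down to weeks via
`interval_length`); within an interval the hazard is treated as constant,
giving the piecewise-exponential likelihood

    ll(β) = Σ rows [ y·(Xβ + log L) − L·exp(Xβ) ]

where `y ∈ {0,1}` marks the interval containing the first event and `L` is
the interval's person-time. This is a Poisson GLM with log person-time
offset; its estimates agree with Cox partial likelihood to well under the
sampling error at realistic sample sizes (tested: |Δ log HR| < 0.02 at
n = 5,000), while giving an explicit parametric baseline in current time
and current age.

**Censoring.** Risk time for an outcome ends at the first of: the outcome
event, death, loss to follow-up, end of follow-up. One event per person.
Intervals are half-open `[t_start, t_end)`; an event exactly on a boundary
belongs to the later interval, except an event at the end of risk time,
which closes the last (possibly partial) interval. Summed interval lengths
reproduce each participant's risk time exactly (tested to 1e-9 years).

**Time-updated covariates.** `current_time` and `current_age` are evaluated
at the interval midpoint by default (`covariate_eval="interval_start"` is
available). For a log-linear hazard the midpoint is the less biased choice;
with 1-month intervals the difference is far below estimation error (the
refinement test bounds the month-vs-week discrepancy of the fitted log GR
at 0.005).

**Competing mortality.** Fracture and fall models stack two person-period
datasets — the outcome expansion (death censors) and a death expansion
(the outcome does not censor) — distinguished by a `cause_stratum` label,
so the outcome and death hazards are estimated jointly. All terms are
stratum-specific by default, which makes the joint fit exactly equivalent
to the two cause-specific fits (coefficients and summed log-likelihood;
tested to 1e-6). This equivalence is deliberate: for hazard-ratio
estimation the duplication changes nothing, and we therefore treat it as
the structural device it is — it matters only when the joint model is used
to share terms across strata (`ModelSpec.stratum_shared`) or to compute
absolute risks, which are out of scope. Death as an outcome is modelled
directly, without duplication.

**Optimization and inference.** Own-authored Newton–Raphson with analytic
gradient and Hessian, step-halving when a step would decrease the
likelihood, start at β = 0 except β₀ = log(total events / total
person-time), convergence when the relative log-likelihood change is below
1e-10, cap 100 iterations; non-convergence is flagged on the result, never
silent. The likelihood is concave, so this is reproducible and
initialization-insensitive. Covariance is the inverse observed information;
CIs and p-values are Wald (z = 1.959964) — no robust variance. Rank
deficiency is detected up front via the eigendecomposition of the scaled
Gram matrix and reported with the names of the collinear terms.
Complete-case filtering is per model: rows missing any model covariate are
dropped and the realised n / events are recorded on the `FitResult`.

**Gradient of risk.** GR = exp(β₃) per SD, CI = exp(β₃ ± 1.959964·SE).
Age-specific GRs use an exposure × current-age product term:
GR(a) = exp(β₃ + β₄·a), Var(log GR(a)) = V₃₃ + a²·V₄₄ + 2a·V₃₄ (delta
method). The exposure is standardized once on the whole analysis cohort
(mean 0, SD 1, denominator n−1) before any expansion, so every adjustment
set sees the same scale; GR per SD is invariant to positive rescaling of
the raw exposure. FRAX-type probabilities enter adjustment models
log-transformed by default (they are strongly right-skewed, range roughly
0.7–80%); `frax_log=False` switches to the raw scale. The printed-style
p-value caps ("p > .30", "p < .001") exist only in the reporting helper
`format_p`, never in stored results.

## 2. The synthetic-cohort generator

The generator emulates the covariate and event structure of a large US
cohort of postmenopausal women aged 50–79 with baseline DXA, so that the
analysis code can be exercised and validated end to end. Emulated,
calibrated features (defaults; all configurable through `GeneratorParams`):

- **Age**: truncated normal, mean 63.3, SD 7.4, bounds 50–79 years.
- **Anthropometry**: height N(161.6, 6.4) cm; BMI mean 28.2, SD 5.9 kg/m²;
  weight derived as BMI·height².
- **ALM/height², FN BMD, BMI** share a trivariate normal latent structure
  with corr(ALM/ht², BMD) = 0.41, corr(ALM/ht², BMI) = 0.70,
  corr(BMD, BMI) = 0.30; ALM/ht² mean 0.56 SD 0.10 g/cm², FN BMD mean 0.72
  SD 0.13 g/cm². ALM (g) is ALM/ht²·height², exactly. The T-score reference
  (young-adult mean 0.849, SD 0.111 g/cm²) is configurable because source
  publications rarely state theirs.
- **Binary risk factors** drawn independently at the cohort prevalences
  (prior fracture 17%, parental hip fracture 12%, smoking 8%,
  corticosteroids ~1%, rheumatoid arthritis 6%, excess alcohol 3%, prior
  falls 33%), with completely-at-random missingness at the per-column rates
  implied by the cohort's "number with data" (e.g. 31% for prior fracture,
  10% for prior falls).
- **Pseudo-FRAX**: 100·logistic(linear predictor) in age, BMI and the risk
  factors (± T-score), intercepts calibrated so the cohort means are ≈9.8%
  (without BMD) and ≈10.4% (with BMD). Only monotonicity (increasing in age
  and each risk factor, decreasing in T-score) and the calibrated means are
  contractual — this is *not* the proprietary FRAX engine, whose
  coefficients are out of scope.
- **Randomization**: three trials (dietary modification, hormone therapy,
  calcium/vitamin D) with independent enrollment (probabilities 0.35 /
  0.30 / 0.40), 1:1 active:placebo; observational-study membership is "not
  enrolled in any trial". Real multi-trial enrollment was not independent;
  the arms are nuisance covariates here, so independence is acceptable.
- **Events**: per-cause log-linear hazards evaluated per month at the
  interval-midpoint age; monthly Bernoulli draws with p = 1 − exp(−λ/12)
  (which composes exactly to exponential survival, so closed-form checks
  are exact in expectation); event time uniform within its month; death
  truncates all other processes; exponential dropout (rate 0.0312/y) and
  administrative censoring at 21.5 y.
- **Nested fracture outcomes** (any ⊇ osteoporotic ⊇ MOF ⊇ hip) are
  simulated as disjoint sub-cause processes whose hazards are differences
  of the configured composite log-linear hazards; the first-event hazard of
  each composite is then exactly its configured form. Differences are
  clipped at zero in the rare covariate corners where a finer cause's
  hazard would overtake its composite (oldest ages at the lowest BMD).
- **Falls** are questionnaire-ascertained: contacts every
  `fall_contact_interval` (default 1 y, "at least annually") while under
  observation; the probability of reporting ≥1 fall over a gap follows the
  fall hazard; counts are truncated-Poisson, top-coded at "3 or more". The
  fall *event* used in time-to-event analyses is the first contact with a
  nonzero count, so fall event times sit on the contact grid — the time
  granularity real questionnaire data would have. 43/11,187 participants
  carry no falls data and are excluded from falls analyses.

**Calibration.** Baseline hazard rates, the dropout rate and the
pseudo-FRAX intercepts were calibrated once, by iterative proportional
rescaling against 40,000-participant simulations, to the cohort's printed
summaries: cumulative event proportions over follow-up of 15% (any
fracture), 11% (osteoporotic), 9% (MOF), 3% (hip), 69% (any reported fall),
20% (death), mean follow-up 14.1 years, FRAX means 9.8/10.4. The frozen
defaults reproduce these at full cohort size to well within Monte-Carlo
error (e.g. mean follow-up 14.06–14.26 y across seeds).

**Exposure effects (defaults).** Fracture hazards depend on the FN BMD
T-score directly (log-HRs −0.30 to −0.44 per T-score unit, strongest for
hip) plus a small *positive* direct ALM term equal to the BMD-conditional
GRs (1.05/1.07/1.06/1.00); through corr(ALM, BMD) = 0.41 these imply
marginal per-SD GRs of roughly 0.91/0.90/0.88/0.81 — the attenuation-and-
inversion pattern that motivates the analysis. Falls get GR 0.98 (null-ish)
and death GR 1.13 at the reference age with an age × exposure log-slope of
−0.0058/y, so the mortality association weakens with age. `true_gr`
reports the configured (conditional) value; parameter-recovery tests
therefore use null-structure configurations in which the configured and
marginal effects coincide.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: the true joint covariate distribution (age is
independent of body composition here; real ALM declines with age),
informative or non-random missingness, correlated trial enrollment, real
FRAX, recurrent falls, secular trends in hazards, and measurement error in
DXA. Tests against this generator validate the *estimator and pipeline
machinery* — calibration, coverage, invariances — not the cohort's
substantive effect sizes, which require the restricted data.

## 3. Problem sizes used in the checks

The validation suite exercises: generator calibration at the full cohort
size (n = 11,187); estimator-vs-Cox agreement at n = 5,000; parameter
recovery and CI coverage over 200 replicates of n = 2,000 with true
GR 0.85 (5-year follow-up, flat hazards — about 440 events per replicate);
interaction type-I error over 200 null replicates of the same design; and
full-pipeline structural runs at n ≈ 1,200. These sizes give Monte-Carlo
precision comfortably inside the asserted tolerances while keeping the
default test run quick.

## 4. Known limitations and open choices

- Wald inference only; no robust/sandwich variance, no likelihood-ratio
  intervals. With hundreds of events the difference is immaterial.
- Linear current-age and current-time terms (as the hazard form states);
  no splines or time-varying coefficients beyond the exposure × time
  product term.
- Complete-case handling per model mirrors the varying per-covariate
  denominators of the emulated cohort; no imputation.
- The duplication dialect (which nuisance terms to share across strata) is
  genuinely underdetermined in the source literature; we default to fully
  stratum-specific (see §1) and expose `stratum_shared`.
- Whether FRAX should enter adjusted models raw or log-transformed is
  likewise unstated in the literature; default log, switchable.
- Absolute 10-year probabilities (the usual end product of the duplication
  method) are not computed.
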