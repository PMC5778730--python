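# Methods

## The model

Each subject i of a cohort of n women aged 50+ has a baseline 10-year
predicted probability of major osteoporotic fracture π_i ∈ [0,1] (a
FRAX®-style estimate) and a fully observed binary outcome D_i. A simulated
binary risk factor is a carrier indicator X_i ~ Bernoulli(p), drawn
independently of π_i and of D_i. The "new model" multiplies carriers'
predictions by an assumed relative risk RR ≥ 1:

    π_i' = π_i · RR   if X_i = 1,   else π_i.

The factor is noise by construction: RR encodes the effect the modeller
*assumes* the factor has, not any true association with the outcome. This
is the configuration under which the experiment's published-style results
arise — the printed IDI cells equal p·(RR−1)·(m_e − m_ne) across both
panels and ΔAUROC is negative, both of which are impossible if the factor
truly carried outcome information at that RR. A factor that is only
"independent of the other predictors" but genuinely associated with the
outcome is a different experiment and out of scope.

Predictions are deliberately **not renormalized** to preserve the cohort
mean, and **not capped** at 1 by default. Both choices are forced by the
closed-form structure of the results: the calibration shift equals
C0/(1+p(RR−1)) − C0 only for the uncentered update, and capping would break
both that identity (visibly at RR = 3.5) and the exact rank invariance that
gives ΔAUROC = 0 at prevalence 100%. Post-injection predictions above 1 are
counted and reported per condition (`n_risks_gt1`; largest at RR = 3.5),
and an optional cap is available but off by default.

## The four statistics

- **AUROC** — Mann–Whitney concordance estimator via midranks; tied pairs
  credit 0.5 (the convention when tie handling is unstated).
- **Calibration ratio** — crude event fraction ÷ mean predicted risk. In a
  registry analysis the numerator would be a censoring-adjusted 10-year
  cumulative incidence; synthetic outcomes are fully observed binary, so
  the crude fraction *is* the 10-year incidence here (see cohort notes).
- **NRI** — subjects are assigned to ordinal risk categories by the
  intervention threshold (a risk exactly at a cutpoint belongs to the
  upper category; the half-open convention is a choice, documented because
  boundary atoms are possible). Events score +1/−1 for moving up/down,
  non-events the opposite. The default estimator is the stratified
  two-part NRI, [P(up|event) − P(down|event)] + [P(down|non-event) −
  P(up|non-event)], bounded in [−2,2] and consistent with the statistic's
  standard definition. Verbal descriptions of the NRI sometimes read as
  "summed scores divided by the number of cohort members", which is a
  different, unstratified index bounded in [−1,1]; both are computed and
  returned (`NriResult.nri` and `NriResult.unstratified`), stratified
  being the default.
- **IDI** — change in discrimination slope,
  [mean(π'|D=1) − mean(π'|D=0)] − [mean(π|D=1) − mean(π|D=0)].

Exact finite-sample identities used as test oracles: for any realized
carrier draw, IDI = (RR−1)·[mean over events of X_iπ_i − mean over
non-events of X_iπ_i]; ΔCal = C_old·(mean π / mean π') − C_old; with
RR > 1 nobody moves down a category and the NRI reduces to
P(X=1 ∧ π ∈ [t/RR, t) | event) − P(X=1 ∧ π ∈ [t/RR, t) | non-event). On
cohorts of ≤ 12 subjects every statistic is additionally checked against
brute-force enumeration (all event/non-event pairs for AUROC, per-subject
scoring for the NRI).

## Closed-form oracles

First-order expectations over the carrier draw (realized carrier fraction
replaced by p):

    E[IDI]  = p·(RR−1)·(m_e − m_ne)
    E[ΔCal] = C0/(1 + p·(RR−1)) − C0
    ΔAUROC  = 0 exactly at p = 1 (common positive multiplier; no cap).

At n ≈ 32,000 the first-order approximation error is orders of magnitude
below 3-decimal rounding. No closed form is attempted for the NRI or for
ΔAUROC at p < 1: both depend on the full shape of the baseline risk
distribution and are checked by simulation against the brute-force
identities above. The "prevalence 33%" of the held-constant condition is
taken as exactly 1/3 (the RR = 3.5 calibration cell, −0.450, pins 1/3;
0.33 would give −0.448).

## The synthetic cohort

The generator emulates the summary structure of the registry study
population: n = 31,999; predicted risk 16.3 ± 9.6% among the ~10–11% of
women who fracture and 10.5 ± 6.8% among those who do not; baseline AUROC
≈ 0.706; baseline calibration ratio 0.990.

**Family.** Group-conditional risks are drawn from a two-parameter family
on (0,1), moment-matched within each outcome group. The default family is
the **logit-normal** (parameters solved numerically by Gauss–Hermite
quadrature): real FRAX risks are right-skewed, and the logit-normal's
heavier upper tail yields a baseline AUROC of ≈ 0.701, against ≈ 0.688 for
the moment-matched Beta. Both families are available (`family=` on
`CohortSpec`); moments are matchable iff sd² < mean·(1−mean), which is
validated with an error naming the offending group.

**Event rate and calibration.** A censored registry cohort can
simultaneously show a crude event fraction of 9.9% and a 10-year
cumulative-incidence calibration ratio of 0.990 against a mean predicted
risk of 11.1%; a fully observed binary world cannot (0.099/0.111 ≈ 0.89).
Since every downstream statistic consumes the calibration ratio, the
default study cohort (`manitoba_like()`) draws outcomes at the 10-year
incidence scale implied by the target ratio: the event rate solves
e/(e·m_e + (1−e)·m_ne) = C0, giving e = 0.11028 (3,529 events of 31,999).
The crude 9.9% remains available via the plain `CohortSpec` default for
uses that want the censored-scale event fraction.

**Noise control.** `manitoba_like()` fixes the event *count* exactly and
affinely standardizes each group's risks to the exact target moments, so
the realized baseline calibration is 0.990 to four decimals and the
expected-value checks test the injection machinery rather than cohort
sampling noise. Plain `CohortSpec` defaults use Bernoulli outcome draws
and raw moment-matched draws (group means then land within ~3 standard
errors of targets); both behaviours are options, not modes baked into the
statistics.

**`risk_first` mode.** When a baseline calibration must hold exactly in
expectation rather than through the event-rate inversion, risks can be
drawn from the outcome-weighted mixture of the two group distributions and
outcomes as Bernoulli(min(1, C0·π)). Group-conditional moments are then
emergent, not matched.

**What the generator does not emulate.** Follow-up time, censoring and
competing risks (outcomes are fully observed); correlation between the new
factor and existing predictors; the registry's category-fraction
breakdown; any real FRAX inputs (T-scores, clinical risk factors). Passing
tests therefore demonstrate the behaviour of the statistics under the
stated noise-factor model on a distributionally realistic cohort — not
properties of any real registry population. In particular the NRI and the
p < 1 ΔAUROC depend on the full baseline risk distribution, so their cell
values here match a real cohort's only qualitatively (sign, monotonicity,
the rise-then-fall of NRI in RR); the IDI and ΔCalibration cells and the
p = 1 ΔAUROC are distribution-free given (C0, m_e, m_ne) and reproduce to
printed precision.

## Simulation design

Default grids: RR 1.25–3.50 by 0.25; prevalence 10–100% by 10%;
intervention threshold 5–50% by 5%; three one-at-a-time panels with the
other parameters held at RR = 2.0, p = 1/3, t = 20%. Each condition
averages R = 200 replicates of the carrier draw (the statistics of
interest are means over a binomial draw at n ≈ 32k, so R = 200 puts the
Monte-Carlo SE of ΔCal near 1e-4, well under printed precision;
`--single-draw` reproduces a published-style single realization).

Seeding: one master seed; each condition's replicate streams derive
deterministically from (panel, prevalence) via `numpy` `SeedSequence`
spawn keys. Since the carrier draw is the only randomness and depends only
on (n, prevalence), conditions differing only in RR or threshold share
identical draws — which makes IDI, ΔAUROC and ΔCalibration exactly
constant across the threshold panel within a replicate set, as they must
be for threshold-free statistics, and makes any single cell reproducible
in isolation. Identical config + seed gives bit-identical output files.

Degenerate inputs: single-class cohorts are rejected wherever a statistic
needs both classes; prevalence 0 and 1 are deterministic draws; RR = 1 is
an exact no-op (all four deltas identically zero with zero SE); a zero
mean risk makes the calibration ratio undefined and raises.

## Known limitations

Single dichotomous factor only; no correlated or continuous factors; no
multiple simultaneous factors; equal implicit weighting of false positives
and false negatives; no confidence intervals for NRI/IDI beyond
Monte-Carlo SEs of the simulated means; no survival machinery (the
censored-vs-crude incidence distinction is resolved by construction, see
above).
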