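# Methods

## The decision problem

An incidentally detected solid renal mass must be classified as malignant
(renal cell carcinoma) or benign before treatment.  Three imaging
strategies are compared — contrast-enhanced ultrasound (CEUS), CT and MRI —
for a cohort aged 62 with a pre-test probability of malignancy of 83.1%.
Each strategy is characterized by a sensitivity, a specificity and an exam
tariff (2020 US Medicare prices).  The analysis is run from the US payer
perspective with a 3% annual discount on both costs and utilities and a
willingness-to-pay (WTP) of 100,000 USD/QALY.

## Model structure

**Decision tree.**  A test with sensitivity Se and specificity Sp splits a
cohort with prevalence p into four branches: TP = p·Se (timely treatment),
FN = p·(1−Se) (delayed treatment), TN = (1−p)·Sp (no action), FP =
(1−p)·(1−Sp) (unnecessary biopsy).  Each branch is charged a one-off acute
expense at entry (exam tariff plus, respectively, in-time surgery 4231.00,
delayed surgery 6346.50, nothing, or the 1375.00 biopsy) and seeds a
Markov cohort in a branch-specific health state: TP starts localized, FN
starts metastatic (the missed tumor progresses untreated; the delayed
expense is charged at model start because no detection-delay duration is
reported), TN and FP start without malignancy.

**Markov cohort.**  Four states — no malignancy, localized malignancy,
metastatic malignancy, dead (absorbing) — with monthly cycles.  Annual
probabilities q are converted to monthly ones under constant hazard,
m = 1 − (1−q)^(1/12).  Background mortality is read from an age-indexed
life table at the attained integer age every cycle.  Death competes with
progression: each row assigns the death probability first and scales the
survivors' destination probabilities by (1 − p_death), which keeps every
row stochastic at all ages including the cap age where the life table's
annual death probability is 1.  (A literal "remainder stays" wiring fails
to normalize once background mortality saturates; the conditional form is
the standard competing-risk treatment and is identical to first order at
ordinary ages.)

Flows in the default ("standard") topology:

* no malignancy → metastatic at monthly(1.00%/yr), → localized (post-
  treatment recurrence) at monthly(10.75%/yr), → dead at background risk;
* localized → metastatic at monthly(13.00%/yr), → no malignancy at a
  monthly cure rate obtained by spreading the per-episode curative-
  resection probability (1 − 0.0573)·0.412 over twelve cycles, → dead at
  background combined with monthly(3.5%/yr) excess;
* metastatic → dead at background combined with monthly(35%/yr) excess.

Rewards are accrued at cycle start (cycle 0 included), with no half-cycle
correction, and discounted by (1 + r)^(−t/12).  Utilities are annual QALY
weights (1 healthy, 0.75 localized, 0.66 metastatic, 0 dead) accrued
pro rata at weight/12 per cycle.  Monthly expenses follow a two-regime
schedule keyed on the cycle index: during the first twelve cycles the
localized and metastatic states bill their first-year rates (2148.25 and
2086.42 USD/month), afterwards their long-term rates (212.67 and 810.58);
the healthy state always bills 108.50.  The default horizon is lifetime:
cycles continue until the life-table cap age of 100, where everyone still
alive dies (456 cycles from age 62).  A one-year horizon cannot produce
double-digit QALY totals, so the published "model time 1 year" is read as
the duration of the first-year regime, not the run length.

**Comparison.**  Strategies are ranked by expected cost; strict dominance
(≤ cost and ≥ effect, one strict) and extended dominance (non-monotone
incremental ICERs along the cost-sorted frontier) are flagged; ICERs
ΔE/ΔO are computed pairwise and between adjacent frontier members; net
monetary benefit is wtp·O − E.  Equal-effect pairs yield a flagged
cost-only comparison rather than a division error; exact cost-and-effect
ties stay on the frontier flagged as equivalent.

## The reference-case costing profile

The published per-strategy totals (CT 10,285.58 USD / 11.95 QALYs, MRI
7,407.70 / 12.25, CEUS 5,539.78 / 12.44) cannot arise from lifetime
accrual of the monthly expenses above: the healthy branch alone would
accrue roughly 19,000 USD of background expenses over a discounted
lifetime, and the published healthy-branch worked example (1,302.00 =
12 × 108.50, undiscounted, for a true negative; just the 1,375.00 biopsy
for a false positive) shows that the source model accrued health-state
expenses for exactly one model year.  Solving the three strategies'
branch-weighted linear equations for the implied pathway values confirms
this and additionally implies that the timely-treatment branch accrued
roughly the 108.50/month maintenance expense (its surgery being the acute
entry charge) and that survival was driven by background mortality alone.

The engine therefore exposes a pluggable `Topology`, and ships a
`REFERENCE_CASE` profile implementing that structural reading: a 12-cycle
costing window with lifetime utility accrual, maintenance-rate billing for
the treated localized state, and background-only mortality with the
branch states held fixed.  Under this profile and the synthetic life
table the package reproduces the published costs within ±5% and the exact
dominance structure (CEUS strictly dominates CT and MRI).  QALYs come out
0.4–0.65 lower than printed across all three strategies: the residual is
the discounted life-year total of the mortality input — the published
figures imply ≈15.6 discounted life-years at age 62, whereas any Gompertz
table with 21 residual years gives ≈14.9 — and closing it would require
the exact national life table (or the source model's terminal-reward
arithmetic), neither of which is published.  The profile selection was a
choice among documented structural interpretations of the published
worked examples; no numeric parameter was fitted to the headline totals.

## Background mortality

`LifeTable` holds annual death probabilities for contiguous integer ages
with an absorbing cap (q = 1 at the cap age, default 100).  Tables load
from two-column CSV (`age,qx`) or are synthesized from a Gompertz hazard,
q(x) = 1 − exp(−a·e^(bx)).  The default synthetic table uses slope
b = 0.09/year (a typical adult mortality slope) with the scale a fitted by
bisection so that residual life expectancy at age 62 is 21 years, matching
the published national figure for a 62-year-old; it is a stand-in, and the
package logs a reminder that exact reproduction of published numbers needs
the real national table.  Life expectancy is the curtate expectation plus
half a year.  Attained age is the integer floor of current age; the
annual→monthly conversion assumes constant hazard within each year of age.

## Sensitivity analysis

**Deterministic.**  One-way sweeps re-run the full pipeline with one
parameter pinned at each end of its range.  Default ranges are ±20% of the
base value for every cost and every sensitivity/specificity, clipped to
[0,1] for probabilities (the source ranges are not published).  Two
outcome metrics are available: the default net-monetary-benefit gap,
NMB(CEUS) − max NMB(alternatives) at the WTP, whose sign is decision-
meaningful; and the signed ICER of CEUS versus its best alternative,
which mirrors the published tornado axis.  The ICER metric stays far
beneath the 100,000 USD/QALY line across all default ranges (worst case
≈ −13,000 under the reference-case profile).  Under the stricter NMB-gap
reading, CEUS loses optimality only at the extreme low end of its ±20%
sensitivity range (0.79, against MRI's 0.90) and at the top of MRI's —
±20% on a 99.1% sensitivity is far outside any reported confidence
interval, so the published no-crossing claim should be read against
narrower, evidence-based ranges.

**Probabilistic.**  Every uncertain parameter carries a distribution:
beta for probabilities and utilities, gamma for costs, parameterized by
its base-case mean and a coefficient of variation converted by method of
moments (beta: ν = m(1−m)/v − 1, α = mν, β = (1−m)ν; gamma: shape 1/cv²,
scale m·cv²).  Dispersions are not published; the default cv is 0.2, a
common convention when uncertainty is unreported.  A beta mean m only
admits cv < √((1−m)/m), so near-degenerate probabilities (e.g. the 99.1%
CEUS sensitivity) cap the cv at half the feasible maximum; means of
exactly 0 or 1, and structural values (age, WTP, discount rate), are held
fixed.  Parameters are sampled independently (no correlations are
published).  Each iteration draws from its own deterministically spawned
random substream, so results are reproducible bit-for-bit from one root
seed and independent of any batching.  Acceptability curves report, per
WTP on a 0–200,000 grid, the fraction of iterations in which each
strategy attains the maximal net monetary benefit; NMB ties go to the
cheaper strategy and exact ties split equally, so fractions sum to 1.
The default run uses 30,000 iterations (≈3 s via the vectorized engine);
the test suite uses 3,000, which leaves Monte-Carlo error on the CEUS
acceptance far from the 50% decision boundary (observed ≈90% under the
default topology, ≈66% under the reference-case profile).

## Validation oracles

* A two-state alive/dead chain with constant monthly hazard has the
  closed-form geometric-series total reward·(1−ρ^H)/(1−ρ) with
  ρ = (1−q)(1+r)^(−1/12); the cohort engine matches it to 1e−9.
* A patient-level microsimulation replays the decision tree and the same
  monthly transition probabilities by direct random draws, with no matrix
  algebra; cohort expectations agree with 100,000-patient microsimulation
  means within 3 Monte-Carlo standard errors across random parameter sets.
* Dominance flags are checked against a brute-force all-pairs comparison
  on random strategy sets.

The random parameter-set generator draws uniformly within clinically
plausible per-field bounds and enforces two orderings (metastatic utility
≤ localized; localized excess mortality ≤ metastatic) so that structural
monotonicities — QALYs nondecreasing in sensitivity, cost nonincreasing
in specificity — are well-posed.  What the synthetic fixtures do not
emulate: real national life-table shape (only its life expectancy at the
cohort age), parameter correlations, and any patient-level heterogeneity
beyond the modeled states; passing tests therefore validate the engine's
arithmetic and orderings, not the clinical accuracy of the inputs.

## Numerical choices and limitations

* Occupancy conservation is enforced to 1e−10 in traces; transition rows
  to 1e−12.  Runs stop early once dead-state occupancy exceeds 1 − 1e−9.
* Monetary outputs are written with two decimals; internal arithmetic is
  full double precision.
* Discounting starts at cycle 0 (the source is silent on cycle 0 vs 1).
* No tunnel states beyond the first-year/later reward switch; recurrence
  applies out of the no-malignancy state only; TP patients are charged no
  confirmatory biopsy (the biopsy expense is tied to false positives).
* The published ICERs (−10,115.05 for MRI, 9,703.86 for CT) cannot be
  reproduced from the published rounded totals under any pairing; the
  package reports all pairwise and frontier-adjacent ICERs instead.
* Single-test strategies only; no reflex-testing combinations, no EVPI.
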