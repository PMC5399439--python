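# Methods

## Model and decision rules

Each arm's response count is binomial with unknown rate π_k, and each rate
carries an independent conjugate beta prior, so every posterior is again
beta: Be(a_k + y_k, b_k + n_k − y_k). All decision quantities are posterior
probabilities:

* criterion 1: `P(π_k < p0 | data)` — the posterior CDF at the historical
  benchmark p0; rule 1 stops arm k (any arm, control included) when it
  exceeds γ1.
* criterion 2: `P(π_k − π_0 > Δ | data)` — rule 2 stops an experimental
  arm when this falls **below** γ2 (with Δ = 0 it is simply the posterior
  probability that the arm beats the control at all).
* criterion 3: `P(π_k − π_0 > δ* | data)` — rule 3 stops an experimental
  arm when this exceeds γ3, i.e. when a clinically sufficient margin δ* is
  established.

Because δ* > Δ, criterion 2 always dominates criterion 3. Threshold
comparisons are strict. The rules are evaluated and reported
independently — the simulator exercises one active rule at a time — and a
combined futility mode (rule 1 OR rule 2) is available behind an explicit
flag in `evaluate_look`. Trigger flags at a look are advisories; the
monitor never deletes data, and the simulator is where stopping has
consequences.

Independence of arms is assumed throughout (no shared frailty, no drift in
the response rate over calendar time), and outcomes are assumed observed
immediately upon enrollment.

## Priors and effective sample size

Priors are elicited by mean m and effective sample size e as
Be(m·e, (1−m)·e), giving variance m(1−m)/(e+1): one pseudo-patient of
information at mean 0.5 has variance 0.125, ten have 0.0227. Fractional
ESS (and hence non-integer beta shapes) is allowed. The named families are
`jeffreys` Be(½,½), `uniform` Be(1,1), `skeptical` (centered on p0) and
`enthusiastic` (centered on p0 + δ*); the informative centers default to
the trial hypotheses so that a sensitivity sweep
(`standard_prior_grid`) crosses a skeptical ESS-10 control prior with
skeptical/enthusiastic ESS-1 and ESS-5 experimental priors.

## Computing the beta-difference probability

The difference of two independent beta variables has no elementary law.
With F and f the beta CDF and density,

    P(π_k < π_0 + d) = ∫₀¹ F_k(p + d) f_0(p) dp,   F saturated to [0, 1],

and the rule quantity `P(π_k − π_0 > d)` is its complement. Numerical
choices:

* **Quantile substitution.** The integral is evaluated as
  ∫₀¹ F_k(Q_0(u) + d) du with Q_0 the control posterior quantile. The
  substituted integrand is bounded, monotone, and free of the endpoint
  density singularities that appear when a shape parameter is below one
  (e.g. a Jeffreys prior with few observations).
* **Kink breakpoint.** Where Q_0(u) + d crosses 0 or 1 the integrand has a
  kink, and for strongly separated posteriors the entire non-trivial part
  of the integrand can hide in a sliver of u next to that kink; the
  crossing point is passed to the integrator as an explicit breakpoint.
* **Adaptive quadrature** (QUADPACK via `scipy.integrate.quad`) at absolute
  tolerance 1e−8. If the error estimate exceeds 100× the tolerance the
  integral is recomputed along the experimental arm's quantile (the
  reflected identity `P(π_0 < π_k − d)`), and if both directions fail an
  `IntegrationError` carrying the achieved tolerance is raised. A stress
  scan over ~5,000 posterior/margin configurations produced no failures and
  reflection-identity defects below 4e−7.
* **Monte-Carlo oracle.** `prob_diff_exceeds_mc` estimates the same
  quantity from independent posterior draws (SE ≈ sqrt(p(1−p)/draws)). It
  exists for cross-checking the quadrature path in tests and is never used
  as a compute path.
* The normal approximation to the beta difference is not implemented: it is
  inaccurate precisely where the rules operate (small differences).

Criteria are reported at full precision and rendered to 4 decimals, which
is the precision at which single-look results are quoted.

## Sequential monitoring

`replay` re-evaluates all three rules after **every** observed outcome, for
all arms (not only the arm that received the patient), indexing looks by
overall enrollment sequence; each trace row also carries the arm's own n,
so trajectories can be plotted against either per-arm or overall patient
count. Criteria depend only on accumulated counts, hence two contracts the
tests enforce: the final look equals a single-look analysis of the final
counts, and permuting outcomes within an arm leaves the final report
unchanged. Replay defaults to `min_enrollment=0` (rules from the first
patient), which is the natural reading for a retrospective reanalysis; pass
`None` to inherit the design's gate.

## Minimum-enrollment gate

`DesignParams.min_enrollment` (default 15) withholds trigger flags early
in the trial, where the beta-difference probability is too variable to act
on. `gate_scope` chooses what the minimum counts:

* `"trial"` (default): total enrollment across arms — rules begin at the
  15th enrolled patient, when each arm holds about 5 under balanced
  allocation. This is the variant whose sequential operating
  characteristics match the reference behavior this package targets
  (average per-arm sample sizes at stopping can fall below 15, which a
  per-arm gate cannot produce).
* `"arm"`: the evaluated arm's own enrollment — a stricter variant that
  delays all decisions until the arm itself has `min_enrollment` patients.

## Simulation engine

* **Fixed design** (`run_fixed`): y_k ~ Binomial(n, π_k) per arm and
  replicate; posterior means, bias, MSE and the three criteria are averaged
  over replicates. Criteria are computed once per unique count pair and
  weighted by multiplicity — an exact reformulation that makes the cost
  independent of the replication budget.
* **Sequential design** (`run_sequential`): patients arrive one at a time,
  each assigned equiprobably among arms still enrolling (marginally the
  balanced multinomial allocation; a per-patient arrival order is needed
  for interim looks and is not part of the allocation model itself). After
  each arrival the active rule is checked for every arm that is eligible
  (past the gate), not yet stopped, and below its cap n_max. A triggered
  arm stops enrolling; its posterior mean at the stopping look is the
  recorded estimate (arms reaching the cap are recorded at the cap).
  An arm that reaches its cap without triggering is not monitored further:
  stopping percentages therefore count genuinely early stops.
* **Control termination.** Under rules 2–3 the control is never itself
  tested; it stops early only when every experimental arm has been stopped
  by the rule, since its comparator role is then exhausted. This behavior
  is toggleable (`control_stops_with_experimental`) and is not counted as
  a rule trigger in the early-stopping percentages.
* **Memoization.** All posterior probabilities depend only on the count
  tuple (y_k, n_k, y_0, n_0), so they are cached process-wide; the cache
  cannot change any value (a dedicated test clears it and compares).
* **Reproducibility.** One root seed; per-replicate RNG streams are spawned
  from a `SeedSequence`, so results are bit-identical across reruns and
  independent of evaluation order.

Default budgets: 10,000 replications for fixed-design summaries and 2,000
for sequential scenarios (50,000 for the cheap rule-1 scenario, whose
early-stopping rate is a small percentage and needs the extra precision).
Simulated percentages carry a Monte-Carlo standard error of
sqrt(p(1−p)/reps); tests compare at three such standard errors, and
average sample sizes at ±1.5 patients.

## Synthetic enrollment logs

`make_fixture_log` emulates the trial's data stream: equiprobable arm
assignment and Bernoulli outcomes, or — for case-study fixtures — a log
constrained to exact final counts with randomized arrival order and
within-arm outcome order. What it does **not** emulate: staggered or
non-exchangeable enrollment (calendar-time drift in the response rate,
which the case study itself hints at), delayed outcome ascertainment,
dropout, or unequal allocation. Tests that pass on these logs therefore
validate the decision machinery, not robustness to those real-data
features; on count-constrained logs only order-invariant quantities (the
final-look criteria) are meaningful assertions.

## Degenerate inputs and tie-breaks

Beta shapes must be strictly positive and counts must satisfy 0 ≤ y ≤ n,
both enforced at construction. `prob_diff_exceeds` maps d ≤ −1 to 1 and
d ≥ 1 to 0 without integrating. Threshold ties (criterion exactly equal to
a γ) do not trigger, matching the strict inequalities of the rules. An
empty enrollment log replays to an empty trace.

## Known limitations

* Binary endpoint only; no time-to-event or continuous outcomes.
* Equal (1:1:…) allocation; no response-adaptive randomization.
* One rule active at a time in the simulator (the combined rule-1-OR-2
  futility flag exists only in single-look reports).
* K is unrestricted in the library, but the simulator's scenario type
  models one control plus two experimental arms, the configuration the
  operating-characteristics summaries target.
* No familywise type-I-error control is attempted: the rules are Bayesian
  advisories whose frequentist error rates are quantified by simulation,
  not controlled by construction.
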