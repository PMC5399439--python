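# mamsbayes

Bayesian multi-arm multi-stage (MAMS) design for randomized phase-II
screening trials with a binary endpoint: several experimental arms are
compared against one concurrent control, and interim looks can drop an arm
for futility or stop it early for efficacy. The package provides the
conjugate beta-binomial machinery, the three posterior-probability stopping
rules, sequential monitoring of a patient-level enrollment log, and a
Monte-Carlo engine for the design's operating characteristics. It is aimed
at trial statisticians designing drop/select phase-II studies and at anyone
reanalyzing such a trial under Bayesian rules.

## The model

Each arm k (k = 0 is the control) has an unknown response probability
π_k with a conjugate beta prior Be(a_k, b_k). After y_k responses among
n_k patients the posterior is Be(a_k + y_k, b_k + n_k − y_k). Priors are
parameterized by their mean and effective sample size (ESS = a + b): a
*skeptical* prior centers on the historical null rate p₀, an *enthusiastic*
prior on the alternative p₀ + δ*, and Be(1,1) / Be(½,½) are the flat and
Jeffreys non-informative choices.

Three rules are monitored, with strict threshold comparisons:

1. **Futility vs. history** — stop arm k if `P(π_k < p₀ | data) > γ₁`
2. **Futility vs. control** — stop arm k if `P(π_k − π₀ > Δ | data) < γ₂`
3. **Efficacy by a margin** — stop arm k if `P(π_k − π₀ > δ* | data) > γ₃`

Rule 1 needs no comparator and applies to every arm including the control;
rules 2–3 apply to experimental arms only. The difference of two
independent beta posteriors has no closed form, so the exceedance
probability is computed by adaptive quadrature of

    P(π_k < π₀ + d) = ∫₀¹ F_k(p + d) f₀(p) dp

with the CDF saturated outside [0, 1], after a quantile substitution that
removes endpoint singularities (see `docs/methods.md`). A Monte-Carlo
estimator over posterior draws serves as an independent cross-check.

## Worked example

A three-arm trial (control A and experimental B, C, 40 patients per arm)
observed 15, 13 and 16 responses. With flat priors and the design
p₀ = 0.30, Δ = 0, δ* = 0.15:

```sh
$ mamsbayes analyze --counts "A=15/40,B=13/40,C=16/40"
arm  control  n  y  posterior_mean  crit1  crit2  crit3  rule1  rule2  rule3
  A     True 40 15          0.3810 0.1384    NaN    NaN  False  False  False
  B    False 40 13          0.3333 0.3346 0.3223 0.0281  False  False  False
  C    False 40 16          0.4048 0.0789 0.5894 0.1161  False  False  False
```

Posterior mean response rates are 0.381 (A), 0.333 (B) and 0.405 (C).
`crit1` is the posterior probability of being below the historical rate
0.30 — small everywhere, so rule 1 (γ₁ = 0.9) drops nothing. `crit2` says
there is only a 0.32 posterior probability that B beats the control at all;
that is above γ₂ = 0.1, so B is not dropped at this look (though a
sequential replay shows `crit2` dipping below 0.1 around the 20th B
patient — see `mamsbayes monitor`). `crit3` shows neither arm comes close
to a 90 % posterior probability of a 0.15 benefit, so no efficacy stop.

The same analysis across a grid of priors (`mamsbayes sensitivity`), a
sequential replay of an enrollment log (`mamsbayes monitor`), operating
characteristics (`mamsbayes simulate`), threshold-calibration surfaces
(`mamsbayes calibrate`) and synthetic log generation
(`mamsbayes make-fixture`) are available from the same CLI; every command
is a thin wrapper over the library API (`evaluate_look`, `replay`,
`run_fixed`, `run_sequential`, `calibration_sweep`, `make_fixture_log`).
An example configuration is in `examples/trial.yaml`.

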