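# Three-arm trial configuration: control A plus experimental B and C.
seed: 1

trial:
  control: A
  arms:
    A: {family: uniform}
    B: {family: uniform}
    C: {family: uniform}
    # informative alternatives, centered on p0 / p0 + delta_star:
    # A: {family: skeptical, ess: 10}
    # B: {family: enthusiastic, ess: 5}
    # or explicit shapes:
    # C: {a: 1.5, b: 3.5}

design:
  p0: 0.3          # historical minimum required response rate (rule 1)
  delta: 0.0       # targeted difference over control (rule 2)
  delta_star: 0.15 # sufficient response-rate margin (rule 3)
  gamma1: 0.9
  gamma2: 0.1
  gamma3: 0.9
  min_enrollment: 15   # patients enrolled before rules may trigger
  gate_scope: trial    # "trial": total enrollment; "arm": per-arm
  n_max: 40            # per-arm cap

simulate:
  pi_control: 0.3
  dB: 0.15         # true benefit of B over the control
  dC: 0.0
  n_per_arm: 40
  reps: 1000
  rule: rule2
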