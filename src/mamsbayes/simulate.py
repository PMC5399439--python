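"""Monte-Carlo engine for the design's operating characteristics.

Two modes:

* ``run_fixed`` — single-look designs: per replicate, draw each arm's
  responses ``y_k ~ Binomial(n, pi_k)``, compute posterior means and the
  three rule criteria once at the full sample size, and average.
* ``run_sequential`` — patients arrive one at a time, each assigned
  equiprobably among the arms still enrolling (marginally a multinomial
  allocation); after every arrival the active rule is evaluated for the
  eligible arms, a triggered arm stops enrolling, and per-arm estimates are
  taken at the stopping look (or at the cap when no rule fired).

Criteria depend only on the count tuple (y_k, n_k, y_0, n_0), so posterior
probabilities are memoized across replicates and scenarios; memoization is
purely an evaluation cache and cannot change any result.  Each replicate
draws from its own deterministically derived RNG stream, so results are
independent of evaluation order for a given root seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .errors import InvalidParameterError
from .monitor import EnrollmentLog
from .posterior import _beta_cdf_cached, _prob_diff_cached
from .priors import BetaPrior
from .rules import DesignParams

__all__ = [
    "ScenarioSpec",
    "OperatingCharacteristics",
    "run_fixed",
    "run_sequential",
    "calibration_sweep",
    "make_fixture_log",
]

RULES = ("fixed", "rule1", "rule2", "rule3")


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario: truth, design, and replication budget.

    Arms are ``("A", "B", "C")`` with A the control; true response rates are
    ``pi_A = pi_control``, ``pi_B = pi_control + dB``, ``pi_C = pi_control +
    dC``.  ``active_rule`` selects which single stopping rule drives arm
    dropping (``"fixed"`` disables stopping).
    """

    pi_control: float = 0.3
    dB: float = 0.0
    dC: float = 0.0
    n_per_arm: int = 40
    reps: int = 10_000
    seed: int = 0
    active_rule: str = "fixed"
    params: DesignParams = DesignParams(
        gamma1=0.95, gamma2=0.05, gamma3=0.95, min_enrollment=15
    )
    priors: Mapping[str, BetaPrior] | None = None
    arms: tuple[str, ...] = ("A", "B", "C")
    total_n: int | None = None
    control_stops_with_experimental: bool = True

    def __post_init__(self) -> None:
        if self.active_rule not in RULES:
            raise InvalidParameterError(
                f"active_rule must be one of {RULES}, got {self.active_rule!r}"
            )
        if self.n_per_arm < 1:
            raise InvalidParameterError("n_per_arm must be positive")
        if self.reps < 1:
            raise InvalidParameterError("reps must be positive")
        for arm, rate in self.true_rates().items():
            if not 0.0 < rate < 1.0:
                raise InvalidParameterError(
                    f"true response rate for arm {arm} is {rate}, outside (0, 1)"
                )

    def control_arm(self) -> str:
        return self.arms[0]

    def true_rates(self) -> dict[str, float]:
        benefits = (0.0, self.dB, self.dC)
        return {
            arm: self.pi_control + benefits[i] for i, arm in enumerate(self.arms)
        }

    def arm_priors(self) -> dict[str, BetaPrior]:
        if self.priors is None:
            return {arm: BetaPrior(1.0, 1.0) for arm in self.arms}
        return dict(self.priors)

    def budget(self) -> int:
        return self.total_n if self.total_n is not None else (
            len(self.arms) * self.n_per_arm
        )


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Averaged results of one scenario.

    ``bias``/``mse`` are for the posterior-mean estimate at the
    stopping-or-end look; ``pct_early`` is the percentage of replicates in
    which the active rule stopped the arm before its cap (for the control
    under rules 2-3, termination because all experimental arms stopped is
    not counted as a rule trigger).  ``mean_crit*`` are the fixed-design
    mean criteria (empty for sequential runs; ``mean_crit2/3`` cover
    experimental arms only).
    """

    arms: tuple[str, ...]
    true_rates: dict[str, float] = field(repr=False)
    bias: dict[str, float]
    mse: dict[str, float]
    avg_n: dict[str, float]
    pct_early: dict[str, float]
    mean_crit1: dict[str, float]
    mean_crit2: dict[str, float]
    mean_crit3: dict[str, float]
    reps: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for arm in self.arms:
            rows.append(
                {
                    "arm": arm,
                    "true_rate": self.true_rates[arm],
                    "bias": self.bias[arm],
                    "mse": self.mse[arm],
                    "avg_n": self.avg_n[arm],
                    "pct_early": self.pct_early[arm],
                    "mean_crit1": self.mean_crit1.get(arm, np.nan),
                    "mean_crit2": self.mean_crit2.get(arm, np.nan),
                    "mean_crit3": self.mean_crit3.get(arm, np.nan),
                }
            )
        return pd.DataFrame(rows)


def _posterior_ab(prior: BetaPrior, y, n):
    return prior.a + y, prior.b + n - y


def run_fixed(spec: ScenarioSpec) -> OperatingCharacteristics:
    """Single-look operating characteristics and mean criteria.

    Vectorized over replicates: criteria are averaged over the (weighted)
    unique response counts, which is exact and independent of ``reps`` cost.
    """
    if spec.active_rule != "fixed":
        raise InvalidParameterError("run_fixed requires active_rule='fixed'")
    rng = np.random.default_rng(spec.seed)
    rates = spec.true_rates()
    priors = spec.arm_priors()
    n = spec.n_per_arm
    control = spec.control_arm()

    draws = {
        arm: rng.binomial(n, rates[arm], size=spec.reps) for arm in spec.arms
    }

    bias, mse, mean_c1, mean_c2, mean_c3 = {}, {}, {}, {}, {}
    yc = draws[control]
    pc = priors[control]
    for arm in spec.arms:
        y = draws[arm]
        pr = priors[arm]
        est = (pr.a + y) / (pr.ess() + n)
        bias[arm] = float(np.mean(est - rates[arm]))
        mse[arm] = float(np.mean((est - rates[arm]) ** 2))

        w = np.bincount(y, minlength=n + 1)
        ys = np.nonzero(w)[0]
        c1 = special.betainc(pr.a + ys, pr.b + n - ys, spec.params.p0)
        mean_c1[arm] = float(np.sum(w[ys] * c1) / spec.reps)

        if arm != control:
            codes = y.astype(np.int64) * (n + 1) + yc
            uniq, counts = np.unique(codes, return_counts=True)
            c2 = c3 = 0.0
            for code, cnt in zip(uniq, counts):
                ye, y0 = divmod(int(code), n + 1)
                ae, be = _posterior_ab(pr, ye, n)
                a0, b0 = _posterior_ab(pc, y0, n)
                c2 += cnt * _prob_diff_cached(ae, be, a0, b0, spec.params.delta, 1e-8)
                c3 += cnt * _prob_diff_cached(
                    ae, be, a0, b0, spec.params.delta_star, 1e-8
                )
            mean_c2[arm] = float(c2 / spec.reps)
            mean_c3[arm] = float(c3 / spec.reps)

    return OperatingCharacteristics(
        arms=spec.arms,
        true_rates=rates,
        bias=bias,
        mse=mse,
        avg_n={arm: float(n) for arm in spec.arms},
        pct_early={arm: 0.0 for arm in spec.arms},
        mean_crit1=mean_c1,
        mean_crit2=mean_c2,
        mean_crit3=mean_c3,
        reps=spec.reps,
    )


def _rule_triggers(
    rule: str,
    p: DesignParams,
    pr: BetaPrior,
    y: int,
    n: int,
    pc: BetaPrior,
    y0: int,
    n0: int,
) -> bool:
    a, b = _posterior_ab(pr, y, n)
    if rule == "rule1":
        return _beta_cdf_cached(a, b, p.p0) > p.gamma1
    a0, b0 = _posterior_ab(pc, y0, n0)
    if rule == "rule2":
        return _prob_diff_cached(a, b, a0, b0, p.delta, 1e-8) < p.gamma2
    return _prob_diff_cached(a, b, a0, b0, p.delta_star, 1e-8) > p.gamma3


def run_sequential(spec: ScenarioSpec) -> OperatingCharacteristics:
    """Sequential per-arm stopping under one active rule.

    Per replicate, arms enroll one patient at a time until each is stopped
    by the rule or reaches its cap ``n_per_arm``.  Rule 1 monitors every arm
    (the control included); rules 2 and 3 monitor the experimental arms,
    and the control stops once all experimental arms have been stopped by
    the rule (when ``control_stops_with_experimental``), since it then has
    no comparator role left.
    """
    if spec.active_rule == "fixed":
        raise InvalidParameterError(
            "run_sequential requires active_rule in {'rule1','rule2','rule3'}"
        )
    rule = spec.active_rule
    p = spec.params
    rates = spec.true_rates()
    priors = spec.arm_priors()
    arms = spec.arms
    k = len(arms)
    control = 0
    cap = spec.n_per_arm
    rate_vec = [rates[a] for a in arms]
    prior_vec = [priors[a] for a in arms]
    comparative = rule in ("rule2", "rule3")

    n_final = np.zeros((spec.reps, k), dtype=np.int64)
    y_final = np.zeros((spec.reps, k), dtype=np.int64)
    early = np.zeros((spec.reps, k), dtype=bool)

    streams = np.random.SeedSequence(spec.seed).spawn(spec.reps)
    for r in range(spec.reps):
        rng = np.random.default_rng(streams[r])
        n = [0] * k
        y = [0] * k
        stopped = [False] * k  # stopped by the rule (not by the cap)
        total = 0
        while True:
            active = [i for i in range(k) if not stopped[i] and n[i] < cap]
            if not active:
                break
            i = active[int(rng.integers(len(active)))]
            outcome = rng.random() < rate_vec[i]
            n[i] += 1
            y[i] += int(outcome)
            total += 1

            gate_total = total >= p.min_enrollment
            for j in range(k):
                if stopped[j] or n[j] >= cap:
                    continue  # capped arms are analyzed at the final look
                if comparative and j == control:
                    continue
                if p.gate_scope == "trial":
                    if not gate_total:
                        continue
                elif n[j] < p.min_enrollment:
                    continue
                if _rule_triggers(
                    rule, p, prior_vec[j], y[j], n[j],
                    prior_vec[control], y[control], n[control],
                ):
                    stopped[j] = True
                    early[r, j] = True
            if (
                comparative
                and spec.control_stops_with_experimental
                and not stopped[control]
                and all(stopped[j] for j in range(k) if j != control)
            ):
                stopped[control] = True  # comparator role exhausted; not a trigger
        n_final[r] = n
        y_final[r] = y

    bias, mse, avg_n, pct_early = {}, {}, {}, {}
    for j, arm in enumerate(arms):
        pr = prior_vec[j]
        est = (pr.a + y_final[:, j]) / (pr.ess() + n_final[:, j])
        bias[arm] = float(np.mean(est - rate_vec[j]))
        mse[arm] = float(np.mean((est - rate_vec[j]) ** 2))
        avg_n[arm] = float(np.mean(n_final[:, j]))
        pct_early[arm] = float(100.0 * np.mean(early[:, j]))

    return OperatingCharacteristics(
        arms=arms,
        true_rates=rates,
        bias=bias,
        mse=mse,
        avg_n=avg_n,
        pct_early=pct_early,
        mean_crit1={},
        mean_crit2={},
        mean_crit3={},
        reps=spec.reps,
    )


def calibration_sweep(
    dB_grid: Sequence[float],
    n_grid: Sequence[int],
    reps: int,
    seed: int,
    params: DesignParams,
    *,
    pi_control: float = 0.3,
) -> pd.DataFrame:
    """Mean criteria surface over true benefit and per-arm sample size.

    Runs the fixed-sample engine on every (dB, n) cell and tabulates the mean
    criteria of the benefiting arm (and the control's criterion 1), suitable
    for line or heatmap plots of threshold calibration.
    """
    if not len(dB_grid) or not len(n_grid):
        raise InvalidParameterError("dB_grid and n_grid must be non-empty")
    if reps < 1:
        raise InvalidParameterError("reps must be positive")
    children = np.random.SeedSequence(seed).spawn(len(dB_grid) * len(n_grid))
    rows = []
    idx = 0
    for n in n_grid:
        for dB in dB_grid:
            child_seed = int(children[idx].generate_state(1)[0] % (2**31))
            idx += 1
            spec = ScenarioSpec(
                pi_control=pi_control,
                dB=dB,
                dC=0.0,
                n_per_arm=int(n),
                reps=reps,
                seed=child_seed,
                active_rule="fixed",
                params=params,
            )
            oc = run_fixed(spec)
            ctrl, exp = spec.arms[0], spec.arms[1]
            rows.append(
                {
                    "dB": dB,
                    "n_per_arm": n,
                    "crit1_control": oc.mean_crit1[ctrl],
                    "crit1": oc.mean_crit1[exp],
                    "crit2": oc.mean_crit2[exp],
                    "crit3": oc.mean_crit3[exp],
                    "bias": oc.bias[exp],
                }
            )
    return pd.DataFrame(rows)


def make_fixture_log(
    spec: ScenarioSpec,
    counts: Mapping[str, tuple[int, int]] | None = None,
) -> EnrollmentLog:
    """Simulate one patient-level enrollment log.

    Unconstrained, each of ``spec.budget()`` patients is assigned
    equiprobably among the arms (marginally multinomial) with a
    Bernoulli(pi_arm) outcome.  With ``counts`` (mapping arm -> (y, n)),
    the log is constrained to hit those exact final counts, with the arrival
    order and within-arm outcome order randomized; only order-invariant
    quantities (final-look criteria) are then reproducible claims.
    """
    rng = np.random.default_rng(spec.seed)
    if counts is None:
        rates = spec.true_rates()
        records = []
        for seq in range(1, spec.budget() + 1):
            arm = spec.arms[int(rng.integers(len(spec.arms)))]
            outcome = int(rng.random() < rates[arm])
            records.append((seq, arm, outcome))
        return EnrollmentLog(records=tuple(records))

    arm_seq: list[str] = []
    outcomes: dict[str, list[int]] = {}
    for arm, (y, n) in counts.items():
        if not 0 <= y <= n:
            raise InvalidParameterError(
                f"arm {arm!r}: infeasible count constraint y={y}, n={n}"
            )
        arm_seq.extend([arm] * n)
        flags = [1] * y + [0] * (n - y)
        rng.shuffle(flags)
        outcomes[arm] = flags
    order = rng.permutation(len(arm_seq))
    records = []
    taken = {arm: 0 for arm in counts}
    for seq, pos in enumerate(order, start=1):
        arm = arm_seq[pos]
        records.append((seq, arm, outcomes[arm][taken[arm]]))
        taken[arm] += 1
    return EnrollmentLog(records=tuple(records))
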