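"""The three posterior-probability stopping rules, evaluated at one look.

For each arm k with posterior ``Be(a_k + y_k, b_k + n_k - y_k)`` and a
control arm 0, the design monitors:

* rule 1 (futility vs. history):   stop if ``P(pi_k < p0) > gamma1``
* rule 2 (futility vs. control):   stop if ``P(pi_k - pi_0 > delta) < gamma2``
* rule 3 (efficacy by a margin):   stop if ``P(pi_k - pi_0 > delta_star) > gamma3``

Rule 1 needs no comparator and is evaluated for every arm including the
control; rules 2 and 3 are evaluated for experimental arms only.  Threshold
comparisons are strict.  Rules are reported independently; a combined
futility flag (rule 1 OR rule 2) is available behind an explicit switch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, InvalidParameterError
from .posterior import ArmState, prob_below, prob_diff_exceeds
from .priors import BetaPrior

__all__ = [
    "DesignParams",
    "ArmDecision",
    "DecisionReport",
    "evaluate_look",
    "sensitivity_grid",
    "standard_prior_grid",
]


@dataclass(frozen=True)
class DesignParams:
    """Design constants shared by all looks.

    Parameters
    ----------
    p0 : float
        Minimum required treatment response rate (historical benchmark).
    delta : float
        Targeted difference over control for the comparative futility rule;
        0 means "any benefit at all".
    delta_star : float
        Sufficient treatment response rate: the benefit margin whose
        posterior exceedance triggers efficacy stopping. Must exceed
        ``delta``.
    gamma1, gamma2, gamma3 : float
        Posterior-probability decision thresholds for rules 1-3.
    min_enrollment : int
        Number of patients that must be enrolled before the rules apply.
    gate_scope : {"trial", "arm"}
        Whether ``min_enrollment`` counts total trial enrollment (default)
        or each arm's own enrollment.
    n_max : int
        Per-arm enrollment cap.
    """

    p0: float = 0.3
    delta: float = 0.0
    delta_star: float = 0.15
    gamma1: float = 0.9
    gamma2: float = 0.1
    gamma3: float = 0.9
    min_enrollment: int = 15
    gate_scope: str = "trial"
    n_max: int = 40

    def __post_init__(self) -> None:
        if not 0.0 < self.p0 < 1.0:
            raise InvalidParameterError(f"p0 must lie in (0, 1), got {self.p0}")
        if not self.delta_star > self.delta:
            raise InvalidParameterError(
                f"delta_star ({self.delta_star}) must exceed delta ({self.delta})"
            )
        for name in ("gamma1", "gamma2", "gamma3"):
            g = getattr(self, name)
            if not 0.0 < g < 1.0:
                raise InvalidParameterError(f"{name} must lie in (0, 1), got {g}")
        if self.min_enrollment < 0:
            raise InvalidParameterError("min_enrollment must be non-negative")
        if self.gate_scope not in ("trial", "arm"):
            raise InvalidParameterError(
                f"gate_scope must be 'trial' or 'arm', got {self.gate_scope!r}"
            )
        if self.n_max < 1:
            raise InvalidParameterError("n_max must be positive")


@dataclass(frozen=True)
class ArmDecision:
    """Rule criteria and trigger flags for one arm at one look.

    ``crit2``/``crit3`` are ``None`` for the control arm (rules 2-3 compare
    against the control and are undefined there).  ``futility`` is the
    combined rule-1-OR-rule-2 flag and is ``None`` unless the combined mode
    was requested.
    """

    arm: str
    is_control: bool
    n: int
    y: int
    posterior_mean: float
    crit1: float
    crit2: float | None
    crit3: float | None
    rule1: bool
    rule2: bool
    rule3: bool
    futility: bool | None = None


@dataclass(frozen=True)
class DecisionReport:
    """All arms' decisions at one look; pure data, never mutates arm states."""

    arms: tuple[ArmDecision, ...]
    params: DesignParams = field(repr=False, default=DesignParams())

    def __getitem__(self, arm: str) -> ArmDecision:
        for a in self.arms:
            if a.arm == arm:
                return a
        raise KeyError(arm)

    def control(self) -> ArmDecision:
        return next(a for a in self.arms if a.is_control)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.arms:
            rows.append(
                {
                    "arm": a.arm,
                    "control": a.is_control,
                    "n": a.n,
                    "y": a.y,
                    "posterior_mean": a.posterior_mean,
                    "crit1": a.crit1,
                    "crit2": a.crit2,
                    "crit3": a.crit3,
                    "rule1": a.rule1,
                    "rule2": a.rule2,
                    "rule3": a.rule3,
                }
            )
        return pd.DataFrame(rows)


def _the_control(arms: Sequence[ArmState]) -> ArmState:
    controls = [a for a in arms if a.is_control]
    if len(controls) != 1:
        raise ConfigurationError(
            f"exactly one control arm required, found {len(controls)} "
            f"among {[a.arm_id for a in arms]}"
        )
    return controls[0]


def evaluate_look(
    arms: Sequence[ArmState],
    params: DesignParams,
    *,
    combine_futility: bool = False,
) -> DecisionReport:
    """Evaluate all three rules for every arm at the current counts.

    Trigger flags are suppressed (all ``False``) while enrollment is below
    ``params.min_enrollment`` — counted per arm or over the whole trial
    according to ``params.gate_scope``; criteria values are reported either
    way.
    """
    ctrl = _the_control(arms)
    total_n = sum(a.n for a in arms)
    decisions = []
    for arm in arms:
        c1 = prob_below(arm, params.p0)
        if arm.is_control:
            c2 = c3 = None
        else:
            c2 = prob_diff_exceeds(arm, ctrl, params.delta)
            c3 = prob_diff_exceeds(arm, ctrl, params.delta_star)
        if params.gate_scope == "trial":
            eligible = total_n >= params.min_enrollment
        else:
            eligible = arm.n >= params.min_enrollment
        r1 = eligible and c1 > params.gamma1
        r2 = eligible and c2 is not None and c2 < params.gamma2
        r3 = eligible and c3 is not None and c3 > params.gamma3
        decisions.append(
            ArmDecision(
                arm=arm.arm_id,
                is_control=arm.is_control,
                n=arm.n,
                y=arm.y,
                posterior_mean=arm.posterior_mean(),
                crit1=c1,
                crit2=c2,
                crit3=c3,
                rule1=r1,
                rule2=r2,
                rule3=r3,
                futility=(r1 or r2) if combine_futility else None,
            )
        )
    return DecisionReport(arms=tuple(decisions), params=params)


def sensitivity_grid(
    counts: Mapping[str, tuple[int, int]],
    control: str,
    prior_grid: Sequence[tuple[str, Mapping[str, BetaPrior]]],
    params: DesignParams,
) -> pd.DataFrame:
    """Decision report for each prior combination, plus an MLE reference row.

    Parameters
    ----------
    counts : mapping arm -> (y, n)
        Observed responses / enrollment per arm.
    control : str
        Which arm is the control.
    prior_grid : sequence of (label, mapping arm -> BetaPrior)
        Prior assignments to sweep.

    Returns
    -------
    DataFrame with one row per (prior combination x arm); the first rows are
    the maximum-likelihood estimates ``y/n`` with criteria left empty.
    """
    if control not in counts:
        raise ConfigurationError(f"control arm {control!r} missing from counts")
    rows = []
    for arm, (y, n) in counts.items():
        rows.append(
            {
                "prior": "MLE",
                "arm": arm,
                "ess": math.nan,
                "n": n,
                "y": y,
                "posterior_mean": y / n,
                "crit1": math.nan,
                "crit2": math.nan,
                "crit3": math.nan,
                "rule1": None,
                "rule2": None,
                "rule3": None,
            }
        )
    for label, priors in prior_grid:
        states = [
            ArmState(arm, priors[arm], n=n, y=y, is_control=(arm == control))
            for arm, (y, n) in counts.items()
        ]
        report = evaluate_look(states, params)
        for dec, state in zip(report.arms, states):
            rows.append(
                {
                    "prior": label,
                    "arm": dec.arm,
                    "ess": state.prior.ess(),
                    "n": dec.n,
                    "y": dec.y,
                    "posterior_mean": dec.posterior_mean,
                    "crit1": dec.crit1,
                    "crit2": math.nan if dec.crit2 is None else dec.crit2,
                    "crit3": math.nan if dec.crit3 is None else dec.crit3,
                    "rule1": dec.rule1,
                    "rule2": dec.rule2,
                    "rule3": dec.rule3,
                }
            )
    return pd.DataFrame(rows)


def standard_prior_grid(
    control: str,
    experimental: Sequence[str],
    *,
    null_rate: float = 0.3,
    alt_rate: float = 0.45,
    control_ess: float = 10.0,
    experimental_ess: Sequence[float] = (1.0, 5.0),
) -> list[tuple[str, dict[str, BetaPrior]]]:
    """The usual sensitivity sweep: non-informative priors everywhere, then a
    skeptical control crossed with skeptical/enthusiastic experimental priors
    at each requested ESS."""
    from .priors import named_prior

    grid: list[tuple[str, dict[str, BetaPrior]]] = []
    for fam in ("jeffreys", "uniform"):
        grid.append((fam, {a: named_prior(fam) for a in [control, *experimental]}))
    ctrl_prior = named_prior("skeptical", control_ess, null_rate, alt_rate)
    for fam in ("skeptical", "enthusiastic"):
        for ess in experimental_ess:
            priors = {control: ctrl_prior}
            for a in experimental:
                priors[a] = named_prior(fam, ess, null_rate, alt_rate)
            grid.append((f"{fam}-ess{ess:g}", priors))
    return grid
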