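"""Conjugate posterior updating and the two posterior-probability kernels.

Every stopping rule reduces to one of two quantities:

* a beta tail probability ``P(pi < t | y, n)`` — the posterior CDF of one
  arm's response rate at a threshold ``t`` (rule 1), and
* the exceedance probability for the difference of two independent beta
  posteriors, ``P(pi_exp - pi_ctrl > d | data)`` (rules 2 and 3).

The difference of two betas has no beta (or otherwise elementary) law, so the
exceedance probability is computed by one-dimensional quadrature of

    P(pi_exp < pi_ctrl + d) = int_0^1 F_exp(p + d) f_ctrl(p) dp

with the experimental CDF saturated to 0 below 0 and 1 above 1, and the rule
quantity returned as its complement.  The integral is evaluated after the
substitution ``u = F_ctrl(p)``:

    int_0^1 F_exp(Q_ctrl(u) + d) du

whose integrand is bounded and free of the endpoint singularities the control
density has when a shape parameter is below one (e.g. a Jeffreys prior with
few observations).  A Monte-Carlo estimator over independent posterior draws
is provided as a brute-force oracle for testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import integrate, special

from .errors import IntegrationError, InvalidParameterError
from .priors import BetaPrior

__all__ = [
    "ArmState",
    "update",
    "prob_below",
    "prob_diff_exceeds",
    "prob_diff_exceeds_mc",
]

#: absolute tolerance requested from the adaptive quadrature
QUAD_TOL = 1e-8


@dataclass(frozen=True)
class ArmState:
    """One arm's identity, prior, and accumulated counts.

    ``y`` responses among ``n`` enrolled patients; the posterior is the
    conjugate update ``Be(a + y, b + n - y)``.
    """

    arm_id: str
    prior: BetaPrior
    n: int = 0
    y: int = 0
    is_control: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.y <= self.n):
            raise InvalidParameterError(
                f"arm {self.arm_id!r}: need 0 <= y <= n, got y={self.y}, n={self.n}"
            )

    def posterior(self) -> BetaPrior:
        return BetaPrior(self.prior.a + self.y, self.prior.b + self.n - self.y)

    def posterior_mean(self) -> float:
        return self.posterior().mean()


def update(state: ArmState, outcome: int) -> ArmState:
    """Record one patient's binary outcome; prior is unchanged."""
    if outcome not in (0, 1):
        raise InvalidParameterError(f"outcome must be 0 or 1, got {outcome!r}")
    return replace(state, n=state.n + 1, y=state.y + int(outcome))


def prob_below(state: ArmState, threshold: float) -> float:
    """Posterior probability that the arm's response rate is below ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise InvalidParameterError(f"threshold must lie in (0, 1), got {threshold}")
    post = state.posterior()
    return _beta_cdf_cached(post.a, post.b, threshold)


@lru_cache(maxsize=None)
def _beta_cdf_cached(a: float, b: float, x: float) -> float:
    return float(special.betainc(a, b, x))


def prob_diff_exceeds(
    exp: ArmState, ctrl: ArmState, d: float, *, tol: float = QUAD_TOL
) -> float:
    """``P(pi_exp - pi_ctrl > d)`` for independent beta posteriors.

    Non-increasing in ``d``; returns 1 for ``d <= -1`` and 0 for ``d >= 1``
    (the difference is supported on (-1, 1)).

    Raises
    ------
    IntegrationError
        If the quadrature's error estimate exceeds the requested tolerance
        by more than two orders of magnitude.
    """
    d = float(d)
    if d <= -1.0:
        return 1.0
    if d >= 1.0:
        return 0.0
    pe, pc = exp.posterior(), ctrl.posterior()
    return _prob_diff_cached(pe.a, pe.b, pc.a, pc.b, d, tol)


def _quantile_sub_quad(
    a_out: float, b_out: float, a_in: float, b_in: float, shift: float, tol: float
) -> tuple[float, float]:
    """``int_0^1 F_in(Q_out(u) + shift) du`` with the inner CDF saturated.

    The substituted integrand is bounded and monotone, so adaptive
    quadrature needs no special handling of density endpoint singularities.
    """

    def integrand(u: float) -> float:
        p = special.betaincinv(a_out, b_out, u)
        x = p + shift
        if x <= 0.0:
            return 0.0
        if x >= 1.0:
            return 1.0
        return float(special.betainc(a_in, b_in, x))

    # The integrand has a kink where Q_out(u) + shift crosses the support
    # edge; without a breakpoint there, a narrow non-zero stretch hiding in
    # the outer tail can be sampled straight past.
    points = None
    if shift < 0.0:
        u_kink = float(special.betainc(a_out, b_out, -shift))
    elif shift > 0.0:
        u_kink = float(special.betainc(a_out, b_out, 1.0 - shift))
    else:
        u_kink = None
    if u_kink is not None and 0.0 < u_kink < 1.0:
        points = [u_kink]

    with warnings.catch_warnings():
        # roundoff chatter from QUADPACK; we enforce the error budget ourselves
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        return integrate.quad(
            integrand, 0.0, 1.0, epsabs=tol, epsrel=tol, limit=300, points=points
        )


@lru_cache(maxsize=None)
def _prob_diff_cached(
    ae: float, be: float, ac: float, bc: float, d: float, tol: float
) -> float:
    # P(exp < ctrl + d) integrated along the control quantile; if the ramp
    # sits too deep in the control's tail for a clean error estimate, redo it
    # along the experimental quantile (P(ctrl < exp - d), the complement).
    val, abserr = _quantile_sub_quad(ac, bc, ae, be, d, tol)
    result = 1.0 - val
    if abserr > 100.0 * tol:
        val2, abserr2 = _quantile_sub_quad(ae, be, ac, bc, -d, tol)
        if abserr2 < abserr:
            result, abserr = val2, abserr2
    if abserr > 100.0 * tol:
        raise IntegrationError(
            f"beta-difference quadrature achieved abs error {abserr:.3g} "
            f"(requested {tol:.3g})",
            achieved=abserr,
            requested=tol,
        )
    return min(max(result, 0.0), 1.0)


def prob_diff_exceeds_mc(
    exp: ArmState, ctrl: ArmState, d: float, draws: int, seed: int
) -> float:
    """Monte-Carlo estimate of ``P(pi_exp - pi_ctrl > d)`` from posterior draws.

    Standard error is about ``sqrt(p * (1 - p) / draws)``.  Intended as an
    independent oracle for the quadrature path, not as a compute path.
    """
    if draws < 1:
        raise InvalidParameterError(f"draws must be >= 1, got {draws}")
    rng = np.random.default_rng(seed)
    pe, pc = exp.posterior(), ctrl.posterior()
    x = rng.beta(pe.a, pe.b, size=draws)
    z = rng.beta(pc.a, pc.b, size=draws)
    return float(np.mean(x - z > d))


def clear_caches() -> None:
    """Drop memoized posterior-probability values (used by tests)."""
    _beta_cdf_cached.cache_clear()
    _prob_diff_cached.cache_clear()
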