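"""Beta priors parameterized by mean and effective sample size (ESS).

A ``Be(a, b)`` prior on a response probability carries prior information
equivalent to ``ESS = a + b`` pseudo-patients with prior mean ``a / (a + b)``.
Elicitation therefore proceeds the other way round: pick a center and an
amount of information, and solve ``a = mean * ess``, ``b = (1 - mean) * ess``.

Four named families cover the usual sensitivity analysis:

``jeffreys``
    Be(1/2, 1/2), ESS 1 — the invariant non-informative choice.
``uniform``
    Be(1, 1), ESS 2 — flat over [0, 1].
``skeptical``
    centered on the null response rate (no effect beyond the historical
    control), with a caller-chosen ESS.
``enthusiastic``
    centered on the alternative (hoped-for) response rate, with a
    caller-chosen ESS.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .errors import InvalidParameterError

__all__ = ["BetaPrior", "from_mean_ess", "named_prior", "PRIOR_FAMILIES"]

PRIOR_FAMILIES = ("jeffreys", "uniform", "skeptical", "enthusiastic")


@dataclass(frozen=True)
class BetaPrior:
    """A beta distribution standing for belief about one arm's response rate.

    Parameters
    ----------
    a, b : float
        Positive beta shape parameters. Non-integer values are allowed:
        elicitation by mean and ESS generally produces fractional shapes.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise InvalidParameterError(
                f"beta shape parameters must be positive, got a={self.a}, b={self.b}"
            )

    def mean(self) -> float:
        return self.a / (self.a + self.b)

    def ess(self) -> float:
        """Effective sample size, ``a + b`` pseudo-patients."""
        return self.a + self.b

    def variance(self) -> float:
        m = self.mean()
        return m * (1.0 - m) / (self.ess() + 1.0)

    def dist(self):
        """The scipy frozen distribution (for plotting / sampling)."""
        return stats.beta(self.a, self.b)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"Be({self.a:g}, {self.b:g})"


def from_mean_ess(mean: float, ess: float) -> BetaPrior:
    """Construct a beta prior with the given mean and effective sample size.

    ``Be(mean * ess, (1 - mean) * ess)``; round-trips ``mean()`` and ``ess()``
    exactly, and has variance ``mean * (1 - mean) / (ess + 1)``.
    """
    if not 0.0 < mean < 1.0:
        raise InvalidParameterError(f"prior mean must lie in (0, 1), got {mean}")
    if not ess > 0.0:
        raise InvalidParameterError(f"prior ESS must be positive, got {ess}")
    return BetaPrior(mean * ess, (1.0 - mean) * ess)


def named_prior(
    family: str,
    ess: float | None = None,
    null_rate: float = 0.3,
    alt_rate: float = 0.45,
) -> BetaPrior:
    """Build one of the named prior families.

    Parameters
    ----------
    family : {"jeffreys", "uniform", "skeptical", "enthusiastic"}
        ``jeffreys`` and ``uniform`` ignore ``ess``; ``skeptical`` centers on
        ``null_rate`` and ``enthusiastic`` on ``alt_rate``, each with the
        requested ESS.
    ess : float, optional
        Effective sample size for the informative families.
    null_rate, alt_rate : float
        The null (historical control) and alternative (sufficient) response
        rates; defaults match a design with p0 = 0.30 and p0 + delta* = 0.45.
    """
    fam = family.lower()
    if fam == "jeffreys":
        return BetaPrior(0.5, 0.5)
    if fam == "uniform":
        return BetaPrior(1.0, 1.0)
    if fam in ("skeptical", "enthusiastic"):
        if ess is None:
            raise InvalidParameterError(f"family {fam!r} requires an ESS")
        center = null_rate if fam == "skeptical" else alt_rate
        return from_mean_ess(center, ess)
    raise InvalidParameterError(
        f"unknown prior family {family!r}; expected one of {PRIOR_FAMILIES}"
    )
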