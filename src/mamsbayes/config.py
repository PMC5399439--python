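"""YAML run configuration shared by the CLI and library callers.

Schema (all sections optional except ``trial``)::

    seed: 1
    trial:
      control: A
      arms:
        A: {family: uniform}            # or {a: 1.0, b: 1.0}
        B: {family: skeptical, ess: 1}  # skeptical/enthusiastic need an ess
        C: {family: uniform}
    design:
      p0: 0.3
      delta: 0.0
      delta_star: 0.15
      gamma1: 0.9
      gamma2: 0.1
      gamma3: 0.9
      min_enrollment: 15
      gate_scope: trial                 # or: arm
      n_max: 40
    simulate:
      pi_control: 0.3
      dB: 0.0
      dC: 0.0
      n_per_arm: 40
      reps: 1000
      rule: fixed

Priors may be given either as a named family (``jeffreys``, ``uniform``,
``skeptical``, ``enthusiastic`` — the informative ones centered on
``design.p0`` and ``design.p0 + design.delta_star``) or as explicit beta
shapes ``{a, b}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError
from .priors import BetaPrior, named_prior
from .rules import DesignParams

__all__ = ["RunConfig", "load_config", "parse_prior"]

DEFAULT_ARMS = {"A": {"family": "uniform"}, "B": {"family": "uniform"}, "C": {"family": "uniform"}}


def parse_prior(
    spec: Mapping[str, Any], null_rate: float, alt_rate: float
) -> BetaPrior:
    """Parse one arm's prior declaration ({family[, ess]} or {a, b})."""
    if "a" in spec or "b" in spec:
        if not {"a", "b"} <= set(spec):
            raise ConfigurationError(
                f"explicit prior needs both 'a' and 'b', got {dict(spec)}"
            )
        return BetaPrior(float(spec["a"]), float(spec["b"]))
    if "family" not in spec:
        raise ConfigurationError(
            f"prior must declare 'family' or explicit 'a'/'b', got {dict(spec)}"
        )
    ess = spec.get("ess")
    return named_prior(
        str(spec["family"]),
        None if ess is None else float(ess),
        null_rate=null_rate,
        alt_rate=alt_rate,
    )


@dataclass(frozen=True)
class RunConfig:
    """Parsed trial configuration: arms, control, priors, design, scenario."""

    control: str
    priors: dict[str, BetaPrior]
    params: DesignParams
    simulate: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def experimental(self) -> list[str]:
        return [a for a in self.priors if a != self.control]


def load_config(path_or_mapping) -> RunConfig:
    """Load and validate a run configuration from YAML (path) or a mapping."""
    if isinstance(path_or_mapping, Mapping):
        raw: Mapping[str, Any] = path_or_mapping
    else:
        with open(path_or_mapping) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ConfigurationError("config root must be a mapping")

    design_raw = dict(raw.get("design", {}))
    try:
        params = DesignParams(**design_raw)
    except TypeError as exc:
        raise ConfigurationError(f"bad design section: {exc}") from exc

    trial = raw.get("trial", {})
    arms_raw = dict(trial.get("arms", DEFAULT_ARMS))
    control = trial.get("control", "A")
    if control not in arms_raw:
        raise ConfigurationError(
            f"control arm {control!r} is not declared among arms {sorted(arms_raw)}"
        )
    alt_rate = params.p0 + params.delta_star
    priors = {
        arm: parse_prior(spec or {}, params.p0, alt_rate)
        for arm, spec in arms_raw.items()
    }
    return RunConfig(
        control=str(control),
        priors=priors,
        params=params,
        simulate=dict(raw.get("simulate", {})),
        seed=int(raw.get("seed", 0)),
    )
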