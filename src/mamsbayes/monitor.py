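"""Sequential replay of a patient-level enrollment log.

The monitor replays an ordered log of (sequence, arm, outcome) records,
re-evaluating all three stopping rules after every observed outcome, and
records the full criteria trajectory plus the first look at which each
(arm, rule) pair triggered.  Criteria depend only on accumulated counts, so
the final look's report equals a single-look analysis of the final counts,
and permuting outcomes within an arm leaves that final report unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from .errors import LogParseError
from .posterior import ArmState, update
from .priors import BetaPrior
from .rules import DecisionReport, DesignParams, evaluate_look

__all__ = [
    "EnrollmentLog",
    "MonitoringTrace",
    "replay",
    "read_log",
    "write_log",
    "write_trace",
]

LOG_COLUMNS = ("seq", "arm", "outcome")
TRACE_COLUMNS = (
    "look",
    "arm",
    "n",
    "y",
    "crit1",
    "crit2",
    "crit3",
    "rule1",
    "rule2",
    "rule3",
)


@dataclass(frozen=True)
class EnrollmentLog:
    """Ordered (sequence_index, arm_id, outcome) records, gap-free from 1."""

    records: tuple[tuple[int, str, int], ...]

    def __post_init__(self) -> None:
        for i, (seq, arm, outcome) in enumerate(self.records, start=1):
            if seq != i:
                raise LogParseError(
                    f"record {i}: sequence index {seq} breaks the gap-free "
                    f"1..N ordering"
                )
            if outcome not in (0, 1):
                raise LogParseError(
                    f"record {i} (arm {arm!r}): outcome must be 0 or 1, "
                    f"got {outcome!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def arms(self) -> set[str]:
        return {arm for _, arm, _ in self.records}

    def final_counts(self) -> dict[str, tuple[int, int]]:
        """Mapping arm -> (y, n) at the end of the log."""
        counts: dict[str, list[int]] = {}
        for _, arm, outcome in self.records:
            c = counts.setdefault(arm, [0, 0])
            c[0] += outcome
            c[1] += 1
        return {arm: (y, n) for arm, (y, n) in counts.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=list(LOG_COLUMNS))


@dataclass(frozen=True)
class MonitoringTrace:
    """Per-look decision reports and cumulative first-trigger records.

    ``first_triggers`` maps ``(arm, rule_number)`` to the first look index at
    which that rule fired for that arm; an entry exists iff some look
    triggered it.  Each look's report carries both the overall look index and
    every arm's own ``n``, so trajectories can be plotted against either
    x-axis.
    """

    looks: tuple[tuple[int, DecisionReport], ...]
    first_triggers: dict[tuple[str, int], int]

    def __len__(self) -> int:
        return len(self.looks)

    def final_report(self) -> DecisionReport:
        if not self.looks:
            raise IndexError("empty trace has no final report")
        return self.looks[-1][1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for look, report in self.looks:
            for dec in report.arms:
                rows.append(
                    {
                        "look": look,
                        "arm": dec.arm,
                        "n": dec.n,
                        "y": dec.y,
                        "crit1": dec.crit1,
                        "crit2": dec.crit2,
                        "crit3": dec.crit3,
                        "rule1": dec.rule1,
                        "rule2": dec.rule2,
                        "rule3": dec.rule3,
                    }
                )
        return pd.DataFrame(rows, columns=list(TRACE_COLUMNS))


def replay(
    log: EnrollmentLog,
    priors: Mapping[str, BetaPrior],
    control: str,
    params: DesignParams,
    *,
    min_enrollment: int | None = 0,
) -> MonitoringTrace:
    """Replay a log, evaluating every rule after each observed outcome.

    ``min_enrollment`` overrides ``params.min_enrollment`` during the replay;
    the default 0 evaluates from the first patient, which is how a
    retrospective reanalysis of a completed stage is usually read (pass
    ``None`` to keep the params value, e.g. the simulator's gate of 15).
    Flags are advisory: the replay never drops an arm, so the trace shows
    what a live monitor would have displayed.
    """
    if min_enrollment is not None:
        params = replace(params, min_enrollment=min_enrollment)
    states: dict[str, ArmState] = {
        arm: ArmState(arm, prior, is_control=(arm == control))
        for arm, prior in priors.items()
    }
    if control not in states:
        raise LogParseError(f"control arm {control!r} has no prior assignment")
    looks = []
    first: dict[tuple[str, int], int] = {}
    for seq, arm, outcome in log.records:
        if arm not in states:
            raise LogParseError(
                f"record {seq}: arm {arm!r} is not in the trial configuration "
                f"({sorted(states)})"
            )
        states[arm] = update(states[arm], outcome)
        report = evaluate_look(list(states.values()), params)
        for dec in report.arms:
            for rule, flag in ((1, dec.rule1), (2, dec.rule2), (3, dec.rule3)):
                if flag:
                    first.setdefault((dec.arm, rule), seq)
        looks.append((seq, report))
    return MonitoringTrace(looks=tuple(looks), first_triggers=first)


def read_log(path) -> EnrollmentLog:
    """Read an enrollment log CSV with columns ``seq,arm,outcome``."""
    try:
        frame = pd.read_csv(path, comment="#")
    except Exception as exc:  # noqa: BLE001 - rewrap with context
        raise LogParseError(f"cannot read enrollment log {path}: {exc}") from exc
    missing = set(LOG_COLUMNS) - set(frame.columns)
    if missing:
        raise LogParseError(
            f"{path}: missing column(s) {sorted(missing)}; "
            f"expected header seq,arm,outcome"
        )
    records = []
    for row in frame.itertuples(index=True):
        try:
            records.append((int(row.seq), str(row.arm), int(row.outcome)))
        except (TypeError, ValueError) as exc:
            raise LogParseError(
                f"{path}, data line {row.Index + 1}: {exc}"
            ) from exc
    return EnrollmentLog(records=tuple(records))


def write_log(log: EnrollmentLog, path) -> None:
    log.to_frame().to_csv(path, index=False)


def write_trace(trace: MonitoringTrace, path) -> None:
    """Write the trace CSV (one row per look x arm, criteria to 4 decimals)."""
    frame = trace.to_frame()
    frame.to_csv(path, index=False, float_format="%.4f")
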