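"""Built-in toy cohorts.

Two deterministic families, both small enough to check by hand:

* :func:`toy_cohort` — 100 subjects followed with annual visits for three
  years: 10, 5 and 5 outcome events in years 1-3 (at mid-year, 0.5 / 1.5 /
  2.5), and 40 dropouts either early (scenario "A", mid-year 1) or late
  (scenario "B", mid-year 3); the remaining 40 are administratively censored
  at 3 years.  The early/late contrast is what separates the person-time
  rates from the Percentage Method, which is blind to dropout timing.
  ``n_dropout_events`` dropouts are given an oracle event at their dropout
  time; the rest are marked event-free through the horizon.

* :func:`curve_demo_cohort` — 100 subjects followed for two years with 30
  dropouts at mid-year 2 in both scenarios, but 30 early events (scenario
  "A") versus 10 (scenario "B").  The reverse Kaplan-Meier curve differs
  between the two even though dropout is identical; the competing-risk
  follow-up curve does not.
"""

from __future__ import annotations

from .cohort_io import NEVER_EVENT, Status, SubjectRecord

__all__ = ["toy_cohort", "curve_demo_cohort", "TOY_TAU", "CURVE_DEMO_TAU"]

TOY_TAU = 3.0
CURVE_DEMO_TAU = 2.0


def _block(start: int, count: int, time: float, status: Status,
           true_t: float | None) -> list[SubjectRecord]:
    return [
        SubjectRecord(f"s{start + i:03d}", time, status, true_t)
        for i in range(count)
    ]


def toy_cohort(scenario: str = "A", n_dropout_events: int = 0) -> list[SubjectRecord]:
    """The worked 3-year, 100-subject cohort (scenarios "A" / "B")."""
    scenario = scenario.upper()
    if scenario not in {"A", "B"}:
        raise ValueError(f"scenario must be 'A' or 'B', got {scenario!r}")
    if not 0 <= n_dropout_events <= 40:
        raise ValueError("n_dropout_events must lie in [0, 40]")
    dropout_time = 0.5 if scenario == "A" else 2.5
    subjects: list[SubjectRecord] = []
    subjects += _block(0, 10, 0.5, Status.EVENT, 0.5)
    subjects += _block(10, 5, 1.5, Status.EVENT, 1.5)
    subjects += _block(15, 5, 2.5, Status.EVENT, 2.5)
    # dropouts: the first n_dropout_events develop the event right after
    # leaving; the rest are event-free through the horizon
    subjects += _block(20, n_dropout_events, dropout_time, Status.DROPOUT, dropout_time)
    subjects += _block(
        20 + n_dropout_events, 40 - n_dropout_events, dropout_time,
        Status.DROPOUT, NEVER_EVENT,
    )
    subjects += _block(60, 40, TOY_TAU, Status.ADMIN_CENSORED, NEVER_EVENT)
    return subjects


def curve_demo_cohort(scenario: str = "A") -> list[SubjectRecord]:
    """The 2-year cohort contrasting reverse-KM and competing-risk curves."""
    scenario = scenario.upper()
    if scenario not in {"A", "B"}:
        raise ValueError(f"scenario must be 'A' or 'B', got {scenario!r}")
    n_events = 30 if scenario == "A" else 10
    subjects: list[SubjectRecord] = []
    subjects += _block(0, n_events, 0.5, Status.EVENT, 0.5)
    subjects += _block(n_events, 30, 1.5, Status.DROPOUT, NEVER_EVENT)
    n_admin = 100 - n_events - 30
    subjects += _block(
        n_events + 30, n_admin, CURVE_DEMO_TAU, Status.ADMIN_CENSORED, NEVER_EVENT
    )
    return subjects
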