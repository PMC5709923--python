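"""Closed-form follow-up-rate estimators.

All estimators take per-subject records truncated to a horizon ``tau`` and
return a percentage in ``[0, 100]``.  Notation: subject i has event time
``T_i`` and censoring (dropout) time ``C_i``; the study ends at ``tau``.

* ``percentage_rate`` — fraction of enrollees not lost to follow-up.
  Treats every dropout as contributing zero person-time, hence its
  well-known downward bias when dropout happens late.
* ``cci_rate`` — Clark's Completeness Index: observed person-time over
  potential person-time where each dropout is imagined followed to ``tau``.
  A lower bound for the true person-time follow-up rate.
* ``spt_rate`` — Simplified Person-Time rate: dropouts keep their observed
  time, events and survivors count as fully followed.  An upper bound.
* ``true_ptfr`` — the person-time follow-up rate itself,
  ``sum min(T_i, C_i, tau) / sum min(T_i, tau)``; computable only with
  oracle event times for the dropouts (simulations, toy cohorts).
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np

from .cohort_io import Status, SubjectRecord, VisitHistory
from .errors import OracleMissingError, PtfrError, UndefinedRateError

__all__ = [
    "percentage_rate",
    "cci_rate",
    "spt_rate",
    "true_ptfr",
    "ptfr_lower_bound",
    "observed_pt_irregular",
]


def _validate(subjects: Sequence[SubjectRecord], tau: float) -> None:
    if len(subjects) == 0:
        raise UndefinedRateError("cannot compute a follow-up rate for an empty cohort")
    if not tau > 0:
        raise UndefinedRateError(f"tau must be positive, got {tau}")
    for r in subjects:
        if r.exit_time > tau + 1e-9:
            raise PtfrError(
                f"subject {r.subject_id!r}: exit_time {r.exit_time} exceeds "
                f"tau={tau}; truncate the cohort to the horizon first"
            )


def _arrays(subjects: Sequence[SubjectRecord]):
    exit_t = np.fromiter((r.exit_time for r in subjects), float, len(subjects))
    dropout = np.fromiter(
        (r.status is Status.DROPOUT for r in subjects), bool, len(subjects)
    )
    return exit_t, dropout


def percentage_rate(subjects: Sequence[SubjectRecord], tau: float) -> float:
    """Percentage Method: ``100 * (N - #dropouts) / N``.

    Depends only on how many subjects were lost, never on when — the
    systematic error the person-time rates exist to correct.
    """
    _validate(subjects, tau)
    n = len(subjects)
    lost = sum(r.status is Status.DROPOUT for r in subjects)
    return 100.0 * (n - lost) / n


def cci_rate(subjects: Sequence[SubjectRecord], tau: float) -> float:
    """Clark's Completeness Index: observed / potential person-time.

    The numerator is ``sum min(T_i, C_i, tau)`` (each subject's observed
    time).  The denominator assigns the full ``tau`` to every dropout and
    the observed ``min(T_i, tau)`` to everyone else.
    """
    _validate(subjects, tau)
    exit_t, dropout = _arrays(subjects)
    observed = float(exit_t.sum())
    potential = float(np.where(dropout, tau, exit_t).sum())
    return 100.0 * observed / potential


def spt_rate(subjects: Sequence[SubjectRecord], tau: float) -> float:
    """Simplified Person-Time rate.

    Dropouts contribute their observed time ``C_i``; events and survivors
    contribute the full ``tau`` (an observed event already provided complete
    information about becoming a case).  Denominator ``N * tau``.
    """
    _validate(subjects, tau)
    exit_t, dropout = _arrays(subjects)
    numer = float(np.where(dropout, exit_t, tau).sum())
    return 100.0 * numer / (len(subjects) * tau)


def true_ptfr(subjects: Sequence[SubjectRecord], tau: float) -> float:
    """True person-time follow-up rate (needs oracle event times).

    ``100 * sum min(T_i, C_i, tau) / sum min(T_i, tau)`` — observed
    person-time over the person-time that would have accrued with no
    dropout.  Every dropout must carry ``true_event_time`` (possibly
    ``NEVER_EVENT`` for "event-free through tau").
    """
    _validate(subjects, tau)
    numer = 0.0
    denom = 0.0
    for r in subjects:
        numer += r.exit_time
        if r.status is Status.EVENT:
            denom += min(r.exit_time, tau)
        elif r.status is Status.ADMIN_CENSORED:
            denom += tau
        else:
            if r.true_event_time is None:
                raise OracleMissingError(
                    f"subject {r.subject_id!r}: dropout without true_event_time "
                    "(use NEVER_EVENT for dropouts known event-free through tau)"
                )
            denom += min(r.true_event_time, tau)
    return 100.0 * numer / denom


def ptfr_lower_bound(subjects: Sequence[SubjectRecord], tau: float) -> float:
    """Conservative bound on the true rate under informative censoring.

    Assuming every dropout stays event-free through ``tau`` maximises the
    no-dropout person-time, so the minimum attainable PTFR is exactly the
    completeness index.
    """
    return cci_rate(subjects, tau)


def observed_pt_irregular(histories: Sequence[VisitHistory],
                          t_target: float) -> float:
    """Observed person-time for irregular / ad-hoc visit schedules.

    A subject last seen event-free contributes their last visit time; a
    subject diagnosed at the last visit contributes the midpoint of the
    final inter-visit gap (the event occurred somewhere inside it).
    Contributions are capped at ``t_target``.
    """
    if not t_target > 0:
        raise PtfrError(f"t_target must be positive, got {t_target}")
    if len(histories) == 0:
        warnings.warn("observed_pt_irregular called with no histories", stacklevel=2)
        return 0.0
    total = 0.0
    for h in histories:
        if h.event_at_last_visit:
            prev = h.visit_times[-2] if len(h.visit_times) >= 2 else 0.0
            t = (prev + h.last_visit) / 2.0
        else:
            t = h.last_visit
        total += min(t, t_target)
    return total
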