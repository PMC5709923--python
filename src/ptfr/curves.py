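"""Follow-up-over-time curves.

Two step curves describe how completeness of follow-up evolves:

* :func:`reverse_km` — the reverse Kaplan-Meier curve: the product-limit
  estimator with the roles of event and censoring exchanged (loss to
  follow-up is the "event"; outcome events and administrative censoring are
  "censored").  Because outcome events leave the risk set, a burst of early
  events depresses this curve even when dropout is unchanged.
* :func:`competing_followup_curve` — the competing-risk correction: outcome
  events are treated as fully followed and never leave the risk set, so the
  curve depends only on the number and timing of dropouts.  Its mean height
  over ``[0, tau]`` equals the Simplified Person-Time rate (as a fraction),
  which is enforced as a test invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort_io import Status, SubjectRecord
from .errors import PtfrError, UndefinedRateError

__all__ = ["StepCurve", "reverse_km", "competing_followup_curve", "curve_auc"]


@dataclass(frozen=True)
class StepCurve:
    """Right-continuous step function on [0, domain_end], starting at 1.

    ``values[i]`` is the curve value immediately after ``knots[i]``.
    """

    knots: np.ndarray
    values: np.ndarray
    domain_end: float

    def __post_init__(self):
        k = np.asarray(self.knots, float)
        v = np.asarray(self.values, float)
        object.__setattr__(self, "knots", k)
        object.__setattr__(self, "values", v)
        if len(k) != len(v):
            raise PtfrError("knots and values must have equal length")
        if len(k) and np.any(np.diff(k) <= 0):
            raise PtfrError("knots must be strictly increasing")
        if np.any((v < -1e-12) | (v > 1 + 1e-12)):
            raise PtfrError("curve values must lie in [0, 1]")

    def __call__(self, t) -> np.ndarray | float:
        t_arr = np.atleast_1d(np.asarray(t, float))
        idx = np.searchsorted(self.knots, t_arr, side="right")
        vals = np.concatenate([[1.0], self.values])[idx]
        return vals if np.ndim(t) else float(vals[0])


def _require_cohort(subjects: Sequence[SubjectRecord]) -> None:
    if len(subjects) == 0:
        raise UndefinedRateError("cannot build a follow-up curve for an empty cohort")


def reverse_km(subjects: Sequence[SubjectRecord], tau: float) -> StepCurve:
    """Reverse Kaplan-Meier follow-up curve.

    Product-limit estimator treating DROPOUT as the event; EVENT and
    ADMIN_CENSORED leave the risk set as censorings.  At tied times,
    censorings are processed after dropouts (standard product-limit
    convention), i.e. they remain in the risk set for that factor.
    """
    _require_cohort(subjects)
    exit_t = np.array([r.exit_time for r in subjects])
    is_drop = np.array([r.status is Status.DROPOUT for r in subjects])
    drop_times = np.unique(exit_t[is_drop])
    knots, values = [], []
    s = 1.0
    for t in drop_times:
        at_risk = int(np.sum(exit_t >= t - 1e-12))
        d = int(np.sum(is_drop & np.isclose(exit_t, t)))
        s *= 1.0 - d / at_risk
        knots.append(t)
        values.append(s)
    return StepCurve(np.asarray(knots), np.asarray(values), float(tau))


def competing_followup_curve(subjects: Sequence[SubjectRecord],
                             tau: float) -> StepCurve:
    """Follow-up curve with outcome events retained as fully followed.

    Events never leave the risk set (the subdistribution treatment of a
    competing risk); with administrative censoring only at ``tau`` the curve
    is simply ``1 - (#dropouts by t) / N``, stepping at dropout times — so
    it is invariant to the amount and timing of outcome events.
    """
    _require_cohort(subjects)
    n = len(subjects)
    exit_t = np.array([r.exit_time for r in subjects])
    is_drop = np.array([r.status is Status.DROPOUT for r in subjects])
    drop_times = np.unique(exit_t[is_drop])
    knots, values = [], []
    cum = 0
    for t in drop_times:
        cum += int(np.sum(is_drop & np.isclose(exit_t, t)))
        knots.append(t)
        values.append(1.0 - cum / n)
    return StepCurve(np.asarray(knots), np.asarray(values), float(tau))


def curve_auc(curve: StepCurve, tau: float) -> float:
    """Exact integral of a step curve over [0, tau], divided by tau.

    For the competing-risk follow-up curve this equals the Simplified
    Person-Time rate as a fraction in [0, 1].
    """
    if not tau > 0:
        raise PtfrError(f"tau must be positive, got {tau}")
    area = 0.0
    prev_t, prev_v = 0.0, 1.0
    for t, v in zip(curve.knots, curve.values):
        if t >= tau:
            break
        area += (t - prev_t) * prev_v
        prev_t, prev_v = float(t), float(v)
    area += (tau - prev_t) * prev_v
    return area / tau
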