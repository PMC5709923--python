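"""Formal Person-Time (FPT) estimator of the follow-up rate.

The true person-time rate needs event times for the dropouts, which are
never observed.  The FPT replaces them with a prediction: the event-time
distribution is estimated from the observed, interval-censored data by the
Turnbull NPMLE, and the expected person-time of the cohort had nobody
dropped out is rebuilt from the fitted conditional event probabilities.

On a regular visit grid ``t_0=0 < t_1 < ... < t_K = tau``:

* conditional event probabilities
  ``P_k = [S(t_{k-1}) - S(t_k)] / S(t_{k-1})``;
* counterfactual cohort size ``N*_0 = N``, ``N*_k = N*_{k-1} (1 - P_k)``;
* expected no-dropout person-time
  ``PT_nodropout = sum_k len_k (N*_{k-1} - N*_{k-1} P_k / 2)`` — events are
  assumed to occur, on average, midway through their interval, mirroring the
  life-table convention used for the observed person-time;
* ``FPT = 100 * PT_observed / PT_nodropout``.

For irregular schedules there is no common grid; the same quantity is
computed directly as ``N * integral_0^tau S(t) dt`` with NPMLE mass placed
at support-interval midpoints (supports extending to the sentinel ``E``
represent subjects event-free past ``tau`` and contribute the full ``tau``).
On a regular grid the two formulas coincide.

Validity rests on non-informative dropout: the dropouts' event risk must
match that of subjects who stayed.  The Turnbull NPMLE is known to slightly
underestimate cumulative incidence, so the FPT inherits a small downward
bias at high event rates; this is documented rather than corrected.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .cohort_io import (
    DEFAULT_SENTINEL_E,
    FollowupReport,
    IntervalDatum,
    Status,
    SubjectRecord,
    VisitHistory,
    build_life_table,
    histories_to_intervals,
    life_table_observed_pt,
    subjects_to_intervals,
)
from .errors import OracleMissingError, PtfrError, UndefinedRateError
from .estimators import (
    cci_rate,
    observed_pt_irregular,
    percentage_rate,
    spt_rate,
    true_ptfr,
)
from .turnbull import NpmleFit, npmle_fit

__all__ = [
    "conditional_event_probs",
    "expected_nodropout_pt",
    "fpt_rate",
    "followup_report",
    "rates_from_life_table",
]


def conditional_event_probs(fit: NpmleFit, boundaries: Sequence[float]) -> np.ndarray:
    """Per-interval conditional event probabilities from a fitted NPMLE.

    ``P_k = [S(t_{k-1}) - S(t_k)] / S(t_{k-1})``, defined as 0 when nobody
    is left to fail (``S(t_{k-1}) = 0``).
    """
    b = np.asarray(boundaries, float)
    if b.ndim != 1 or len(b) < 2 or np.any(np.diff(b) <= 0):
        raise PtfrError("boundaries must be strictly increasing")
    s = fit.survival(b)
    prev, cur = s[:-1], s[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(prev > 0, (prev - cur) / np.where(prev > 0, prev, 1.0), 0.0)
    return np.clip(p, 0.0, 1.0)


def expected_nodropout_pt(
    probs: Sequence[float],
    n: int,
    boundaries: Sequence[float],
) -> float:
    """Expected person-time of an N-subject cohort with no dropout.

    Runs the counterfactual cohort forward through the visit grid with the
    given conditional event probabilities; each interval contributes its
    survivors in full and its events for half the interval (midpoint
    convention).  Equals ``N * t_K`` when all probabilities are zero.
    """
    p = np.asarray(probs, float)
    if np.any((p < -1e-12) | (p > 1 + 1e-12)):
        raise PtfrError("conditional probabilities must lie in [0, 1]")
    if n < 1:
        raise PtfrError("n must be >= 1")
    lengths = np.diff(np.asarray(boundaries, float))
    if len(lengths) != len(p):
        raise PtfrError("need one probability per interval")
    n_star = float(n)
    total = 0.0
    for length, pk in zip(lengths, p):
        total += length * (n_star - n_star * pk / 2.0)
        n_star *= 1.0 - pk
    return total


def _integrated_survival_midpoint(fit: NpmleFit, tau: float) -> float:
    """integral_0^tau S(t) dt with mass at support midpoints.

    The NPMLE is indeterminate within a support; placing each support's mass
    at its midpoint is the interval-censored analogue of the life-table
    midpoint convention.  Supports whose right endpoint exceeds ``tau``
    (in particular tail supports ending at the sentinel) hold subjects still
    event-free at ``tau`` and contribute the full horizon.
    """
    mids = fit.supports.mean(axis=1)
    beyond = fit.supports[:, 1] > tau + 1e-12
    event_time = np.where(beyond, np.inf, mids)
    return float(np.sum(fit.masses * np.minimum(event_time, tau)))


def fpt_rate(
    subjects: Sequence[SubjectRecord] | None = None,
    *,
    histories: Sequence[VisitHistory] | None = None,
    tau: float,
    boundaries: Sequence[float] | None = None,
    sentinel_e: float = DEFAULT_SENTINEL_E,
    tol: float = 1e-8,
    max_iter: int = 10000,
) -> float:
    """Formal Person-Time follow-up rate, as a percentage.

    Regular schedules: pass ``subjects`` plus the visit ``boundaries``
    (ending at ``tau``); observed person-time comes from the life-table
    midpoint formula.  Irregular schedules: pass visit ``histories``;
    observed person-time uses last-visit censoring and final-gap midpoints.
    """
    if (subjects is None) == (histories is None):
        raise PtfrError("pass exactly one of subjects= or histories=")
    if subjects is not None:
        if boundaries is None:
            raise PtfrError("regular-schedule FPT needs visit boundaries")
        b = np.asarray(boundaries, float)
        if abs(b[-1] - tau) > 1e-9:
            raise PtfrError(f"boundaries must end at tau={tau}")
        if len(subjects) == 0:
            raise UndefinedRateError("empty cohort")
        table = build_life_table(subjects, b)
        pt_observed = life_table_observed_pt(table)
        data = subjects_to_intervals(subjects, b, sentinel_e)
        fit = npmle_fit(data, tol=tol, max_iter=max_iter)
        probs = conditional_event_probs(fit, b)
        pt_nodropout = expected_nodropout_pt(probs, len(subjects), b)
    else:
        if len(histories) == 0:
            raise UndefinedRateError("empty cohort")
        pt_observed = observed_pt_irregular(histories, tau)
        data = histories_to_intervals(histories, sentinel_e)
        fit = npmle_fit(data, tol=tol, max_iter=max_iter)
        pt_nodropout = len(histories) * _integrated_survival_midpoint(fit, tau)
    if pt_nodropout <= 0:
        raise UndefinedRateError("expected no-dropout person-time is zero")
    return 100.0 * pt_observed / pt_nodropout


def rates_from_life_table(
    table,
    *,
    sentinel_e: float = DEFAULT_SENTINEL_E,
    compute_fpt: bool = True,
) -> FollowupReport:
    """All rates computable from a pre-aggregated life table.

    The horizon is the table's last boundary.  Exits are placed at interval
    midpoints (the same convention the table's person-time formula uses),
    which makes these rates identical to the subject-level ones whenever the
    underlying exits really did occur mid-interval.  The true person-time
    rate needs oracle event times and is never available from a life table.
    """
    b = np.asarray(table.boundaries, float)
    tau = float(b[-1])
    mids = (b[:-1] + b[1:]) / 2.0
    e = np.asarray(table.n_events, float)
    c = np.asarray(table.n_dropouts, float)
    n = table.n_at_risk[0]
    if n < 1:
        raise UndefinedRateError("empty life table")
    n_final = table.n_final
    d = float(c.sum())
    pt_observed = life_table_observed_pt(table)
    cci_denom = float((e * mids).sum()) + (d + n_final) * tau
    spt_numer = float((c * mids).sum()) + (n - d) * tau
    rate_fpt = None
    if compute_fpt:
        data = [
            IntervalDatum(b[k], b[k + 1], int(e[k]))
            for k in range(len(e))
            if e[k] > 0
        ] + [
            IntervalDatum(b[k], sentinel_e, int(c[k]))
            for k in range(len(c))
            if c[k] > 0
        ]
        if n_final > 0:
            data.append(IntervalDatum(tau, sentinel_e, n_final))
        fit = npmle_fit(data)
        probs = conditional_event_probs(fit, b)
        pt_nodropout = expected_nodropout_pt(probs, n, b)
        if pt_nodropout <= 0:
            raise UndefinedRateError("expected no-dropout person-time is zero")
        rate_fpt = 100.0 * pt_observed / pt_nodropout
    return FollowupReport(
        horizon_tau=tau,
        n_eligible=n,
        rate_percentage=100.0 * (n - d) / n,
        rate_cci=100.0 * pt_observed / cci_denom,
        rate_spt=100.0 * spt_numer / (n * tau),
        rate_fpt=rate_fpt,
    )


def followup_report(
    subjects: Sequence[SubjectRecord],
    tau: float,
    *,
    boundaries: Sequence[float] | None = None,
    sentinel_e: float = DEFAULT_SENTINEL_E,
    compute_fpt: bool = True,
) -> FollowupReport:
    """Assemble every computable rate for one horizon into a report.

    The true person-time rate is included only when every dropout carries an
    oracle event time; the FPT only when visit ``boundaries`` are supplied
    (and ``compute_fpt`` is not disabled).  ``subjects`` must already be
    truncated to ``tau``.
    """
    oracle_ok = all(
        r.true_event_time is not None
        for r in subjects
        if r.status is Status.DROPOUT
    )
    rate_true = true_ptfr(subjects, tau) if (oracle_ok and subjects) else None
    rate_fpt = None
    if compute_fpt and boundaries is not None:
        rate_fpt = fpt_rate(
            subjects, tau=tau, boundaries=boundaries, sentinel_e=sentinel_e
        )
    return FollowupReport(
        horizon_tau=tau,
        n_eligible=len(subjects),
        rate_percentage=percentage_rate(subjects, tau),
        rate_cci=cci_rate(subjects, tau),
        rate_spt=spt_rate(subjects, tau),
        rate_fpt=rate_fpt,
        rate_true_ptfr=rate_true,
    )
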