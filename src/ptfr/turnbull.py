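"""Turnbull's nonparametric MLE for interval-censored event times.

The estimator generalises the Kaplan-Meier product-limit curve to data in
which each subject's event time is only known to lie in a half-open interval
``(L_i, R_i]``.  All likelihood mass lives on the *maximal intersections*
("innermost" or Turnbull intervals): half-open intervals ``(q, p]`` whose
left endpoint is some observed ``L_i``, whose right endpoint is some
observed ``R_j``, and which contain no other observation endpoint strictly
inside.  On those supports the NPMLE is found by the self-consistency (EM)
iteration: each observation spreads its unit mass over the supports it
contains in proportion to the current mass vector, and the masses are
re-averaged.  The log-likelihood is non-decreasing along the iteration.

The NPMLE is indeterminate *within* a support interval; this module reports
the survival function as right-continuous with each support's mass placed at
its right endpoint.  Downstream code that needs point values (the FPT on a
regular visit grid) only ever evaluates at visit boundaries, where the NPMLE
is unique.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort_io import IntervalDatum
from .errors import ConvergenceWarning, PtfrError

__all__ = ["NpmleFit", "turnbull_support", "npmle_fit", "encode_exact_time"]

#: Width used to encode an exactly observed event time t as (t - eps, t].
EXACT_EPS = 1e-9


def encode_exact_time(t: float, weight: float = 1.0) -> IntervalDatum:
    """Encode an exactly observed event time as a vanishingly thin interval."""
    return IntervalDatum(t - EXACT_EPS, t, weight)


@dataclass(frozen=True)
class NpmleFit:
    """Fitted Turnbull NPMLE.

    Attributes
    ----------
    supports : array (J, 2) of disjoint, ordered Turnbull intervals (q_j, p_j].
    masses : probability assigned to each support; non-negative, sums to 1.
    loglik : final weighted log-likelihood.
    loglik_trace : log-likelihood after every EM iteration.
    n_iter : EM iterations performed.
    converged : whether the mass change fell below tolerance before max_iter.
    """

    supports: np.ndarray
    masses: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = field(repr=False, default=None)

    def survival(self, t) -> np.ndarray | float:
        """S(t) = 1 - (mass of supports wholly at or before t); S(0-) = 1.

        Right-continuous, with each support's mass at its right endpoint.
        """
        t_arr = np.atleast_1d(np.asarray(t, float))
        if np.any(t_arr < 0):
            raise PtfrError("survival requested at a negative time")
        rights = self.supports[:, 1]
        cum = np.concatenate([[0.0], np.cumsum(self.masses)])
        idx = np.searchsorted(rights, t_arr + 1e-12, side="left")
        s = 1.0 - cum[idx]
        s = np.clip(s, 0.0, 1.0)
        return s if np.ndim(t) else float(s[0])


def turnbull_support(data: Sequence[IntervalDatum]) -> np.ndarray:
    """Maximal intersections of the observation intervals.

    Merge-sort all endpoints, right endpoints ordered before left endpoints
    at equal values (``(q, q]`` is empty); every left endpoint immediately
    followed by a right endpoint delimits one support ``(q, p]``.
    """
    if len(data) == 0:
        raise PtfrError("no interval data supplied")
    endpoints = []
    for d in data:
        endpoints.append((d.left, 1))   # left, sorts after a right at same value
        endpoints.append((d.right, 0))
    endpoints.sort()
    supports = []
    prev_left = None
    for value, kind in endpoints:
        if kind == 1:
            prev_left = value
        else:
            if prev_left is not None:
                supports.append((prev_left, value))
                prev_left = None
    return np.asarray(supports, float)


def _membership(data: Sequence[IntervalDatum], supports: np.ndarray) -> np.ndarray:
    """Boolean (n_obs, J): support (q, p] contained in observation (l, r]."""
    lefts = np.array([d.left for d in data])[:, None]
    rights = np.array([d.right for d in data])[:, None]
    q = supports[None, :, 0]
    p = supports[None, :, 1]
    return (lefts <= q + 1e-12) & (p <= rights + 1e-12)


def npmle_fit(
    data: Sequence[IntervalDatum],
    tol: float = 1e-8,
    max_iter: int = 10000,
) -> NpmleFit:
    """Fit the NPMLE by self-consistency (EM) iteration.

    Initialisation is uniform over supports (deterministic).  Convergence is
    declared when the largest absolute mass change falls below ``tol``; at
    ``max_iter`` without convergence a :class:`ConvergenceWarning` is issued
    and the fit is returned with ``converged=False``.
    """
    if not tol > 0:
        raise PtfrError("tol must be positive")
    supports = turnbull_support(data)
    j = len(supports)
    a = _membership(data, supports)
    if not a.any(axis=1).all():
        bad = int(np.flatnonzero(~a.any(axis=1))[0])
        raise PtfrError(
            f"observation ({data[bad].left}, {data[bad].right}] contains no "
            "support interval — inconsistent interval data"
        )
    w = np.array([d.weight for d in data], float)
    total_w = w.sum()
    m = np.full(j, 1.0 / j)
    a_f = a.astype(float)
    trace = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        denom = a_f @ m
        trace.append(float(w @ np.log(denom)))
        m_new = m * (a_f.T @ (w / denom)) / total_w
        delta = float(np.max(np.abs(m_new - m)))
        m = m_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"NPMLE self-consistency did not converge in {max_iter} iterations",
            ConvergenceWarning,
            stacklevel=2,
        )
    final_loglik = float(w @ np.log(a_f @ m))
    trace.append(final_loglik)
    m = np.clip(m, 0.0, None)
    m /= m.sum()
    return NpmleFit(
        supports=supports,
        masses=m,
        loglik=final_loglik,
        n_iter=n_iter,
        converged=converged,
        loglik_trace=np.asarray(trace),
    )
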