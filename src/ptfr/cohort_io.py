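"""Domain types, CSV readers/writers and converters for cohort follow-up data.

The package works with three representations of the same cohort:

* per-subject records (:class:`SubjectRecord`) — one exit time and an exit
  status per participant, time measured in years from that subject's entry;
* visit histories (:class:`VisitHistory`) — the raw visit times for cohorts
  with intermittent or ad-hoc follow-up;
* a life table (:class:`LifeTable`) — per-interval counts at risk, events
  and dropouts on a common visit grid.

Converters in this module move between them and build the interval-censored
data (:class:`IntervalDatum`) consumed by the Turnbull NPMLE: an observed
event in visit interval k is only known to lie in ``(t_{k-1}, t_k]``, and a
subject lost to follow-up after visit ``t_j`` may fail any time in
``(t_j, E]`` where ``E`` is a sentinel far beyond the end of study.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import PtfrError, RowValidationError, SchemaError

#: Default sentinel right endpoint for open-ended censoring intervals, in
#: years.  Any value comfortably beyond the study horizon works; 100 years
#: exceeds every human follow-up study.
DEFAULT_SENTINEL_E = 100.0

#: Marker for "this dropout did not develop the event by the horizon".
#: Stored in ``SubjectRecord.true_event_time``; ``min(NEVER_EVENT, tau)``
#: then contributes the full horizon to counterfactual person-time.
NEVER_EVENT = math.inf

_TIME_EPS = 1e-9


class Status(Enum):
    """Exit status of a subject at the end of their observation.

    ``DROPOUT`` is loss to follow-up of any cause other than the event of
    interest; ``ADMIN_CENSORED`` is censoring caused solely by the study
    ending — the two must not be conflated, because every follow-up rate in
    this package penalises dropout but not administrative censoring.
    """

    EVENT = "event"
    DROPOUT = "dropout"
    ADMIN_CENSORED = "admin_censored"

    @classmethod
    def parse(cls, value) -> "Status":
        """Parse a CSV cell: case-insensitive names or codes 1/2/0."""
        if isinstance(value, Status):
            return value
        if isinstance(value, (int, np.integer)) or (
            isinstance(value, float) and float(value).is_integer()
        ):
            try:
                return {1: cls.EVENT, 2: cls.DROPOUT, 0: cls.ADMIN_CENSORED}[int(value)]
            except KeyError:
                raise PtfrError(f"unknown status code {value!r}") from None
        text = str(value).strip().lower()
        for member in cls:
            if text == member.value:
                return member
        if text in {"1", "2", "0"}:
            return cls.parse(int(text))
        raise PtfrError(f"unknown status {value!r}")


@dataclass(frozen=True, slots=True)
class SubjectRecord:
    """One participant's follow-up summary.

    Parameters
    ----------
    subject_id : opaque identifier.
    exit_time : years from entry to exit (event, dropout, or admin censoring).
    status : why observation ended.
    true_event_time : optional oracle event time in years, available only in
        simulations and toy cohorts.  ``NEVER_EVENT`` (``math.inf``) marks a
        subject known not to develop the event within the horizon.
    entry_offset : optional calendar offset (years from study start) for
        staggered-entry cohorts.
    """

    subject_id: str
    exit_time: float
    status: Status
    true_event_time: float | None = None
    entry_offset: float | None = None

    def __post_init__(self):
        if not (self.exit_time >= 0):
            raise PtfrError(
                f"subject {self.subject_id!r}: exit_time must be >= 0, "
                f"got {self.exit_time!r}"
            )
        if (
            self.status is Status.EVENT
            and self.true_event_time is not None
            and not math.isclose(self.true_event_time, self.exit_time, abs_tol=1e-9)
        ):
            raise PtfrError(
                f"subject {self.subject_id!r}: an observed event's "
                "true_event_time must equal its exit_time"
            )


@dataclass(frozen=True, slots=True)
class VisitHistory:
    """Visit times (years from entry) for one subject, ad-hoc schedules allowed."""

    subject_id: str
    visit_times: tuple[float, ...]
    event_at_last_visit: bool = False

    def __post_init__(self):
        times = tuple(float(t) for t in self.visit_times)
        object.__setattr__(self, "visit_times", times)
        if not times:
            raise PtfrError(f"subject {self.subject_id!r}: empty visit history")
        if any(t < 0 for t in times):
            raise PtfrError(f"subject {self.subject_id!r}: negative visit time")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise PtfrError(
                f"subject {self.subject_id!r}: visit times must be strictly increasing"
            )

    @property
    def last_visit(self) -> float:
        return self.visit_times[-1]


@dataclass(frozen=True, slots=True)
class LifeTable:
    """Actuarial life table on boundaries ``t_0=0 < t_1 < ... < t_K``.

    ``n_at_risk[k]`` is the count at the start of interval k (``N_{k-1}`` in
    actuarial notation); ``n_events`` / ``n_dropouts`` are the exits within
    the interval.  The bookkeeping identity
    ``N_k = N_{k-1} - N_Ek - N_Ck`` is enforced at construction.
    """

    boundaries: tuple[float, ...]
    n_at_risk: tuple[int, ...]
    n_events: tuple[int, ...]
    n_dropouts: tuple[int, ...]

    def __post_init__(self):
        b = tuple(float(t) for t in self.boundaries)
        object.__setattr__(self, "boundaries", b)
        for name in ("n_at_risk", "n_events", "n_dropouts"):
            object.__setattr__(self, name, tuple(int(v) for v in getattr(self, name)))
        k = len(b) - 1
        if k < 1 or any(y <= x for x, y in zip(b, b[1:])):
            raise PtfrError("boundaries must be strictly increasing with >= 1 interval")
        if not (len(self.n_at_risk) == len(self.n_events) == len(self.n_dropouts) == k):
            raise PtfrError("per-interval count vectors must have K entries")
        if any(v < 0 for v in self.n_at_risk + self.n_events + self.n_dropouts):
            raise PtfrError("life-table counts must be non-negative")
        for i in range(k):
            nxt = self.n_at_risk[i] - self.n_events[i] - self.n_dropouts[i]
            if nxt < 0:
                raise PtfrError(f"interval {i + 1}: more exits than subjects at risk")
            if i + 1 < k and self.n_at_risk[i + 1] != nxt:
                raise PtfrError(
                    f"interval {i + 2}: N_k = N_(k-1) - N_Ek - N_Ck violated"
                )

    @property
    def n_intervals(self) -> int:
        return len(self.boundaries) - 1

    @property
    def interval_lengths(self) -> np.ndarray:
        b = np.asarray(self.boundaries)
        return np.diff(b)

    @property
    def n_final(self) -> int:
        """Subjects still under observation at t_K."""
        return self.n_at_risk[-1] - self.n_events[-1] - self.n_dropouts[-1]


@dataclass(frozen=True, slots=True)
class IntervalDatum:
    """A half-open censoring interval ``(left, right]`` with a count weight."""

    left: float
    right: float
    weight: float = 1.0

    def __post_init__(self):
        if not (self.left < self.right):
            raise PtfrError(f"interval ({self.left}, {self.right}] is empty")
        if not (self.weight > 0):
            raise PtfrError("interval weight must be positive")


@dataclass(frozen=True, slots=True)
class FollowupReport:
    """All follow-up rates for one horizon, percentages in [0, 100].

    ``lower_bound`` equals ``rate_cci``: assuming every dropout stays
    event-free maximises counterfactual person-time, so the completeness
    index is the worst case for the true person-time rate even under
    informative censoring.  Construction enforces the identities that hold
    for every cohort: CCI <= SPT, and CCI <= true PTFR when the oracle rate
    is available.  The SPT usually also bounds the true rate from above,
    but not identically — a dropout whose counterfactual event falls soon
    after the dropout time can push the true rate past the SPT — so that
    direction is deliberately not a hard invariant.
    """

    horizon_tau: float
    n_eligible: int
    rate_percentage: float
    rate_cci: float
    rate_spt: float
    rate_fpt: float | None = None
    rate_true_ptfr: float | None = None

    def __post_init__(self):
        rates = [self.rate_percentage, self.rate_cci, self.rate_spt]
        rates += [r for r in (self.rate_fpt, self.rate_true_ptfr) if r is not None]
        if any(not (-1e-6 <= r <= 100 + 1e-6) for r in rates):
            raise PtfrError("rates must lie in [0, 100]")
        if self.rate_cci > self.rate_spt + 1e-9:
            raise PtfrError("invariant violated: CCI must not exceed SPT")
        if (
            self.rate_true_ptfr is not None
            and self.rate_cci > self.rate_true_ptfr + 1e-9
        ):
            raise PtfrError("invariant violated: CCI must not exceed the true PTFR")

    @property
    def lower_bound(self) -> float:
        return self.rate_cci


# ---------------------------------------------------------------------------
# CSV input / output
# ---------------------------------------------------------------------------

_SUBJECT_COLUMNS = ("subject_id", "exit_time", "status")
_SUBJECT_OPTIONAL = ("true_event_time", "entry_offset")


def _resolve(df: pd.DataFrame, schema: Mapping[str, str] | None, logical: str,
             required: bool) -> str | None:
    name = (schema or {}).get(logical, logical)
    if name in df.columns:
        return name
    if required:
        raise SchemaError(f"missing required column {name!r} (for {logical!r})")
    return None


def read_subjects(source, schema: Mapping[str, str] | None = None) -> list[SubjectRecord]:
    """Read per-subject records from a CSV path or stream.

    ``schema`` maps logical names (``subject_id``, ``exit_time``, ``status``,
    ``true_event_time``, ``entry_offset``) to actual column names.  Unknown
    columns are ignored; row order is preserved.  ``true_event_time`` accepts
    blanks (unknown), numbers, or the literal ``never`` / ``inf``.
    """
    df = pd.read_csv(source, dtype={"subject_id": str})
    cid = _resolve(df, schema, "subject_id", True)
    cexit = _resolve(df, schema, "exit_time", True)
    cstat = _resolve(df, schema, "status", True)
    ctrue = _resolve(df, schema, "true_event_time", False)
    coff = _resolve(df, schema, "entry_offset", False)

    records: list[SubjectRecord] = []
    for row_idx, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        try:
            true_t = None
            if ctrue is not None:
                raw = rowd[ctrue]
                if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                    true_t = None
                elif str(raw).strip().lower() in {"never", "inf", "infinity"}:
                    true_t = NEVER_EVENT
                else:
                    true_t = float(raw)
            offset = None
            if coff is not None:
                raw = rowd[coff]
                if raw is not None and not (isinstance(raw, float) and math.isnan(raw)):
                    offset = float(raw)
            records.append(
                SubjectRecord(
                    subject_id=str(rowd[cid]),
                    exit_time=float(rowd[cexit]),
                    status=Status.parse(rowd[cstat]),
                    true_event_time=true_t,
                    entry_offset=offset,
                )
            )
        except RowValidationError:
            raise
        except PtfrError as exc:
            raise RowValidationError(row_idx, str(exc)) from None
        except (TypeError, ValueError) as exc:
            raise RowValidationError(row_idx, str(exc)) from None
    return records


def write_subjects(records: Sequence[SubjectRecord], path) -> None:
    """Write subject records to CSV; inverse of :func:`read_subjects`."""
    rows = []
    for r in records:
        true_t: object
        if r.true_event_time is None:
            true_t = ""
        elif math.isinf(r.true_event_time):
            true_t = "never"
        else:
            true_t = r.true_event_time
        rows.append(
            {
                "subject_id": r.subject_id,
                "exit_time": r.exit_time,
                "status": r.status.value,
                "true_event_time": true_t,
                "entry_offset": "" if r.entry_offset is None else r.entry_offset,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_visit_histories(source, schema: Mapping[str, str] | None = None) -> list[VisitHistory]:
    """Read long-format visit histories: one row per visit.

    Columns (remappable via ``schema``): ``subject_id``, ``visit_time``,
    ``event_flag``.  The flag is meaningful on the last row of each subject;
    subjects appear in first-visit order of the file.
    """
    df = pd.read_csv(source, dtype={"subject_id": str})
    cid = _resolve(df, schema, "subject_id", True)
    ctime = _resolve(df, schema, "visit_time", True)
    cflag = _resolve(df, schema, "event_flag", True)
    histories = []
    for sid, group in df.groupby(cid, sort=False):
        times = tuple(float(t) for t in group[ctime])
        flag = bool(group[cflag].iloc[-1])
        histories.append(VisitHistory(str(sid), times, flag))
    return histories


def write_visit_histories(histories: Sequence[VisitHistory], path) -> None:
    rows = []
    for h in histories:
        for i, t in enumerate(h.visit_times):
            last = i == len(h.visit_times) - 1
            rows.append(
                {
                    "subject_id": h.subject_id,
                    "visit_time": t,
                    "event_flag": int(h.event_at_last_visit and last),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_life_table(source) -> LifeTable:
    """Read a pre-aggregated life table CSV.

    Columns: ``t_start, t_end, n_at_risk, n_events, n_dropouts``; rows must
    be contiguous intervals starting at 0.
    """
    df = pd.read_csv(source)
    for col in ("t_start", "t_end", "n_at_risk", "n_events", "n_dropouts"):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    starts = df["t_start"].to_numpy(float)
    ends = df["t_end"].to_numpy(float)
    if abs(starts[0]) > _TIME_EPS:
        raise SchemaError("life table must start at t=0")
    if not np.allclose(starts[1:], ends[:-1]):
        raise SchemaError("life-table intervals must be contiguous")
    return LifeTable(
        boundaries=(starts[0], *ends),
        n_at_risk=tuple(df["n_at_risk"]),
        n_events=tuple(df["n_events"]),
        n_dropouts=tuple(df["n_dropouts"]),
    )


def write_life_table(table: LifeTable, path) -> None:
    b = table.boundaries
    pd.DataFrame(
        {
            "t_start": b[:-1],
            "t_end": b[1:],
            "n_at_risk": table.n_at_risk,
            "n_events": table.n_events,
            "n_dropouts": table.n_dropouts,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Converters
# ---------------------------------------------------------------------------

def _interval_index(boundaries: Sequence[float], t: float) -> int:
    """1-based index k of the half-open interval (t_{k-1}, t_k] containing t.

    An exit exactly at a visit time belongs to the interval ending there
    (exits are detected at visits); t = 0 is clamped into the first interval.
    """
    b = np.asarray(boundaries, float)
    k = int(np.searchsorted(b, t - _TIME_EPS, side="left"))
    return max(k, 1)


def build_life_table(subjects: Sequence[SubjectRecord],
                     boundaries: Sequence[float]) -> LifeTable:
    """Aggregate subject records into a life table on a common visit grid.

    Events and dropouts count in the interval containing their exit time;
    administrative censoring at ``t_K`` contributes to no exit column.
    """
    b = tuple(float(t) for t in boundaries)
    if len(b) < 2 or any(y <= x for x, y in zip(b, b[1:])):
        raise PtfrError("boundaries must be strictly increasing with >= 1 interval")
    if abs(b[0]) > _TIME_EPS:
        raise PtfrError("boundaries must start at 0")
    t_k = b[-1]
    k = len(b) - 1
    events = [0] * k
    drops = [0] * k
    n = len(subjects)
    for r in subjects:
        if r.exit_time > t_k + _TIME_EPS:
            raise PtfrError(
                f"subject {r.subject_id!r}: exit_time {r.exit_time} exceeds t_K={t_k}"
            )
        if r.status is Status.ADMIN_CENSORED:
            if r.exit_time < t_k - _TIME_EPS:
                raise PtfrError(
                    f"subject {r.subject_id!r}: administrative censoring before "
                    f"t_K={t_k}; truncate the cohort to the horizon first"
                )
            continue
        idx = _interval_index(b, r.exit_time) - 1
        if r.status is Status.EVENT:
            events[idx] += 1
        else:
            drops[idx] += 1
    at_risk = []
    cur = n
    for i in range(k):
        at_risk.append(cur)
        cur -= events[i] + drops[i]
    return LifeTable(b, tuple(at_risk), tuple(events), tuple(drops))


def life_table_observed_pt(table: LifeTable) -> float:
    """Observed person-time under the actuarial midpoint convention.

    Each interval contributes ``len_k * (N_{k-1} - (N_Ek + N_Ck)/2)``:
    subjects exiting within an interval are assumed to do so, on average,
    midway through it.
    """
    n = np.asarray(table.n_at_risk, float)
    e = np.asarray(table.n_events, float)
    c = np.asarray(table.n_dropouts, float)
    return float(np.sum(table.interval_lengths * (n - (e + c) / 2.0)))


def subjects_to_intervals(
    subjects: Sequence[SubjectRecord],
    boundaries: Sequence[float],
    sentinel_e: float = DEFAULT_SENTINEL_E,
) -> list[IntervalDatum]:
    """Censoring intervals for the NPMLE from a regular visit grid.

    * event in visit interval k  ->  ``(t_{k-1}, t_k]``
    * dropout in visit interval k  ->  ``(t_{k-1}, E]`` — the subject's last
      visit was ``t_{k-1}`` and their event may occur any time afterwards
    * subject event-free at ``t_K``  ->  ``(t_K, E]``

    Identical intervals are aggregated into one weighted datum.
    """
    b = tuple(float(t) for t in boundaries)
    t_k = b[-1]
    if not sentinel_e > t_k:
        raise PtfrError(f"sentinel E={sentinel_e} must exceed t_K={t_k}")
    counts: Counter[tuple[float, float]] = Counter()
    for r in subjects:
        if r.status is Status.EVENT:
            k = _interval_index(b, r.exit_time)
            counts[(b[k - 1], b[k])] += 1
        elif r.status is Status.DROPOUT:
            k = _interval_index(b, r.exit_time)
            counts[(b[k - 1], sentinel_e)] += 1
        else:
            counts[(t_k, sentinel_e)] += 1
    return [IntervalDatum(l, rgt, w) for (l, rgt), w in sorted(counts.items())]


def histories_to_intervals(
    histories: Sequence[VisitHistory],
    sentinel_e: float = DEFAULT_SENTINEL_E,
) -> list[IntervalDatum]:
    """Censoring intervals for irregular / ad-hoc visit schedules.

    Event at the last visit -> ``(t_{K_i-1}, t_{K_i}]`` (previous visit, or
    entry at 0 when the event visit is the first); otherwise the subject was
    event-free when last seen -> ``(t_{K_i}, E]``.
    """
    counts: Counter[tuple[float, float]] = Counter()
    for h in histories:
        if h.event_at_last_visit:
            prev = h.visit_times[-2] if len(h.visit_times) >= 2 else 0.0
            counts[(prev, h.last_visit)] += 1
        else:
            if not sentinel_e > h.last_visit:
                raise PtfrError(
                    f"sentinel E={sentinel_e} must exceed last visit {h.last_visit}"
                )
            counts[(h.last_visit, sentinel_e)] += 1
    return [IntervalDatum(l, r, w) for (l, r), w in sorted(counts.items())]


def truncate_at_horizon(subjects: Iterable[SubjectRecord],
                        horizon: float) -> list[SubjectRecord]:
    """Truncate every record at ``horizon``.

    Exits after the horizon become administrative censorings at the horizon;
    a dropout exactly at the horizon is end-of-study censoring, not loss to
    follow-up.  Oracle event times are preserved.
    """
    out = []
    for r in subjects:
        if r.exit_time > horizon + _TIME_EPS or (
            r.status is Status.DROPOUT
            and math.isclose(r.exit_time, horizon, abs_tol=_TIME_EPS)
        ):
            out.append(
                replace(r, exit_time=horizon, status=Status.ADMIN_CENSORED)
            )
        else:
            out.append(r)
    return out


def eligible_subset(
    subjects: Sequence[SubjectRecord],
    horizon: float,
    study_span: float,
) -> list[SubjectRecord]:
    """Subjects with enough potential follow-up for a ``horizon``-year rate.

    With staggered entry, only subjects entering at least ``horizon`` years
    before the study closes (``entry_offset + horizon <= study_span``) can be
    assessed at that horizon; retained subjects are truncated at the horizon.
    """
    kept = []
    for r in subjects:
        if r.entry_offset is None:
            raise PtfrError(
                f"subject {r.subject_id!r}: entry_offset required for "
                "horizon-eligibility filtering"
            )
        if r.entry_offset + horizon <= study_span + _TIME_EPS:
            kept.append(r)
    return truncate_at_horizon(kept, horizon)
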