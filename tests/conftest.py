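"""Shared fixtures: deterministic random cohorts with oracle event times."""

from __future__ import annotations

import numpy as np
import pytest

from ptfr import NEVER_EVENT, Status, SubjectRecord
from ptfr.datasets import curve_demo_cohort, toy_cohort


def random_oracle_cohort(rng: np.random.Generator, tau: float = 5.0,
                         n: int | None = None) -> list[SubjectRecord]:
    """A cohort with continuous exponential event/dropout times and oracle T.

    Rates are themselves randomised so property tests sweep a wide range of
    event and dropout intensities.
    """
    n = n or int(rng.integers(2, 60))
    lam = rng.uniform(0.01, 0.6)
    mu = rng.uniform(0.01, 0.8)
    t = rng.exponential(1.0 / lam, n)
    c = rng.exponential(1.0 / mu, n)
    records = []
    for i, (ti, ci) in enumerate(zip(t, c)):
        if ti <= ci and ti <= tau:
            records.append(SubjectRecord(str(i), float(ti), Status.EVENT, float(ti)))
        elif ci < ti and ci < tau:
            true_t = float(ti) if ti <= tau else NEVER_EVENT
            records.append(SubjectRecord(str(i), float(ci), Status.DROPOUT, true_t))
        else:
            records.append(
                SubjectRecord(str(i), float(tau), Status.ADMIN_CENSORED, NEVER_EVENT)
            )
    return records


@pytest.fixture
def toy_a():
    return toy_cohort("A")


@pytest.fixture
def toy_b():
    return toy_cohort("B")


@pytest.fixture
def toy_a_events():
    return toy_cohort("A", n_dropout_events=5)


@pytest.fixture
def curve_a():
    return curve_demo_cohort("A")


@pytest.fixture
def curve_b():
    return curve_demo_cohort("B")
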