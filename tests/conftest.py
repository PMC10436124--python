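import numpy as np
import pandas as pd
import pytest

from qgsurv import Cohort, GeneratorConfig, make_cohort

SCHEMA_2 = {"sex": ["male", "female"]}


def toy_cohort(rows, covariate_schema=None, exposure_names=("pm25",)):
    """Build a Cohort from (subject_id, start, stop, event, pm25[, sex]) tuples."""
    cols = ["subject_id", "start", "stop", "event", *exposure_names]
    if covariate_schema:
        cols += list(covariate_schema)
    df = pd.DataFrame(rows, columns=cols)
    return Cohort(df, list(exposure_names), covariate_schema or {})


@pytest.fixture
def three_subject_cohort():
    """Hand-sized counting-process fixture: 3 subjects, staggered intervals,
    2 events, one covariate.  Small enough for risk sets to be enumerated by
    hand or by the brute-force oracle."""
    rows = [
        ("a", 0.0, 1.0, 0, 31.0),
        ("a", 1.0, 2.5, 1, 55.0),
        ("b", 0.0, 1.0, 0, 40.0),
        ("b", 1.0, 2.0, 0, 47.0),
        ("b", 2.0, 3.0, 1, 52.0),
        ("c", 0.5, 1.5, 0, 36.0),
        ("c", 1.5, 3.5, 0, 44.0),
    ]
    return toy_cohort(rows)


@pytest.fixture(scope="session")
def small_sim_cohort():
    """One simulated mid-size cohort shared by read-only tests."""
    cfg = GeneratorConfig(n_subjects=1200)
    cohort, summary = make_cohort(cfg, seed=42)
    return cohort, summary


def brute_partial_loglik(beta, X, start, stop, event, ties="efron"):
    """Independent brute-force Cox partial log-likelihood.

    Direct enumeration over event times and risk sets, written without any
    of the package's vectorized bucketing; the test oracle for cox_loglik.
    """
    beta = np.asarray(beta, float)
    X = np.atleast_2d(np.asarray(X, float))
    eta = X @ beta
    w = np.exp(eta)
    n = len(start)
    ll = 0.0
    for t in sorted(set(stop[i] for i in range(n) if event[i] == 1)):
        D = [i for i in range(n) if event[i] == 1 and stop[i] == t]
        R = [i for i in range(n) if start[i] < t <= stop[i]]
        d = len(D)
        s0 = sum(w[i] for i in R)
        s0d = sum(w[i] for i in D)
        for i in D:
            ll += eta[i]
        for l in range(d):
            frac = l / d if ties == "efron" else 0.0
            ll -= np.log(s0 - frac * s0d)
    return ll
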