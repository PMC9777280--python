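import numpy as np
import pytest

from trajsurv.cohort import CohortTable, CovariateSpec


def make_cohort(values, time, event, specs=None, mask=None, ids=None, dates=None):
    """Hand-built cohort helper used across the suite."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, m = values.shape
    if specs is None:
        specs = [CovariateSpec(f"x{j+1}") for j in range(m)]
    if mask is None:
        mask = np.zeros_like(values, dtype=bool)
    if ids is None:
        ids = np.array([f"P{i:03d}" for i in range(n)], dtype=object)
    return CohortTable(specs=list(specs), values=values, mask=np.asarray(mask, bool),
                       time=np.asarray(time, float), event=np.asarray(event, int),
                       patient_ids=np.asarray(ids, object), admission_date=dates)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_cohort(rng, n=None, n_inv=None, n_tv=None, missing=0.1,
                  with_dates=False):
    """Random valid cohort with a mix of invariant/time-varying covariates."""
    n = n or int(rng.integers(1, 40))
    n_inv = n_inv if n_inv is not None else int(rng.integers(0, 4))
    n_tv = n_tv if n_tv is not None else int(rng.integers(0, 3))
    if n_inv + n_tv == 0:
        n_inv = 1
    specs = [CovariateSpec(f"a{j}", "continuous", "invariant") for j in range(n_inv)]
    specs += [CovariateSpec(f"z{j}", "continuous", "time_varying") for j in range(n_tv)]
    m = n_inv + 2 * n_tv
    values = rng.normal(size=(n, m)).round(6)
    mask = rng.uniform(size=(n, m)) < missing
    values[mask] = 0.0
    dates = None
    if with_dates:
        dates = (np.datetime64("2018-01-01") +
                 rng.integers(0, 1000, size=n).astype("timedelta64[D]"))
    return make_cohort(values, rng.exponential(20, size=n).round(4),
                       rng.integers(0, 2, size=n), specs=specs, mask=mask,
                       dates=dates)
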