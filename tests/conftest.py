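import dataclasses

import numpy as np
import pytest

from gluforecast.cgm_io import GlucoseSeries
from gluforecast.synthetic_cgm import default_cohort_config, simulate_cohort

T0 = np.datetime64("2022-03-01T00:00:00", "s")
STEP5 = np.timedelta64(300, "s")


def regular_series(values, patient="P001", start=T0, interval_s=300, cal=None):
    values = np.asarray(values, dtype=np.float64)
    ts = start + np.arange(len(values)) * np.timedelta64(interval_s, "s")
    return GlucoseSeries(patient, ts, values, cal)


@pytest.fixture(scope="session")
def small_cohort():
    """2 patients x 4 days: the reduced benchmark cohort."""
    cfg = dataclasses.replace(
        default_cohort_config(), n_patients=2, days_per_patient=4
    )
    return simulate_cohort(cfg, seed=1)


@pytest.fixture(scope="session")
def tiny_cohort():
    """1 patient x 2 days: fastest end-to-end fixture (576 samples)."""
    cfg = dataclasses.replace(
        default_cohort_config(),
        n_patients=1,
        days_per_patient=2,
        gap_rate_per_day=0.0,
    )
    return simulate_cohort(cfg, seed=3)
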