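import numpy as np
import pandas as pd
import pytest

from sedtriad import datasets
from sedtriad.doseresponse import DoseResponseSeries, log_logistic


@pytest.fixture(scope="session")
def guidelines():
    return datasets.load_guidelines()


@pytest.fixture(scope="session")
def chemistry_records():
    return datasets.load_sediment_chemistry()


@pytest.fixture(scope="session")
def chemistry_by_site(chemistry_records):
    return {c.site: c for c in chemistry_records}


@pytest.fixture(scope="session")
def biomarker_panel():
    return datasets.load_biomarker_panel()


@pytest.fixture(scope="session")
def ec50_table():
    return datasets.load_ec50_estimates()


@pytest.fixture(scope="session")
def loe_matrix():
    return datasets.build_loe_matrix()


def make_series(ec50, slope, doses=(0, 5, 10, 25, 50, 100, 200), upper=100.0,
                endpoint="viability_pct", direction_sign=1, noise_sd=0.0,
                replicates=1, rng=None, fpg=False):
    """Build a DoseResponseSeries around a log-logistic truth curve."""
    doses = np.asarray(doses, dtype=float)
    mu = log_logistic(doses, ec50, direction_sign * slope, 0.0, upper)
    rows = []
    for rep in range(replicates):
        y = mu.copy()
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=doses.size)
        for d, v in zip(doses, y):
            rows.append({"concentration": d, "replicate": rep, "response": v})
    return DoseResponseSeries(site="sim", fraction=1, endpoint=endpoint, fpg=fpg,
                              observations=pd.DataFrame(rows))
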