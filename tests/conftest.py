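import numpy as np
import pytest

from mesolim import default_cohort_config, generate_cohort, load_response
from mesolim.records import standardize_units_frame
from mesolim.temperature import derive_gas_exchange


@pytest.fixture(scope="session")
def tobacco():
    return load_response("tobacco")


@pytest.fixture(scope="session")
def arabidopsis():
    return load_response("arabidopsis")


@pytest.fixture(scope="session")
def cohort():
    """A clean six-PFT synthetic compilation (no planted violations)."""
    return generate_cohort(default_cohort_config(seed=7, n_per_pft=40))


@pytest.fixture(scope="session")
def standardised_cohort(cohort, tobacco):
    """Cohort after unit standardisation and g_m,25 / Fick's-law derivation."""
    return derive_gas_exchange(standardize_units_frame(cohort), tobacco)


@pytest.fixture()
def cohort_csv(cohort, tmp_path):
    path = tmp_path / "cohort.csv"
    cohort.to_csv(path, index=False)
    return path


def type7_quartiles(values):
    """Independent type-7 quantile oracle (hand-rolled linear interpolation)."""
    s = np.sort(np.asarray(values, dtype=float))
    out = []
    for q in (0.25, 0.75):
        pos = (len(s) - 1) * q
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        out.append(s[lo] + (pos - lo) * (s[hi] - s[lo]))
    return out[0], out[1]
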