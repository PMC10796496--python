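import numpy as np
import pytest

from htestrat.cohort import printed_cerehetis_cohort, records_to_frame
from htestrat.logit import fit_logit
from htestrat.scores import compute_hti
from htestrat.simulate import default_cerehetis_config, generate_cohort


@pytest.fixture(scope="session")
def grouped():
    return printed_cerehetis_cohort()


@pytest.fixture(scope="session")
def units(grouped):
    """Unit-record expansion of the published grouped cohort."""
    return grouped.expand_units()


@pytest.fixture(scope="session")
def sht_fit(units):
    """Treatment + HTI logit for symptomatic HT on the published cohort."""
    return fit_logit(units["sht"].to_numpy(), units[["arm", "hti"]])


@pytest.fixture(scope="session")
def synth_frame():
    """A mid-sized synthetic cohort with recomputed HTI, as a DataFrame."""
    cfg = default_cerehetis_config(n=4000, seed=202)
    df = records_to_frame(generate_cohort(cfg))
    df["hti"] = [
        compute_hti(a, n, hm, af)
        for a, n, hm, af in zip(df.aspects, df.nihss, df.hmca, df.af_ecg)
    ]
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
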