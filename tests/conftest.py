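import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lakehealth.synthetic import (apply_censoring, generate_abiotic,
                                  generate_plankton, taihu_design,
                                  taihu_lods, taihu_response_spec,
                                  taihu_variable_specs)

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def abiotic_396():
    """One seeded 396-row synthetic monitoring table."""
    return generate_abiotic(taihu_design(), taihu_variable_specs(), seed=7)


@pytest.fixture(scope="session")
def censored_396(abiotic_396):
    return apply_censoring(abiotic_396, taihu_lods())


@pytest.fixture(scope="session")
def plankton_396(abiotic_396):
    return generate_plankton(abiotic_396, taihu_response_spec(), seed=7)


def make_sample(rows):
    """Long-format plankton sample from (taxon, group, biomass) triples."""
    return pd.DataFrame(
        [{"site_id": "S01", "month": 1, "taxon": t, "group": g,
          "wet_biomass_mg_per_L": b} for t, g, b in rows])
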