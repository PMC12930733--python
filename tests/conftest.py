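"""Shared fixtures: synthetic populations and amputed cohorts.

Everything is generated programmatically with fixed seeds; expensive
populations are session-scoped so the suite draws its samples from one
realisation of the registry-like generator.
"""

import dataclasses

import numpy as np
import pytest

import ordmisim as om


@pytest.fixture(scope="session")
def population_50k():
    """Default-calibration population at the size the generator contracts
    are specified against."""
    return om.generate_population(om.GeneratorConfig(population_size=50_000,
                                                     seed=2026))


@pytest.fixture(scope="session")
def population_uncensored():
    cfg = dataclasses.replace(om.GeneratorConfig(population_size=50_000,
                                                 seed=7), censoring=None)
    return om.generate_population(cfg)


@pytest.fixture(scope="session")
def cohort_5k(population_50k):
    return om.sample_population(population_50k, 5000, seed=11)


@pytest.fixture(scope="session")
def amputed_5k(cohort_5k):
    """N = 5,000 cohort with 20% of ECOG deleted completely at random."""
    amp, realized, _ = om.ampute(
        cohort_5k, om.AmputationConfig("MCAR", 0.2, seed=13))
    return amp


@pytest.fixture(scope="session")
def predictors_5k(amputed_5k):
    return om.build_predictors(amputed_5k)


@pytest.fixture(scope="session")
def toy_records():
    """Hand-sized tidy records frame for metric arithmetic."""
    import pandas as pd

    rows = []
    for rep, est in enumerate([0.9, 1.0, 1.1]):
        rows.append(dict(scenario="s", replicate=rep, method="m",
                         term="ecog_1", truth=1.0, estimate=est,
                         ci_low=0.5, ci_high=1.5, failed=False))
    return pd.DataFrame(rows)
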