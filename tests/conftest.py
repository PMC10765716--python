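import numpy as np
import pandas as pd
import pytest

from fraildex.codebook import default_schema
from fraildex.frailty import score_cohort
from fraildex.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def big_cohort():
    """One large default cohort shared by distribution-level tests."""
    return generate_cohort(GeneratorConfig(n=20_000, seed=20))


@pytest.fixture(scope="session")
def small_cohort():
    """Default cohort at survey scale, with scored FI merged in."""
    cohort = generate_cohort(GeneratorConfig(n=2561, seed=42))
    fi = score_cohort(cohort.baseline, default_schema())
    data = (
        cohort.baseline[["person_id", "age", "sex", "education", "living_alone"]]
        .merge(fi, on="person_id")
        .merge(cohort.outcomes, on="person_id")
    )
    return cohort, data


def make_analysis_frame(cohort, schema=None):
    """Join baseline covariates, scored FI and outcomes for model fitting."""
    fi = score_cohort(cohort.baseline, schema or default_schema())
    return (
        cohort.baseline[["person_id", "age", "sex", "education", "living_alone"]]
        .merge(fi, on="person_id")
        .merge(cohort.outcomes, on="person_id")
    )


def blank_responses(schema):
    """A full set of deficit-free responses (first level of every item)."""
    return {spec.item_id: spec.codes[0] for spec in schema}
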