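import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from metaborank import MetaboliteTable, SampleMetadata, SyntheticConfig, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


def make_table(values, mask=None, drug_flags=None, scale="raw", pathways=None):
    """Hand-built MetaboliteTable from a 2-D array."""
    values = np.array(values, dtype=float)  # copy: tests mutate tables freely
    n, p = values.shape
    samples = pd.Index([f"S{i}" for i in range(n)], name="sample_id")
    mets = pd.Index([f"m{j}" for j in range(p)], name="metabolite_id")
    vals = pd.DataFrame(values, index=samples, columns=mets)
    m = pd.DataFrame(
        np.zeros((n, p), bool) if mask is None else np.asarray(mask, bool),
        index=samples,
        columns=mets,
    )
    ann = pd.DataFrame(
        {
            "name": mets,
            "super_pathway": pathways if pathways is not None else ["Amino Acid"] * p,
            "sub_pathway": ["sub"] * p,
            "is_drug_metabolite": drug_flags if drug_flags is not None else [False] * p,
        },
        index=mets,
    )
    return MetaboliteTable(values=vals, below_lod=m, annotations=ann, scale=scale)


def make_metadata(outcome):
    outcome = np.asarray(outcome, dtype=int)
    idx = pd.Index([f"S{i}" for i in range(len(outcome))], name="sample_id")
    return SampleMetadata(frame=pd.DataFrame({"died": outcome}, index=idx))


@pytest.fixture(scope="session")
def default_cohort():
    """The study-condition cohort: 60 x 411, 13 planted effects, 42% events."""
    return generate_cohort(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort for pipeline-level tests."""
    return generate_cohort(
        SyntheticConfig(
            n_samples=40, n_metabolites=60, n_pathways=4, n_effect_metabolites=5, seed=7
        )
    )
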