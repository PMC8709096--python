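import pandas as pd
import pytest

from uropept import datasets
from uropept.core import AbundanceMatrix, clinical_frame
from uropept.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def table1_peptides():
    return datasets.load_peptide_annotation()


@pytest.fixture(scope="session")
def protein_sequences():
    return datasets.load_protein_sequences()


@pytest.fixture(scope="session")
def cohort_table():
    return datasets.load_cohort_table()


@pytest.fixture(scope="session")
def default_cohort(table1_peptides):
    """One default synthetic cohort (n=2000, seed=1), shared across tests."""
    records, matrix, truth = generate_cohort(
        GeneratorConfig(n_subjects=2000, seed=1), table1_peptides
    )
    return clinical_frame(records), matrix, truth


@pytest.fixture
def toy_matrix():
    """3 samples x 3 peptides with one non-detection."""
    frame = pd.DataFrame(
        {
            "p1": [10.0, 5.0, 2.0],
            "p2": [1.0, None, 3.0],
            "p3": [4.0, 6.0, 8.0],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    return AbundanceMatrix(frame)
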