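import numpy as np
import pandas as pd
import pytest

from mdlca.preprocess import ExpressionProfile, PreprocessConfig
from mdlca.pipeline import prepare_cohort
from mdlca.synthetic_data import SyntheticCohortSpec, generate_cohort_arrays


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_profiles(matrix: np.ndarray, genes=None, patients=None):
    """Expression profiles from a genes x patients matrix."""
    n_genes, n_patients = matrix.shape
    genes = genes or [f"G{i}" for i in range(n_genes)]
    patients = patients or [f"P{j}" for j in range(n_patients)]
    return [ExpressionProfile(values=pd.Series(matrix[:, j], index=genes),
                              patient_id=patients[j])
            for j in range(n_patients)]


@pytest.fixture(scope="session")
def small_cohort_arrays():
    spec = SyntheticCohortSpec(n_patients=18, volume_side=16, n_genes=24,
                               n_modules=3, effect_size=3.0, seed=7)
    return spec, generate_cohort_arrays(spec)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_arrays):
    _, c = small_cohort_arrays
    return prepare_cohort(c["volumes"], c["masks"], c["profiles"],
                          c["labels"], c["patient_ids"],
                          pre_cfg=PreprocessConfig(target_side=16))
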