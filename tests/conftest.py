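import numpy as np
import pandas as pd
import pytest

from recurpath.io import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    genes = [f"G{i}" for i in range(30)]
    samples = [f"S{i}" for i in range(8)]
    values = rng.lognormal(4.0, 1.0, size=(30, 8))
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), "raw_counts")


@pytest.fixture
def paired_meta():
    rows = []
    for i in range(1, 5):
        rows.append({"sample_id": f"P{i}", "patient_id": f"pt{i}", "tissue_class": "primary",
                     "cohort": "study", "histology_label": "hcc"})
        rows.append({"sample_id": f"R{i}", "patient_id": f"pt{i}", "tissue_class": "recurrent",
                     "cohort": "study", "histology_label": "hcc"})
    return pd.DataFrame(rows)
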