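import numpy as np
import pandas as pd
import pytest

from cfrna import CountMatrix, SampleTable, default_design, generate_counts


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """2x2 deterministic count matrix."""
    df = pd.DataFrame(
        [[1, 2], [3, 4]], index=["g1", "g2"], columns=["s1", "s2"]
    )
    return CountMatrix(df, pd.Series(["protein_coding", "lncRNA"], index=df.index))


@pytest.fixture
def tiny_samples() -> SampleTable:
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2"],
                "subject_id": ["p1", "p2"],
                "group": ["control", "DLBCL"],
                "coo_label": [None, "GCB"],
                "timepoint": ["diagnosis", "diagnosis"],
                "plasma_volume": [0.2, 0.2],
                "ldh": [200.0, 428.0],
            }
        )
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded synthetic cohort with planted disease/COO/prognostic structure."""
    design = default_design(seed=1234, n_genes=600)
    counts, samples, truth = generate_counts(design)
    return design, counts, samples, truth
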