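import numpy as np
import pandas as pd
import pytest

from microstab import simulate
from microstab.tables import GenusCountTable, MetadataTable


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared across tests (seed fixed)."""
    return simulate.generate_cohort(simulate.SimConfig(seed=42))


@pytest.fixture()
def tiny_counts():
    """3 genera x 4 samples toy table (2 subjects x 2 timepoints)."""
    data = pd.DataFrame(
        {
            "S1_T0": [10, 5, 0],
            "S1_T1": [8, 6, 1],
            "S2_T0": [0, 2, 9],
            "S2_T1": [1, 1, 10],
        },
        index=["Lactobacillus", "Gardnerella", "Prevotella"],
    )
    return GenusCountTable(data)


@pytest.fixture()
def tiny_metadata(tiny_counts):
    rows = []
    for sid in tiny_counts.samples:
        subject, tp = sid.rsplit("_", 1)
        rows.append({
            "sample": sid, "subject": subject,
            "cohort": "cancer" if subject == "S1" else "healthy",
            "timepoint": tp, "age": 60.0, "BMI": 27.0, "race": "Caucasian",
            "pH": 4.5,
        })
    return MetadataTable(pd.DataFrame(rows).set_index("sample"))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
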