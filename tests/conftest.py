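from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from secretodiff import LogIntensityMatrix, StudyDesign

DATA = Path(__file__).parent / "data"


@pytest.fixture
def toy_paths():
    return {
        "protein_groups": DATA / "toy_proteinGroups.txt",
        "design": DATA / "toy_design.tsv",
        "gocc": DATA / "toy_gocc.tsv",
    }


@pytest.fixture
def toy_design():
    from secretodiff import read_design

    return read_design(DATA / "toy_design.tsv")


def make_design(groups, batch="b1", untreated="UT"):
    """groups: {condition: n_replicates} (single batch helper)."""
    rows = []
    for cond, n in groups.items():
        for i in range(1, n + 1):
            rows.append({"sample_id": f"{batch}_{cond}_{i}", "batch": batch,
                         "condition": cond, "donor": str(i), "replicate": i})
    return StudyDesign(pd.DataFrame(rows), untreated_label=untreated)


def make_matrix(values, design, stage="raw_log2"):
    """values: dict protein -> list of floats/np.nan ordered as design samples."""
    df = pd.DataFrame(values, index=design.sample_ids).T
    batch_of = dict(zip(design.table["sample_id"], design.table["batch"]))
    return LogIntensityMatrix(df, stage=stage, batch_of_sample=batch_of)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
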