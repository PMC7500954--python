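import numpy as np
import pandas as pd
import pytest

from cytoruv import CellTable, PanelTable, SampleSheet, arcsinh_transform
from cytoruv.synthetic import default_study, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """Paper-like two-batch preset at desk scale (24 samples x 150 cells)."""
    config = default_study("two_batch_paper_like", cells_per_sample=150, seed=3)
    return simulate_study(config)


@pytest.fixture(scope="session")
def small_study_arcsinh(small_study):
    return arcsinh_transform(small_study.cells_raw)


@pytest.fixture()
def tiny_panel():
    return PanelTable(
        pd.DataFrame(
            {
                "metal": ["M1", "M2", "M3"],
                "antigen": ["CD3", "CD19", "pSTAT1"],
                "class": ["lineage", "lineage", "functional"],
            }
        )
    )


def make_cells(values, sample_id=None, batch=None, names=None):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return CellTable(
        values,
        np.asarray(sample_id if sample_id is not None else ["s1"] * m),
        np.asarray(batch if batch is not None else [1] * m),
        list(names) if names is not None else [f"p{i}" for i in range(n)],
    )


@pytest.fixture()
def two_batch_sheet():
    def _sheet(n_patients=2, batches=(1, 2), prefix="P"):
        rows = []
        for b in batches:
            for i in range(n_patients):
                rows.append(
                    {
                        "sample_id": f"{prefix}{i + 1}_B{b}",
                        "patient_id": f"{prefix}{i + 1}",
                        "condition": "x",
                        "batch": b,
                        "file_path": "",
                    }
                )
        return SampleSheet(pd.DataFrame(rows))

    return _sheet
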