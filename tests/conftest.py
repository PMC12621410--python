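import numpy as np
import pandas as pd
import pytest

import ecostruct as es
from ecostruct.data_model import CellTable, MarkerPanel


@pytest.fixture(scope="session")
def tiny_panel() -> MarkerPanel:
    return MarkerPanel(
        pd.DataFrame(
            {
                "marker_name": ["m1", "m2", "m3"],
                "channel_tag": ["Nd142", "Nd143", "Nd144"],
                "class": ["lineage", "lineage", "functional"],
            }
        )
    )


def make_cells(df: pd.DataFrame, panel: MarkerPanel, **defaults) -> CellTable:
    """Fill in boilerplate columns so tests can specify only what matters."""
    df = df.copy()
    if "cell_id" not in df:
        df["cell_id"] = np.arange(1, len(df) + 1)
    if "roi_id" not in df:
        df["roi_id"] = defaults.get("roi_id", "R1")
    if "patient_id" not in df:
        df["patient_id"] = defaults.get("patient_id", "P1")
    for m in panel.markers:
        if m not in df:
            df[m] = 1.0
    return CellTable(df, panel, raw=defaults.get("raw", True))


@pytest.fixture(scope="session")
def small_cohort():
    """A scaled-down synthetic cohort shared by read-only tests."""
    cfg = es.small_config(seed=0, cells_per_roi=800.0, patients_per_subtype=2,
                          rois_per_patient=1)
    return es.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def annotated_cohort(small_cohort):
    """The same cohort with ground-truth phenotypes attached as labels."""
    cells, cohort, truth = small_cohort
    return cells.with_columns(phenotype=truth.cells["phenotype"].to_numpy()), cohort, truth
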