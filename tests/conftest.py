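import numpy as np
import pandas as pd
import pytest

from dynacyt import generate_panel, null_config, study_mimic_config
from dynacyt.panel import MediatorPanel


def make_panel(cells: dict, mediators: list[str]) -> MediatorPanel:
    """Build a panel from {(procedure, time): 2-D array (animals x mediators)}."""
    rows = []
    for (proc, t), arr in cells.items():
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        for i, row in enumerate(arr):
            sid = f"{proc}-{t}h-{i + 1:02d}"
            for m, v in zip(mediators, row):
                rows.append((sid, proc, t, m, float(v)))
    return MediatorPanel(
        pd.DataFrame(rows, columns=["subject_id", "procedure", "time_h", "mediator", "value"])
    )


@pytest.fixture(scope="session")
def study_panel_truth():
    """One study-mimic panel (54 animals, 21 mediators) with its ground truth."""
    return generate_panel(study_mimic_config(), seed=1)


@pytest.fixture(scope="session")
def study_panel(study_panel_truth):
    return study_panel_truth[0]


@pytest.fixture(scope="session")
def study_truth(study_panel_truth):
    return study_panel_truth[1]


@pytest.fixture(scope="session")
def null_panel():
    """Panel with no planted effects or correlation blocks."""
    panel, _ = generate_panel(null_config(), seed=5)
    return panel
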