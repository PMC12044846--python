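import numpy as np
import pandas as pd
import pytest

from evscore import GeneWeights, SimConfig
from evscore.scoring import COPY_TABLE_COLUMNS


def make_copy_table(rows):
    """rows: list of (sample_id, patient_id, timepoint, label, gene, copies)."""
    return pd.DataFrame(rows, columns=COPY_TABLE_COLUMNS)


@pytest.fixture
def unit_weights():
    genes = ["ALB", "APOH", "FGB", "FGG", "H2AX", "TF"]
    return GeneWeights(
        weights=pd.Series({g: 1.0 for g in genes}),
        reference_stats=pd.DataFrame(columns=["mean", "sd"]),
    )


@pytest.fixture
def small_config():
    return SimConfig(seed=0, n_datasets=2, n_genes=40, n_samples_per_group=10)


@pytest.fixture
def pilot_table():
    """Deterministic toy pilot cohort: 4 HCC vs 4 cirrhosis, 2 genes."""
    rng = np.random.default_rng(7)
    rows = []
    for i in range(4):
        rows.append((f"h{i}", f"h{i}", "single", "HCC", "ALB", 200 + 10 * i))
        rows.append((f"h{i}", f"h{i}", "single", "HCC", "TF", 150 + 5 * i))
    for i in range(4):
        rows.append((f"c{i}", f"c{i}", "single", "cirrhosis", "ALB", 20 + 2 * i))
        rows.append((f"c{i}", f"c{i}", "single", "cirrhosis", "TF", 30 + 3 * i))
    return make_copy_table(rows)
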