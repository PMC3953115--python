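import numpy as np
import pandas as pd
import pytest

from nsclcmir.cohort import CohortDesign, PlantedTruth, default_truth
from nsclcmir.io import ExpressionMatrix


@pytest.fixture
def small_design():
    return CohortDesign(n_scc=6, n_ad=5, n_genes=40, n_mirnas=12,
                        n_replicates=3, seed=7, cohort="training")


@pytest.fixture
def small_truth():
    return PlantedTruth(
        de_genes=(("G0001", "AD", 0.5), ("G0002", "SCC", 0.5)),
        de_mirnas=(("miR-sim-001", "SCC", 2.0), ("miR-sim-002", "AD", 2.0)),
        true_pairs=(("miR-sim-001", "G0001", 0.4),
                    ("miR-sim-002", "G0002", 0.4)),
        decoy_pairs=(("miR-sim-001", "G0010"),),
    )


@pytest.fixture
def training_truth():
    return default_truth(CohortDesign(seed=1))


def make_matrix(values, subtypes, genes=None):
    """Small ExpressionMatrix helper for unit tests."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    meta = pd.DataFrame(
        {"subtype": list(subtypes), "cohort": "test", "tissue": "tumor",
         "patient_id": samples},
        index=pd.Index(samples, name="sample_id"))
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                            columns=samples),
        metadata=meta)
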