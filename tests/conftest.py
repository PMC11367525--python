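import numpy as np
import pandas as pd
import pytest

from omiclag.data_model_io import ExpressionMatrix
from omiclag.synthetic_data import SimulationConfig, generate_paired_dataset


def make_sample_table(modality, timepoints, n_reps, plate=True, prefix=None):
    """Sample-table helper mirroring the generator's naming scheme."""
    prefix = prefix or ("rna" if modality == "transcript" else "prot")
    rows = []
    for t in timepoints:
        for r in range(1, n_reps + 1):
            rows.append(
                {
                    "sample_id": f"{prefix}_t{t:g}_r{r}",
                    "modality": modality,
                    "time_h": float(t),
                    "replicate": str(r),
                    "plate": f"plate_t{t:g}_r{r}" if plate else "",
                }
            )
    return pd.DataFrame(rows)


def make_matrix(values, samples, value_kind="log_intensity", genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples["sample_id"].tolist()), value_kind
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One mid-size paired dataset with the kinetic lag, shared by tests."""
    config = SimulationConfig(n_genes=400, seed=3, delta_range=(1 / 3, 1 / 3))
    return config, generate_paired_dataset(config)


@pytest.fixture(scope="session")
def protein_samples_5tp():
    return make_sample_table("protein", [0, 2, 4, 8, 10], 3)


@pytest.fixture(scope="session")
def rna_samples_6tp():
    return make_sample_table("transcript", [0, 2, 4, 6, 8, 10], 4)
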