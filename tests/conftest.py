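import numpy as np
import pandas as pd
import pytest

from kinostate.synthetic_data import SimConfig, make_ground_truth


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """A miniature study: fast, full pipeline coverage."""
    return SimConfig(
        n_kinases=30,
        n_genes=60,
        n_cell_lines=8,
        n_drugs_kinobead=8,
        n_drugs_kinomescan=8,
        n_shared_drugs=4,
        panel_overlap_fraction=0.5,
        missing_rate=0.1,
        sensitivity_coverage=1.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_ground_truth(tiny_config):
    return make_ground_truth(tiny_config, n_drivers=5)


def make_records(rows):
    """Profiling records from (drug, kinase, value, assay[, mutant]) tuples."""
    out = []
    for row in rows:
        drug, kinase, value, assay = row[:4]
        mutant = row[4] if len(row) > 4 else False
        out.append(
            {
                "drug_id": drug,
                "kinase_id": kinase,
                "value": value,
                "assay": assay,
                "mutant_flag": mutant,
            }
        )
    return pd.DataFrame(out)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
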