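import numpy as np
import pandas as pd
import pytest

from nestmicro.io import OtuTable
from nestmicro.simulate import FIXTURE_PARAMS, generate_dataset


@pytest.fixture(scope="session")
def fixture_dataset():
    """One small complete synthetic study (table, metadata, taxonomy, truth)."""
    return generate_dataset(FIXTURE_PARAMS)


@pytest.fixture()
def toy_table():
    """3 OTUs x 4 samples: two biological, one blank, one negative control."""
    counts = pd.DataFrame(
        {
            "S1": [50.0, 3.0, 0.0],
            "S2": [30.0, 10.0, 2.0],
            "BL1": [5.0, 0.0, 0.0],
            "NC1": [0.0, 0.0, 100.0],
        },
        index=["OTU_A", "OTU_B", "OTU_C"],
    )
    roles = pd.Series(
        {"S1": "biological", "S2": "biological", "BL1": "blank", "NC1": "negative_control"}
    )
    return OtuTable(counts, roles)


def make_metadata(n_nests=2, nestlings=3, treatment="control", replicates=2):
    """Metadata for a minimal fully-crossed control design."""
    rows = []
    for n in range(n_nests):
        nest = f"N{n + 1}"
        for k in range(nestlings):
            bird = f"B{nest}_{k + 1}"
            for age in ("D8", "D15"):
                for rep in range(1, replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{bird}_{age}_r{rep}",
                            "bird_id": bird,
                            "nest_of_origin": nest,
                            "nest_of_rearing": nest,
                            "age_class": age,
                            "nest_treatment": treatment,
                            "body_mass_g": 12.0 if age == "D8" else 18.0,
                            "tarsus_mm": np.nan if age == "D8" else 19.3,
                            "replicate_id": f"r{rep}",
                            "sample_role": "biological",
                        }
                    )
    return pd.DataFrame(rows)
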