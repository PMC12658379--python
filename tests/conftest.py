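import pandas as pd
import pytest
from hypothesis import settings

from engramkit import SpineGenConfig, gen_spine_table, refine_spines

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def refined_spines() -> pd.DataFrame:
    """A refined synthetic spine table shared by classification/clustering tests."""
    table = gen_spine_table(SpineGenConfig(n_spines=1500, neckless_fraction=0.1, seed=7))
    kept, _ = refine_spines(table)
    return kept


def make_counts(n_dapi, n_cfos, n_mcherry, n_overlap, animal="a0", area=1.0, region="LEC"):
    """One-row slice-count frame for arithmetic tests."""
    return pd.DataFrame(
        [{
            "animal_id": animal, "slice_id": f"{animal}_s0", "region": region,
            "area_mm2": area, "n_dapi": n_dapi, "n_cfos": n_cfos,
            "n_mcherry": n_mcherry, "n_overlap": n_overlap,
        }]
    )
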