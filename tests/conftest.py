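import numpy as np
import pandas as pd
import pytest

from twinct.ct_io import CtTable, TwinDesign
from twinct.synthetic_data import SimulationConfig, simulate_twin_ct


@pytest.fixture
def small_ct_table() -> CtTable:
    """Two controls + two targets over one twin pair (samples P1A, P1B)."""
    values = pd.DataFrame(
        {
            "P1A": [32.0, 32.0, 21.93, 27.0],
            "P1B": [31.0, 33.0, 25.0, np.nan],
        },
        index=["U6-2", "SNORD48", "miR-107", "miR-9"],
    )
    return CtTable(values)


@pytest.fixture
def one_pair_design() -> TwinDesign:
    return TwinDesign(
        pd.DataFrame(
            {
                "sample_id": ["P1A", "P1B"],
                "pair_id": ["P1", "P1"],
                "member": ["A", "B"],
                "zygosity": ["monozygotic", "monozygotic"],
            }
        )
    )


@pytest.fixture
def two_zygosity_design() -> TwinDesign:
    rows = []
    for pair, zyg in [("M1", "monozygotic"), ("D1", "dizygotic")]:
        for member in ("A", "B"):
            rows.append((f"{pair}{member}", pair, member, zyg))
    return TwinDesign(pd.DataFrame(rows, columns=["sample_id", "pair_id", "member", "zygosity"]))


@pytest.fixture
def simulated_study():
    """A mid-sized simulated twin study with one undetected assay."""
    return simulate_twin_ct(SimulationConfig(n_mirnas=200, seed=20240915))
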