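import numpy as np
import pandas as pd
import pytest

from amdgxe import SimulationConfig, simulate_eye_records
from amdgxe.io import MAJOR_VARIANTS


@pytest.fixture
def toy_weights() -> pd.DataFrame:
    """Seven variants: the five canonical majors plus two non-majors."""
    rows = [(v, "T", 0.5, True) for v in MAJOR_VARIANTS]
    rows += [("nm1", "A", 0.5, False), ("nm2", "G", -0.2, False)]
    return pd.DataFrame(rows, columns=["variant_id", "risk_allele", "beta", "is_major"])


@pytest.fixture
def group_intake_row():
    """Factory for a single subject's food-group intake row."""

    def make(subject_id="s1", sex="male", vegetables=0.0, legumes=0.0, fruits=0.0,
             cereals=0.0, fish=0.0, meat=0.0, dairy=0.0, alcohol=0.0,
             mufa_sfa_ratio=np.nan):
        return {
            "subject_id": subject_id, "sex": sex, "vegetables": vegetables,
            "legumes": legumes, "fruits": fruits, "cereals": cereals, "fish": fish,
            "meat": meat, "dairy": dairy, "alcohol": alcohol,
            "mufa_sfa_ratio": mufa_sfa_ratio,
        }

    return make


@pytest.fixture
def eye_records_small() -> pd.DataFrame:
    """A moderate simulated eye-record table for model-level tests."""
    return simulate_eye_records(SimulationConfig(n_subjects=600, seed=11))


def crude_2x2_records(a: int, b: int, c: int, d: int) -> pd.DataFrame:
    """Singleton-cluster records realising a 2x2 exposure/outcome table.

    a exposed cases, b exposed controls, c unexposed cases, d unexposed
    controls; exposure is carried on ``high_grs``.
    """
    rows = []
    for outcome, exposed, count in ((1, True, a), (0, True, b), (1, False, c), (0, False, d)):
        for _ in range(count):
            rows.append(
                {
                    "subject_id": f"s{len(rows)}",
                    "outcome": outcome,
                    "high_grs": exposed,
                    "high_mediscore": False,
                    "sex": "female",
                    "age_cat": "60-70",
                    "smoking": "non-smoker",
                    "exercise": False,
                }
            )
    return pd.DataFrame(rows)
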