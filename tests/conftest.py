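import numpy as np
import pandas as pd
import pytest

from methylmine.synthetic import SimulationConfig, simulate_cohort

#: the standard strong-separation study cohort: 4 cancers, 20 tumor + 10
#: normal each, 500 background probes, 10 planted probes per class
STANDARD_CONFIG = SimulationConfig(
    cancer_codes=("BRCA", "COAD", "LUSC", "PRAD"),
    n_tumor=20,
    n_normal=10,
    n_background_probes=500,
    planted=(
        ("cancer_hyper", "BRCA", 10),
        ("cancer_hypo", "COAD", 10),
        ("tissue_hyper", "LUSC", 10),
        ("tissue_hypo", "PRAD", 10),
    ),
    seed=20201030,
)


@pytest.fixture(scope="session")
def standard_cohort():
    return simulate_cohort(STANDARD_CONFIG)


@pytest.fixture()
def two_cancer_manifest():
    rows = []
    for code in ("AAA", "BBB"):
        for i in range(4):
            rows.append((f"{code}_T{i}", code, "primary_tumor"))
        for i in range(4):
            rows.append((f"{code}_N{i}", code, "normal_tissue"))
    return pd.DataFrame(rows, columns=["sample_id", "cancer_code", "tissue_type"]).set_index("sample_id")


def make_beta(values: dict[str, list[float]], samples: list[str]) -> pd.DataFrame:
    """Tiny beta matrix from probe -> row values."""
    return pd.DataFrame.from_dict(values, orient="index", columns=samples).rename_axis("probe_id")
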