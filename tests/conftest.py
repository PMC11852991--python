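import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from uropanel import BIOMARKERS, Cohort, CutoffTable, default_config, generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


#: Control-quartile cutoffs reported for the study cohort (pg/mL); the four
#: panel members without published quartiles are filled with the theoretical
#: quartiles of the generator's default calibration so every rule stays
#: evaluable.
REFERENCE_CUTOFFS = {
    "eotaxin": (1.60, 3.41, 6.59),
    "IL-6": (0.60, 0.84, 1.16),
    "IL-8": (1.31, 4.42, 12.63),
    "IP-10": (1.80, 3.74, 19.94),
    "MCP-1": (28.32, 106.16, 230.25),
    "RANTES": (1.97, 3.80, 8.04),
    "TNF-a": (0.62, 0.73, 0.95),
    "8-OHdG": (4.74, 13.90, 22.34),
    "8-isoprostane": (6.94, 13.35, 22.10),
}


@pytest.fixture(scope="session")
def reference_cutoffs() -> CutoffTable:
    return CutoffTable.from_dict(REFERENCE_CUTOFFS, source="FILE")


@pytest.fixture(scope="session")
def default_cfg():
    return default_config()


@pytest.fixture(scope="session")
def cohort(default_cfg) -> Cohort:
    """Default synthetic cohort (46 controls, 334 NHIC, 42 HIC)."""
    return generate_cohort(default_cfg, seed=1234)


def make_cohort(groups, fill: float = 1.0, **columns) -> Cohort:
    """Hand-built cohort: biomarkers default to ``fill``, overridable per column."""
    n = len(groups)
    df = pd.DataFrame({"subject_id": [f"P{i}" for i in range(n)], "group": list(groups)})
    for name in BIOMARKERS:
        df[name] = columns.get(name, np.full(n, fill, dtype=float))
    for name, values in columns.items():
        if name not in BIOMARKERS:
            df[name] = values
    return Cohort(df)


@pytest.fixture
def cohort_factory():
    return make_cohort
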