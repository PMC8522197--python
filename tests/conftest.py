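import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from lncpair import (
    ClinicalTable,
    ExpressionMatrix,
    SimulationConfig,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def cohort():
    """Default reduced-scale synthetic cohort with planted structure."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort whose planted pair effects are all zero (global survival null)."""
    cfg = SimulationConfig(planted_log_hazard_ratios=(0.0, 0.0, 0.0), seed=13)
    return simulate_cohort(cfg)


@pytest.fixture()
def small_expr():
    rng = np.random.default_rng(5)
    genes = [f"G{i}" for i in range(6)]
    samples = [f"S{i}" for i in range(20)]
    values = pd.DataFrame(rng.lognormal(2, 1, (6, 20)), index=genes, columns=samples)
    groups = pd.Series(["tumor"] * 12 + ["normal"] * 8, index=samples)
    return ExpressionMatrix(values, groups)


def random_survival(rng, n, censor_frac=0.3):
    """Tie-free random survival data for oracle comparisons."""
    time = rng.exponential(5.0, n)
    event = rng.random(n) > censor_frac
    return time, event.astype(int)


@pytest.fixture()
def toy_clinical():
    def _make(time, event, ids=None):
        ids = ids or [f"S{i}" for i in range(len(time))]
        return ClinicalTable(
            pd.DataFrame({"time": time, "event": event},
                         index=pd.Index(ids, name="sample_id"))
        )

    return _make
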