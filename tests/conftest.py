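import numpy as np
import pandas as pd
import pytest

from mvjoint.data_model import LongitudinalDataset, ModelSpec, SurvivalDataset


@pytest.fixture
def growth_spec():
    return ModelSpec()


@pytest.fixture
def toy_long():
    """Two subjects, two outcomes, two visits each."""
    rows = []
    for sid, gender in ((1, 0.0), (2, 1.0)):
        for outcome, base in (("height", 60.0), ("weight", 7.0)):
            for t in (0.25, 0.5):
                rows.append(
                    {
                        "subject_id": sid,
                        "time": t,
                        "outcome": outcome,
                        "value": base + 10 * t + sid,
                        "gender": gender,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def toy_surv():
    return pd.DataFrame(
        {
            "subject_id": [1, 2, 3],
            "time": [1.0, 2.5, 4.0],
            "event": [1, 0, 0],
            "finland": [0.0, 1.0, 0.0],
            "germany": [0.0, 0.0, 0.0],
            "sweden": [0.0, 0.0, 1.0],
            "gender": [0.0, 1.0, 1.0],
            "hla": [1.0, 0.0, 0.0],
            "fdr": [0.0, 0.0, 1.0],
        }
    )


@pytest.fixture
def toy_long_ds(toy_long, growth_spec):
    return LongitudinalDataset(toy_long, growth_spec.outcomes, growth_spec.covariate_columns)


@pytest.fixture
def toy_surv_ds(toy_surv, growth_spec):
    return SurvivalDataset(toy_surv, growth_spec.survival_covariates)


@pytest.fixture
def rng():
    return np.random.default_rng(20220427)
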