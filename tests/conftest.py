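import pandas as pd
import pytest
from hypothesis import settings

import firearmcost as fc

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset() -> fc.SyntheticDataset:
    """Small but fully structured synthetic dataset (6+5 states)."""
    cfg = fc.GeneratorConfig(
        seed=101,
        n_sample_states=6,
        n_nonsample_states=5,
        hospitals_per_state=3,
        visits_per_state_year=220.0,
    )
    return fc.generate_dataset(cfg)


@pytest.fixture(scope="session")
def analytic_sample(small_dataset) -> pd.DataFrame:
    """Costed, derived, hospital-joined sample-state visits."""
    costed, _ = fc.cost_pipeline(
        small_dataset.sample_visits(), small_dataset.ccr, small_dataset.cpi
    )
    derived = fc.derive_all(costed)
    return fc.attach_hospital_attributes(derived, small_dataset.hospitals)
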