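import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from twinmeth import MethylationMatrix, SimConfig
from twinmeth.simulate import AmpliconSimSpec, simulate_twin_cohort

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_matrix(values, sample_ids=None, unit_ids=None) -> MethylationMatrix:
    """Small literal matrix builder for hand-constructed fixtures."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    unit_ids = unit_ids or [f"A.u{j}" for j in range(k)]
    return MethylationMatrix(
        pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"),
                     columns=unit_ids)
    )


def flat_spec(name="A", n_units=8, drift_multiplier=1.0, **kw) -> AmpliconSimSpec:
    """A drift-free single amplicon with no per-unit mean profile: the
    cleanest conditions for checking the ACE variance arithmetic."""
    defaults = dict(mean_level=0.5, var_A=0.002, var_C=0.0015, var_E=0.002,
                    unit_noise_sd=0.01, unit_mean_spread=0.0)
    defaults.update(kw)
    return AmpliconSimSpec(name, n_units=n_units,
                           drift_multiplier=drift_multiplier, **defaults)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study design (31 MZ + 16 DZ pairs, four amplicons)."""
    return simulate_twin_cohort(SimConfig(seed=11))
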