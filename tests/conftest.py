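import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import alimix as am

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_frame():
    """Default-condition synthetic dataset, modest size."""
    frame, truth = am.generate(n_sites=6, n_per_site=20, seed=42)
    return frame, truth


@pytest.fixture(scope="session")
def fitted():
    """One reduced-scale fit shared across modules.

    10 sites x 40 observations with the default missingness and censoring,
    fit with 2 chains x 400 draws after 400 warmup sweeps.
    """
    frame, truth = am.generate(n_sites=10, n_per_site=40, seed=101)
    data, scaling = am.standardize(frame, am.PREDICTORS)
    model = am.build_model(data)
    with np.errstate(all="ignore"):
        result = am.fit(model, chains=2, draws_per_chain=400, warmup=400, seed=202)
    return {
        "frame": frame,
        "truth": truth,
        "data": data,
        "scaling": scaling,
        "model": model,
        "result": result,
    }
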