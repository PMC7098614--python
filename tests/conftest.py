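import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import trialpower as tp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params18() -> tp.PopulationParams:
    """Default 6-endpoint x 3-time study population."""
    return tp.default_population(seed=2026)


@pytest.fixture(scope="session")
def params4() -> tp.PopulationParams:
    """Small 2-endpoint x 2-time population for large-n moment checks."""
    corr = np.array(
        [
            [1.0, 0.5, 0.3, 0.2],
            [0.5, 1.0, 0.4, 0.3],
            [0.3, 0.4, 1.0, 0.5],
            [0.2, 0.3, 0.5, 1.0],
        ]
    )
    return tp.PopulationParams(
        mu=np.array([5.0, 8.0, 3.0, 12.0]),
        var=np.array([1.0, 4.0, 0.8, 9.0]),
        corr=corr,
        labels=tp.make_labels(("a", "b"), ("day1", "day7")),
    )
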