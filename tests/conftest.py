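import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from grace_melt import (
    MeltRun,
    SimSampleSpec,
    default_grid,
    default_panel,
    simulate_curve,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Every copy pair of the published genotype classes (dedup'd) plus (0,0).
ALL_COPY_PAIRS = [(2, 2), (2, 1), (2, 0), (1, 1), (1, 0), (2, 3)]


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def grid():
    return default_grid()


def make_run(panel, pairs, noise_sd=0.0, scales=None, seed=0, baseline_slope=-0.05):
    """Build a run with one WT control plus one sample per copy pair."""
    rng = np.random.default_rng(seed)
    curves = {
        "WT": simulate_curve(
            SimSampleSpec(
                "WT", {"HBA1": 2, "HBA2": 2},
                noise_sd=noise_sd, baseline_slope=baseline_slope,
            ),
            panel, rng=rng,
        )
    }
    ids = []
    for i, (c1, c2) in enumerate(pairs):
        sid = f"S{i}"
        ids.append(sid)
        curves[sid] = simulate_curve(
            SimSampleSpec(
                sid, {"HBA1": c1, "HBA2": c2},
                scale=(scales[i] if scales else 1.0),
                noise_sd=noise_sd, baseline_slope=baseline_slope,
            ),
            panel, rng=rng,
        )
    return MeltRun("fixture", curves, "WT"), dict(zip(ids, pairs))


@pytest.fixture(scope="session")
def noiseless_run(panel):
    """Noiseless run covering every distinct copy pair, unit scale."""
    return make_run(panel, ALL_COPY_PAIRS)
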