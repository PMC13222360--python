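import numpy as np
import pandas as pd
import pytest

from flyway.config import PipelineConfig
from flyway.simulate import SimConfig, simulate_population


@pytest.fixture(scope="session")
def small_population():
    """Six birds, two annual cycles, gap-free, 30-min fixes."""
    cfg = SimConfig(n_individuals=6, n_years=2, seed=42)
    trajectories, truth = simulate_population(cfg)
    return cfg, trajectories, truth


@pytest.fixture(scope="session")
def segmented(small_population):
    """Segmentation of the small population (shared across tests)."""
    from flyway.segmentation import segment_annual_cycle

    cfg, trajectories, truth = small_population
    pc = PipelineConfig()
    out = {}
    for tr in trajectories:
        out[tr.bird_id] = segment_annual_cycle(tr, pc)
    return pc, out, truth


@pytest.fixture
def pipeline_config():
    return PipelineConfig()


def make_fixes(times_h, lats, lons, start="2020-01-01"):
    """Fix table from hours-since-start plus coordinate lists."""
    base = pd.Timestamp(start, tz="UTC")
    return pd.DataFrame(
        {
            "timestamp": [base + pd.Timedelta(hours=float(h)) for h in times_h],
            "lat": np.asarray(lats, dtype=float),
            "lon": np.asarray(lons, dtype=float),
        }
    )
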