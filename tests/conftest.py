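import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import cinscore as cs

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_segments(rows) -> cs.SegmentTable:
    """Build a SegmentTable from (sample, chrom, start, end, mean) tuples."""
    df = pd.DataFrame(rows, columns=["sample_id", "chromosome", "start_bp", "end_bp", "segment_mean"])
    df["num_probes"] = 10
    return cs.SegmentTable.from_frame(df)


@pytest.fixture
def toy_segments() -> cs.SegmentTable:
    """Two adjacent 100-bp chr1 segments with means +0.5 and -0.5."""
    return make_segments([("S1", "1", 1, 100, 0.5), ("S1", "1", 101, 200, -0.5)])


@pytest.fixture
def flat_segments() -> cs.SegmentTable:
    """An all-neutral multi-chromosome profile."""
    return make_segments(
        [("S1", "1", 1, 1000, 0.0), ("S1", "2", 1, 500, 0.0), ("S1", "X", 1, 800, 0.0)]
    )


@pytest.fixture
def toy_sim_config() -> cs.SimulationConfig:
    return cs.SimulationConfig(genome=cs.GenomeModel.toy(), n_per_group=10, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
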