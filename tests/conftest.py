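import logging

import numpy as np
import pandas as pd
import pytest

from wormbiome.core_io import AbundanceTable, SampleMetadata
from wormbiome.simulate import (
    SimulationConfig,
    sample_metacommunity,
    sample_reads,
    simulate_assembly,
)

# the neutral-fit / NST warnings are expected on small fixtures
logging.getLogger("wormbiome").setLevel(logging.ERROR)


@pytest.fixture
def small_table() -> AbundanceTable:
    counts = np.array(
        [
            [10, 5, 0, 1],
            [8, 0, 2, 2],
            [12, 3, 1, 0],
            [9, 4, 0, 3],
        ]
    )
    return AbundanceTable.from_arrays(
        counts, ["s1", "s2", "s3", "s4"], ["tA", "tB", "tC", "tD"]
    )


@pytest.fixture
def small_metadata() -> SampleMetadata:
    return SampleMetadata(
        pd.DataFrame(
            {
                "source": ["host", "host", "control", "control"],
                "time_h": [16.0, 42.0, 16.0, 42.0],
                "replicate": ["r1", "r2", "r1", "r2"],
                "plate": ["p1", "p2", "c1", "c2"],
            },
            index=["s1", "s2", "s3", "s4"],
        )
    )


def simulate_group_table(
    S: int,
    N: int,
    depth: int,
    n_rep: int,
    generations: float,
    m: float,
    fitness: np.ndarray,
    seed: int,
    sigma: float = 1.5,
) -> AbundanceTable:
    """One group of replicate communities sampled at a single time point."""
    meta = sample_metacommunity(S, sigma, seed)
    cfg = SimulationConfig(
        S=S,
        N=N,
        m=m,
        depth=depth,
        time_points_h=(float(generations),),
        replicates=n_rep,
        fitness={"control": fitness},
    )
    rows = [
        sample_reads(
            simulate_assembly(meta, cfg, "control", seed * 1000 + r)[-1],
            depth,
            seed * 2000 + r,
        )
        for r in range(n_rep)
    ]
    return AbundanceTable.from_arrays(
        np.vstack(rows),
        [f"s{r}" for r in range(n_rep)],
        [f"T{i:02d}" for i in range(S)],
    )
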