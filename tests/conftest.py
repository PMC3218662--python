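import numpy as np
import pandas as pd
import pytest

import countde as cd


@pytest.fixture
def worked_counts() -> pd.DataFrame:
    """3-gene x 2-sample table whose size factors are (1/sqrt2, sqrt2)."""
    return pd.DataFrame(
        [[1, 2], [4, 8], [9, 18]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
        dtype=np.int64,
    )


@pytest.fixture(scope="session")
def null_pipeline():
    """A moderate null simulation with the full pipeline fitted once.

    Shared across tests that only need *some* fitted objects; seeds and
    sizes are fixed so results are reproducible.
    """
    spec = cd.SimulationSpec(
        n_genes=4000, conditions={"A": 2, "B": 2},
        size_factors=(0.7, 1.1, 0.9, 1.3), scv=0.1, seed=11,
    )
    counts, design, truth = cd.simulate_counts(spec)
    sf = cd.estimate_size_factors(counts)
    vfs = cd.pooled_variance_function(counts, design, sf, mode="per-condition")
    return {"spec": spec, "counts": counts, "design": design,
            "truth": truth, "sf": sf, "vfs": vfs}
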