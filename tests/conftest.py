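import numpy as np
import pytest

import popsplit as ps


@pytest.fixture
def rng():
    return np.random.default_rng(20131030)


@pytest.fixture
def table2_values():
    """One simulated reference mixture: N=2000, 3% small subpopulation."""
    spec = ps.MixtureSpec(n_total=2000, small_pct_true=3.0, seed=42)
    values, _ = ps.simulate_mixture(spec)
    return values


@pytest.fixture
def multi_image_dataset():
    """Six-image dataset (~63 AGV) with one obviously dim image (~20 AGV)."""
    rng = np.random.default_rng(7)
    records = []
    for img in range(6):
        for cell, v in enumerate(rng.normal(63, 3.9, size=200)):
            records.append(ps.CellRecord(f"img{img + 1}", f"c{cell + 1}", float(v)))
    for cell, v in enumerate(rng.normal(20, 3.9, size=200)):
        records.append(ps.CellRecord("img7", f"c{cell + 1}", float(v)))
    return ps.FluorescenceDataset(records=records, condition_label="synthetic")
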