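import numpy as np
import pandas as pd
import pytest

from trawljsdm.data_model import CommunityTable


@pytest.fixture
def toy_hauls():
    def make(n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "haul_id": [f"h{i}" for i in range(n)],
                "lon": rng.uniform(13, 16, n),
                "lat": rng.uniform(42.5, 45, n),
                "year": 1996 + (np.arange(n) % 4),
                "depth": rng.uniform(15, 250, n),
                "bot_temp": rng.uniform(8, 26, n),
                "seabed": np.where(rng.uniform(size=n) < 0.5, "sand", "mud_to_muddy_sand"),
                "swept_area": rng.uniform(0.03, 0.06, n),
            }
        )

    return make


@pytest.fixture
def toy_table(toy_hauls):
    def make(counts: dict, seed=0):
        counts = pd.DataFrame(counts)
        return CommunityTable(toy_hauls(len(counts), seed), counts)

    return make
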