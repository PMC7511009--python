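import numpy as np
import pandas as pd
import pytest

from trophlink.baseline import BaselineObservation
from trophlink.diet import PreyItem, StomachRecord
from trophlink.synthetic import SyntheticConfig, simulate_study


@pytest.fixture(scope="session")
def study():
    """One default synthetic study (published survey structure), seed 42."""
    return simulate_study(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def small_config():
    """A lighter synthetic config for fast end-to-end runs."""
    return SyntheticConfig(seed=7, n_stations=40, n_baseline_obs=25)


@pytest.fixture
def mixed_stomachs():
    """10 non-empty stomachs: group A in 6, group B in 4, both in 2.

    Built so J_A = 6, J_B = 4 over P = 10 (stomachs 4 and 5 hold both; the
    last two stomachs are non-empty with an out-of-focus prey group).
    """
    def item(sid, group):
        return PreyItem(sid, f"{group}_taxon", group, "whole", 1)

    stomachs = []
    for k in range(10):
        sid = f"s{k}"
        items = []
        if k < 6:
            items.append(item(sid, "fish"))
        if 4 <= k < 8:
            items.append(item(sid, "mollusk"))
        if k >= 8:
            items.append(item(sid, "other"))
        stomachs.append(StomachRecord(sid, f"f{k}", "autumn", "20-25cm", items))
    return stomachs


@pytest.fixture
def five_obs():
    """Five baseline observations in a ~50 km neighbourhood."""
    rng = np.random.default_rng(0)
    return [
        BaselineObservation(f"o{k}", 50.0 + rng.uniform(-0.3, 0.3),
                            1.0 + rng.uniform(-0.4, 0.4), 7.0 + rng.normal(0, 0.5))
        for k in range(5)
    ]


@pytest.fixture
def cell_frame():
    """Factor skeleton matching the survey design (empty winter 10-15cm cell)."""
    from trophlink import reference as ref
    rows = []
    for (season, sc), n in ref.N_SCA.items():
        rows += [{"season": season, "size_class": sc}] * n
    return pd.DataFrame(rows)
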