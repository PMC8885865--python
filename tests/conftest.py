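import math

import numpy as np
import pandas as pd
import pytest

import dietshift as ds


@pytest.fixture
def noiseless_shock_params():
    """Quadratic shock with known coefficients and no noise."""
    return ds.SeasonalShockParams(
        noise_sigma=0.0,
        shock_log_effect=math.log(1.5),
        shock_decay=(-0.01, 0.0002),
    )


@pytest.fixture
def flat_series():
    """Identical 2019/2020 series with no shock, trend or noise."""
    params = ds.SeasonalShockParams(
        noise_sigma=0.0, shock_log_effect=0.0, shock_decay=(0.0, 0.0)
    )
    return ds.generate_interest_series(params)


@pytest.fixture
def default_spec():
    return ds.ModelSpec("quadratic", 10, 30, 12)


def make_series(volumes_2019, volumes_2020=None, country="XX", label="s", start_week=1):
    """Build a small InterestSeries from raw volume lists."""
    rows = []
    for w, v in enumerate(volumes_2019, start=start_week):
        rows.append({"year": 2019, "week": w, "volume": v})
    for w, v in enumerate(volumes_2020 if volumes_2020 is not None else [], start=start_week):
        rows.append({"year": 2020, "week": w, "volume": v})
    return ds.InterestSeries(country, label, pd.DataFrame(rows))


def make_mobility(values, start="2020-02-01", country="XX"):
    idx = pd.date_range(start, periods=len(values), freq="D")
    return ds.MobilitySeries(country, pd.Series(np.asarray(values, float), index=idx))


@pytest.fixture
def tiny_catalog(tmp_path):
    """Synthetic 8-entity catalog CSV: 4 foods in 2 categories + 4 access modes."""
    rows = [
        ("/m/f1", "bread", "food", "bakery", "", ""),
        ("/m/f2", "croissant", "food", "bakery", "", ""),
        ("/m/f3", "cake", "food", "desserts", "", ""),
        ("/m/f4", "ice cream", "food", "desserts", "", ""),
        ("/m/a1", "recipe", "access_mode", "", "home", "household"),
        ("/m/a2", "delivery", "access_mode", "", "home", "third_party"),
        ("/m/a3", "picnic", "access_mode", "", "outside", "household"),
        ("/m/a4", "restaurant", "access_mode", "", "outside", "third_party"),
    ]
    path = tmp_path / "catalog.csv"
    path.write_text(
        "entity_id,display_name,kind,category,access_home,access_preparer\n"
        + "\n".join(",".join(r) for r in rows)
        + "\n"
    )
    return path
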