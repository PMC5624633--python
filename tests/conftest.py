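import numpy as np
import pandas as pd
import pytest

import cpuerecon as cr


@pytest.fixture(scope="session")
def base_cfg():
    return cr.SimConfig(seed=11, n_landings=800, n_vessels=4, n_days=15, n_trips=1200)


@pytest.fixture(scope="session")
def landings(base_cfg):
    return cr.gen_landings(base_cfg)


@pytest.fixture(scope="session")
def track_data():
    """500 labelled vessel-days at the generator's defaults."""
    cfg = cr.SimConfig(seed=21, n_vessels=10, n_days=50)
    points, labels = cr.gen_tracks(cfg)
    return cfg, points, labels


@pytest.fixture(scope="session")
def day_tracks(track_data):
    _, points, _ = track_data
    return cr.split_days(points)


@pytest.fixture(scope="session")
def trips_data():
    cfg = cr.SimConfig(seed=31, n_trips=5000)
    trips, truth = cr.gen_trips(cfg)
    return cfg, trips, truth


@pytest.fixture(scope="session")
def cpue_data():
    cfg = cr.SimConfig(seed=41, n_trips=10_000)
    records, truth = cr.gen_cpue(cfg)
    return cfg, records, truth


def make_divergent_records(seed, n=3000):
    """Two grounds with opposite abundance trends and unequal noise."""
    years = range(2001, 2011)
    rising = {y: float(np.exp(-1.0 + 0.22 * i)) for i, y in enumerate(years)}
    falling = {y: float(np.exp(1.0 - 0.22 * i)) for i, y in enumerate(years)}
    cfg_s = cr.SimConfig(seed=seed, n_trips=n // 2, year_effects=falling,
                         pcm_logsd=0.4, south_frac=1.0)
    cfg_n = cr.SimConfig(seed=seed + 50_000, n_trips=n // 2, year_effects=rising,
                         pcm_logsd=0.8, south_frac=0.0)
    rs, _ = cr.gen_cpue(cfg_s)
    rn, _ = cr.gen_cpue(cfg_n)
    rn["trip_id"] = "N" + rn["trip_id"]
    return pd.concat([rs, rn], ignore_index=True)


def cv_specs():
    """Final model formulations used in the split-sample comparisons."""
    specs = {
        k: (cr.ModelSpec("ZPM", ("year", "month")), cr.ModelSpec("PCM", ("year", "month")))
        for k in ("south", "north")
    }
    specs["combined"] = (
        cr.ModelSpec("ZPM", ("year", "month", "area")),
        cr.ModelSpec("PCM", ("year", "month", "area")),
    )
    return specs
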