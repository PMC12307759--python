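import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from foodloss import simulate

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_panel():
    """Default-condition indicator panel (13 + 92 countries) with truth."""
    panel, labels = simulate.generate_indicator_panel(
        simulate.IndicatorSimConfig(seed=11)
    )
    return panel, labels


@pytest.fixture(scope="session")
def grains_records():
    """Complete (no-missingness) single-stratum FLP panel with truth."""
    _, labels = simulate.generate_indicator_panel(simulate.IndicatorSimConfig(seed=11))
    cfg = simulate.FLPSimConfig(
        effects={"grains": (14.117, -8.023, 0.005)},
        missing_commodity=0.0,
        missing_activity=0.0,
        missing_flp=0.0,
        obs_per_cell=4,
        seed=21,
    )
    records, truth = simulate.generate_flp_panel(cfg, labels)
    return records, labels, truth


@pytest.fixture()
def toy_lmm_data():
    """Small balanced two-group dataset for exact-oracle comparisons."""

    def make(n_countries=4, n_obs=3, sigma_u=2.0, sigma_e=1.5, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_countries):
            country = f"C{i}"
            dev = "developed" if i < n_countries // 2 else "developing"
            u = rng.normal(0, sigma_u)
            for _ in range(n_obs):
                year = int(rng.integers(2000, 2023))
                e = rng.normal(0, sigma_e)
                flp = 12.0 - 6.0 * (dev == "developing") + 0.1 * (year - 2000) + u + e
                rows.append((country, year, dev, flp))
        return pd.DataFrame(rows, columns=["country", "year", "development", "flp"])

    return make


def noiseless_flp_config(**overrides):
    base = dict(
        effects={"grains": (14.0, -8.0, 0.2)},
        sigma_u=0.0,
        sigma_e=0.0,
        missing_commodity=0.0,
        missing_activity=0.0,
        missing_flp=0.0,
        seed=5,
    )
    base.update(overrides)
    return simulate.FLPSimConfig(**base)


@pytest.fixture()
def small_labels():
    names = [f"A{i}" for i in range(6)] + [f"B{i}" for i in range(6)]
    return pd.Series(
        ["developed"] * 6 + ["developing"] * 6, index=names, name="development"
    )


def replace_cfg(cfg, **kw):
    return dataclasses.replace(cfg, **kw)
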