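import logging

import pandas as pd
import pytest

from pollencast.io_ingest import extract_seasons
from pollencast.metrics import scheme_for
from pollencast.synthetic import default_model, simulate_dataset

logging.getLogger("pollencast").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def betula_ds():
    """Six calibrated synthetic birch years (shared, read-only)."""
    return simulate_dataset(default_model("Betula"), years=6, seed=3)


@pytest.fixture(scope="session")
def betula_seasons(betula_ds):
    return extract_seasons(betula_ds.pollen)


@pytest.fixture(scope="session")
def betula_scheme():
    return scheme_for("Betula")


def make_linear_fixture(n_years: int = 3, season_days: int = 70):
    """Daily series where pollen is an exact linear function of the stored
    mean temperature — a closed-form check for the regression path."""
    import numpy as np

    pollen_rows, meteo_rows = [], []
    for year in range(2000, 2000 + n_years):
        dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        doy = dates.dayofyear.to_numpy(dtype=float)
        tg_si = 10.0 + 8.0 * np.cos(2 * np.pi * (doy - 200) / len(dates)) + 0.01 * (year - 2000)
        met = pd.DataFrame({"date": dates})
        met["tg"] = pd.array(np.round(tg_si * 10).astype(int), dtype="Int64")
        for v, base in (("tn", 50), ("tx", 150), ("hu", 60), ("cc", 4), ("ss", 50),
                        ("fg", 30), ("pp", 10130), ("qq", 150), ("sd", 0)):
            met[v] = pd.array([base] * len(dates), dtype="Int64")
        meteo_rows.append(met)
        conc = np.zeros(len(dates))
        start = 100
        sl = slice(start, start + season_days)
        conc[sl] = 2.0 * (met["tg"].to_numpy(dtype=float)[sl] / 10.0) + 50.0
        pollen_rows.append(
            pd.DataFrame({"date": dates, "taxon": "Betula", "concentration": conc})
        )
    return (
        pd.concat(pollen_rows, ignore_index=True),
        pd.concat(meteo_rows, ignore_index=True),
    )


@pytest.fixture(scope="session")
def linear_fixture():
    return make_linear_fixture()
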