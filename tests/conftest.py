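import datetime as dt

import numpy as np
import pytest

from fruitgauge import SimConfig, simulate_cohort
from fruitgauge.pipeline import cohort_config, modelling_frame
from fruitgauge.size_models import fit_ratio_curve, fit_regressor


@pytest.fixture
def config():
    return SimConfig(seed=11)


@pytest.fixture
def small_config():
    return SimConfig(seed=123, n_trees=4, fruits_per_tree=2, images_per_date=2,
                     families=("linear", "gbdt"))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def benchmark():
    """Default two-cohort benchmark with fitted models, shared across tests.

    Simulates the training season and the held-out season at the default
    desk scale (24 trees x 5 fruits x ~13 dates x 5 poses x 2 tiers) and
    fits, per tier, the ratio curve and the gradient-boosted model on the
    fruit-area + ratio feature subset.
    """
    cfg = SimConfig(seed=11)
    year1 = simulate_cohort(cohort_config(cfg, "year1"))
    year2 = simulate_cohort(cfg)
    out = {"config": cfg, "year1": year1, "year2": year2}
    for tier in ("high", "low"):
        train = modelling_frame(year1["observations"], year1["caliper"], tier)
        test = modelling_frame(year2["observations"], year2["caliper"], tier)
        out[tier] = {
            "train": train,
            "test": test,
            "gbdt": fit_regressor("gbdt", "fruit_ratio", train, seed=cfg.seed),
            "ratio_curve": fit_ratio_curve(train),
        }
    return out


@pytest.fixture
def noiseless_stress_cohort():
    """Noise-free cohort for the exact growth/stress algebraic identity."""
    cfg = SimConfig(seed=3, n_trees=6, fruits_per_tree=2, psi_noise_sd=0.0,
                    caliper_noise_sd_mm=0.0, rain_events=())
    cohort = simulate_cohort(cfg)
    return cfg, cohort


def make_psi_frame(tree_id, start, psi_values, gap_days):
    """Psi measurement frame at explicit integer-day gaps (test helper)."""
    import pandas as pd

    dates = [start]
    for g in gap_days:
        dates.append(dates[-1] + dt.timedelta(days=int(g)))
    return pd.DataFrame({"tree_id": tree_id, "date": dates, "psi_MPa": psi_values})
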