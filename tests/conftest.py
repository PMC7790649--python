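import pandas as pd
import pytest

import dendropatterns as dp


@pytest.fixture(scope="session")
def low_noise_dataset():
    """One low-noise simulated study (8 plots) shared across tests."""
    cfg = dp.SimulationConfig(noise_sigma=0.05)
    plots, series, truth = dp.simulate_dataset(cfg, seed=1234)
    return plots, series, truth


@pytest.fixture(scope="session")
def low_noise_matrix(low_noise_dataset):
    _, series, _ = low_noise_dataset
    profiles = [dp.segment_series(s) for s in series]
    return profiles, dp.standardize_segment_matrix(profiles)


def make_inventory(
    heights,
    dbhs=None,
    plot_id="P1",
    area=400.0,
    species=None,
    vitality=None,
    sapling_count=0,
    sapling_area=0.0,
):
    """Small hand-built plot inventory."""
    n = len(heights)
    trees = pd.DataFrame(
        {
            "tree_id": [f"T{i + 1}" for i in range(n)],
            "species": species or ["PIMA"] * n,
            "dbh_cm": dbhs if dbhs is not None else [20.0] * n,
            "height_m": heights,
            "vitality": vitality or ["alive"] * n,
            "crown_status": ["intact"] * n,
        }
    )
    return dp.PlotInventory(
        plot_id=plot_id,
        plot_area_m2=area,
        trees=trees,
        sapling_count=sapling_count,
        sapling_area_m2=sapling_area,
    )
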