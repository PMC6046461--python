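import warnings

import numpy as np
import pandas as pd
import pytest

import gscontrast as gc


@pytest.fixture
def toy_counts() -> gc.CountMatrix:
    """4 genes x 2 samples; sample s1 has the worked-example counts."""
    return gc.CountMatrix(
        ["gA", "gB", "gC", "gD"],
        ["s1", "s2"],
        np.array([[5, 50], [1, 10], [10, 100], [3, 30]]),
    )


@pytest.fixture(scope="session")
def sim_dataset():
    """Default-scale simulated study with planted DE genes and sets."""
    cfg = gc.SimulationConfig(seed=7)
    universe = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    collection = gc.simulate_random_collection(100, (10, 50), universe, seed=1)
    counts, sheet, truth = gc.simulate_counts(cfg, collection)
    return {
        "config": cfg,
        "collection": collection,
        "counts": counts,
        "sheet": sheet,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def sim_contrasts(sim_dataset):
    """Filtered matrix plus both within-stratum DE contrasts."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filtered = gc.filter_low_counts(sim_dataset["counts"])
        young = gc.nb_exact_contrast(
            filtered, sim_dataset["sheet"], "young-sham", "young-DOCA"
        )
        aging = gc.nb_exact_contrast(
            filtered, sim_dataset["sheet"], "aging-sham", "aging-DOCA"
        )
    return {"filtered": filtered, "young": young, "aging": aging}


@pytest.fixture
def ivsd_table() -> gc.SummaryStatsTable:
    """Printed septal-thickness summary row (mean, SEM, n per cell)."""
    return gc.SummaryStatsTable(
        {
            "IVSd": {
                "young-sham": (0.69, 0.03, 6),
                "young-DOCA": (1.02, 0.05, 6),
                "aging-sham": (0.67, 0.03, 6),
                "aging-DOCA": (1.01, 0.03, 8),
            }
        }
    )
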