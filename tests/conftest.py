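import numpy as np
import pandas as pd
import pytest

import nirleaf as nl
from nirleaf.pipeline import preprocess


@pytest.fixture(scope="session")
def fert_data():
    """Default fertilization experiment, preprocessed, shared across tests."""
    cfg = nl.SimConfig()
    fresh, dried, ref = nl.generate_fertilization_experiment(cfg, seed=11)
    return preprocess(fresh), preprocess(dried), ref


@pytest.fixture(scope="session")
def reference_model(fert_data):
    """Dried-leaf N calibration used as the reference model downstream."""
    _, dried, ref = fert_data
    return nl.optimize_calibration(
        dried, ref, "leaf_N", "dried", transform="natural_log",
        n_iterations=60, seed=1,
    )


@pytest.fixture()
def small_grid():
    return nl.SpectralGrid(start_nm=350.0, end_nm=550.0, step_nm=1.0,
                           splice_points_nm=(450.0,))


@pytest.fixture()
def small_spectra(small_grid):
    """24 leaves x 2 replicates with a single y-driven band at 450 nm."""
    rng = np.random.default_rng(7)
    n = 24
    wl = small_grid.wavelengths()
    y = rng.uniform(1.0, 4.0, size=n)
    band = np.exp(-0.5 * ((wl - 450.0) / 15.0) ** 2)
    base = 0.4 + 0.05 * (wl - 350.0) / 200.0
    rows, meta = [], []
    for i in range(n):
        for rep in (1, 2):
            a = base + 0.02 * y[i] * band
            r = 10.0 ** (-a) + rng.normal(0, 5e-4, size=wl.size)
            rows.append(np.clip(r, 1e-6, 1.0))
            meta.append({"sample_id": f"S{i:02d}", "replicate": rep,
                         "state": "dried", "group": None})
    s = nl.SpectraSet(small_grid, pd.DataFrame(meta), np.vstack(rows))
    ref = nl.ReferenceTable(pd.DataFrame({
        "sample_id": [f"S{i:02d}" for i in range(n)],
        "species": "Plantago lanceolata",
        "leaf_N": y,
        "leaf_P": rng.uniform(1.0, 3.0, size=n),
        "fert_N_level": np.nan,
        "fert_P_level": np.nan,
    }))
    return s, ref, y
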