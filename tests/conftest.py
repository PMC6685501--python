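import logging

import numpy as np
import pandas as pd
import pytest

import spermdfi as s

logging.getLogger("spermdfi").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def quiet_cohort():
    """Small noiseless cohort shared by closed-loop tests."""
    cfg = s.SyntheticConfig(n_cells=60, seed=3, noise_sd=0.0, donor_shift_sd=0.0)
    table, truth = s.generate_feature_table(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def rendered_cohort(quiet_cohort):
    cfg, table, truth = quiet_cohort
    images = list(s.generate_image_cohort(table, truth, cfg))
    return cfg, table, truth, images


@pytest.fixture()
def default_cell(quiet_cohort):
    """One rendered default-geometry cell with its table row and truth."""
    cfg, table, truth = quiet_cohort
    row = table.iloc[0]
    truth_row = {"acrosome_fraction": truth.acrosome_fraction[0]}
    images = s.generate_cell_images(row, truth_row, cfg,
                                    rng=np.random.default_rng(0))
    return row, truth_row, images


def make_table(features: dict, dfi=None) -> pd.DataFrame:
    """Build a minimal feature table from column arrays."""
    n = len(next(iter(features.values())))
    base = {
        "donor": np.zeros(n, dtype=int),
        "cell_id": [f"c{i:05d}" for i in range(n)],
    }
    for f in s.FEATURES:
        base[f] = np.asarray(features.get(f, np.full(n, 1.0)), dtype=float)
    base["DFI"] = np.full(n, 0.1) if dfi is None else np.asarray(dfi, float)
    return pd.DataFrame(base)
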