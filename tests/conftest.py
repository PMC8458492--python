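"""Shared fixtures: small hand-built tables and seeded synthetic studies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gcexpose import FeatureTable, NoiseModel, make_universe, simulate_study


@pytest.fixture
def make_table():
    """Factory building a FeatureTable from literal rows.

    features: list of (feature_id, mz, rt, {sample_id: intensity-or-None})
    manifest: list of (sample_id, role, batch_id)
    """

    def _make(features, manifest):
        man = pd.DataFrame(manifest, columns=["sample_id", "role", "batch_id"])
        man["injection_replicates"] = 1
        man = man.set_index("sample_id")
        meta_rows, int_rows = [], []
        for fid, mz, rt, cells in features:
            meta_rows.append((fid, mz, rt))
            int_rows.append({s: (np.nan if v is None else v) for s, v in cells.items()})
        meta = pd.DataFrame(meta_rows, columns=["feature_id", "mz", "rt"]).set_index(
            "feature_id"
        )
        intensities = pd.DataFrame(int_rows, index=meta.index).reindex(
            columns=list(man.index)
        )
        return FeatureTable(meta=meta, intensities=intensities, manifest=man)

    return _make


@pytest.fixture(scope="session")
def noiseless_universe():
    noise = NoiseModel.noiseless(seed=11)
    return make_universe(17, (4, 6), noise=noise), noise


@pytest.fixture(scope="session")
def noiseless_study(noiseless_universe):
    (chems, library, refs), noise = noiseless_universe
    table, truth = simulate_study(chems, 20, noise=noise)
    return chems, library, refs, table, truth


@pytest.fixture(scope="session")
def noisy_study():
    noise = NoiseModel(seed=23)
    chems, library, refs = make_universe(25, (4, 6), noise=noise)
    table, truth = simulate_study(chems, 20, noise=noise)
    return chems, library, refs, table, truth
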