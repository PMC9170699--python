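import numpy as np
import pytest
from hypothesis import settings

from radnano import mc

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def vesicle_geom_166():
    """The reference vesicle: 166 x 50 nm spheres (32.4 vol%) in 400 nm."""
    return mc.build_vesicle_geometry(166, seed=1)


@pytest.fixture(scope="session")
def au_vesicle_score(vesicle_geom_166):
    """Shared Au vesicle simulation (csda electrons, triplicate seeds)."""
    return mc.simulate_vesicle(
        vesicle_geom_166, "Au", "kv150", n_histories=20_000, seed=11,
        electron_mode="csda", n_replicates=3,
    )


@pytest.fixture(scope="session")
def cell_scores_kv():
    """Cytoplasm/nucleus DEFs for the four headline materials, shared seeds."""
    out = {}
    geom = mc.build_cell_geometry(5)
    for mat in ("Au", "HfO2", "WO3", "TiO2"):
        out[mat] = mc.simulate_cell(
            geom, mat, "kv150", n_histories=20_000, seed=11, n_replicates=2
        )
    return out


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(1234))
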