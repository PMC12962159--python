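import numpy as np
import pytest

from ecocouple import plspm, synthetic as syn
from ecocouple.raster import RasterGrid


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_grid():
    vals = np.arange(20, dtype=float).reshape(4, 5)
    return RasterGrid(vals, epoch=2000)


@pytest.fixture
def two_latent_spec():
    """Minimal 2-latent path model A -> B with two indicators each."""
    return plspm.PathModelSpec(
        ["A", "B"], {"A": ["a1", "a2"], "B": ["b1", "b2"]}, [("A", "B")])


def two_latent_table(path: float, n: int = 1000, seed: int = 0, loading: float = 0.9):
    ms = syn.LatentModelSpec.standardized(
        ["A", "B"], {("A", "B"): path},
        {"A": ["a1", "a2"], "B": ["b1", "b2"]},
        {"a1": loading, "a2": loading, "b1": loading, "b2": loading},
        n=n, seed=seed)
    return syn.generate_sem_table(ms)


def fake_fit(latent_names, edges, coeffs, blocks=None):
    """PLSFit carrying a given structural matrix (for effect-decomposition tests)."""
    import pandas as pd

    blocks = blocks or {n: [f"{n}_x"] for n in latent_names}
    spec = plspm.PathModelSpec(latent_names, blocks, edges)
    idx = {n: i for i, n in enumerate(latent_names)}
    B = np.zeros((len(latent_names), len(latent_names)))
    for (src, dst), val in coeffs.items():
        B[idx[dst], idx[src]] = val
    frame = pd.DataFrame(B, index=latent_names, columns=latent_names)
    return plspm.PLSFit(spec=spec, outer_weights={}, loadings={},
                        scores=pd.DataFrame(), path_coefficients=frame,
                        r2={}, communality={}, block_communality={},
                        gof=0.0, gof_label="poor", n_iterations=0, converged=True)
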