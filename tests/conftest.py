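import numpy as np
import pandas as pd
import pytest

from concord.config import SimConfig


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_genes=100, seed=1)


@pytest.fixture(scope="session")
def small_sim(small_config):
    """One small simulated experiment shared across read-only tests."""
    from concord.synthetic import simulate_all

    return simulate_all(small_config)


def make_arrays(M, A=None, treatment="SKF", dye_swapped=None, noise=0.0,
                seed=0):
    """Build a spot-level array table from a genes x arrays matrix of log2
    ratios (each gene printed in duplicate)."""
    rng = np.random.default_rng(seed)
    M = np.asarray(M, dtype=float)
    n_genes, n_arrays = M.shape
    if A is None:
        A = np.tile(np.linspace(8, 12, n_genes)[:, None], (1, n_arrays))
    dye_swapped = dye_swapped or [False] * n_arrays
    frames = []
    for a in range(n_arrays):
        for dup in range(2):
            m = M[:, a] + rng.normal(0, noise, n_genes)
            t = 2.0 ** (A[:, a] + m / 2.0)
            r = 2.0 ** (A[:, a] - m / 2.0)
            if dye_swapped[a]:
                t, r = r, t
            frames.append(pd.DataFrame({
                "array_id": f"{treatment}_A{a + 1}",
                "treatment": treatment,
                "dye_swapped": dye_swapped[a],
                "spot_id": [f"S{i:05d}_{dup}" for i in range(n_genes)],
                "gene_id": [f"G{i:05d}" for i in range(n_genes)],
                "ch_treat": t, "ch_ref": r,
            }))
    return pd.concat(frames, ignore_index=True)
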