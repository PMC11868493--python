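"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's k-d-tree code paths: they
are plain O(n·m) numpy scans that define correctness for the spatial
statistics.
"""

import numpy as np
import pandas as pd
import pytest

from tmespatial import io, synthetic


def brute_force_nn(ref_xy: np.ndarray, nbr_xy: np.ndarray) -> np.ndarray:
    """Nearest-neighbor distances by full pairwise scan."""
    diff = ref_xy[:, None, :] - nbr_xy[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1)).min(axis=1)


def brute_force_interactions(xy: np.ndarray, labels: np.ndarray, cell_ids: np.ndarray,
                             phenotypes: list) -> np.ndarray:
    """Nearest-other-phenotype count matrix by per-cell exhaustive scan."""
    idx = {p: i for i, p in enumerate(phenotypes)}
    matrix = np.zeros((len(phenotypes), len(phenotypes)), dtype=int)
    for i in range(len(xy)):
        others = labels != labels[i]
        if not others.any():
            continue
        d = np.sqrt(((xy[others] - xy[i]) ** 2).sum(axis=1))
        dmin = d.min()
        tied = np.flatnonzero(np.isclose(d, dmin, rtol=0.0, atol=0.0))
        # tie rule: smallest cell_id
        winner = tied[np.argmin(cell_ids[others][tied])]
        matrix[idx[labels[i]], idx[labels[others][winner]]] += 1
    return matrix


def random_cell_table(rng: np.random.Generator, n: int, phenotypes,
                      width: float = 1000.0) -> pd.DataFrame:
    """Random labeled cell table for oracle comparisons."""
    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "sample_id": "R1",
            "x_um": rng.uniform(0, width, n),
            "y_um": rng.uniform(0, width, n),
            "phenotype": rng.choice(list(phenotypes), n),
        }
    )


@pytest.fixture(scope="session")
def small_tissue():
    """One modest synthetic tissue with phenotypes and regions assigned."""
    config = synthetic.TissueConfig(
        tumor_intensity_per_mm2=800.0,
        immune_counts={"CD8+Tim3-": 120, "CD8+Tim3+": 40, "CD4+": 80},
        seed=11,
    )
    cells, regions = synthetic.gen_tissue(config)
    cells = io.assign_phenotypes(cells)
    cells = io.assign_regions(cells, regions)
    return cells, regions, config
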