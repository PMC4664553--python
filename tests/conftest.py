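import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))


def ranked_pairs_from_matrix(S: np.ndarray, ids=None) -> pd.DataFrame:
    """All upper-triangle pairs of a symmetric similarity matrix, ranked
    by descending similarity with the lexicographic tie-break."""
    n = S.shape[0]
    if ids is None:
        ids = np.array([f"n{i:03d}" for i in range(n)], dtype=object)
    else:
        ids = np.asarray(ids, dtype=object)
    iu = np.triu_indices(n, 1)
    sim = S[iu]
    order = np.lexsort((ids[iu[1]], ids[iu[0]], -np.abs(sim)))
    return pd.DataFrame(
        {
            "node1": ids[iu[0]][order],
            "node2": ids[iu[1]][order],
            "similarity": sim[order],
            "p": 0.0,
            "fdr": 0.0,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_expression():
    """50 genes x 200 samples, two planted 18-gene modules + background."""
    from pfnet.synthetic import PlantedDesign, generate_expression

    design = PlantedDesign(
        n_genes=50, n_samples=200, module_sizes=(18, 18), loading=0.8, seed=11
    )
    return generate_expression(design)
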