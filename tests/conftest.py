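import numpy as np
import pandas as pd
import pytest

import irdm
from irdm.synthetic_data import CohortSpec, generate_cohort, make_centroids


@pytest.fixture(scope="session")
def panel():
    return irdm.default_panel()


@pytest.fixture(scope="session")
def model():
    return make_centroids(CohortSpec(seed=42))


@pytest.fixture(scope="session")
def cohort600():
    """Balanced 600-sample cohort at noise 0.3 — the standard recovery setup."""
    return generate_cohort(CohortSpec(n_samples=600, noise_sd=0.3, seed=42))


@pytest.fixture()
def tiny_matrix():
    """3 genes x 2 samples, hand-written values."""
    df = pd.DataFrame(
        {"s1": [2.0, 4.0, 0.0], "s2": [1.0, -1.0, 3.0]},
        index=["CCL5", "CXCL9", "AURKA"],
    )
    return irdm.ExpressionMatrix(df, state="cpm_log2")


def brute_spearman(x, y):
    """Independent oracle: average ranks by explicit sorting, then Pearson
    computed from raw sums."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def avg_ranks(v):
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    n = len(x)
    sx, sy = rx.sum(), ry.sum()
    sxx = (rx * rx).sum()
    syy = (ry * ry).sum()
    sxy = (rx * ry).sum()
    num = n * sxy - sx * sy
    den = np.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den
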