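import numpy as np
import pandas as pd
import pytest

from cernet.matrix import ExpressionMatrix


@pytest.fixture
def small_counts():
    """6-sample, 8-feature counts matrix with two clearly DE features."""
    rng = np.random.default_rng(42)
    base = rng.integers(50, 500, size=(8, 6)).astype(float)
    base[0, 3:] *= 8  # up in GF_T
    base[1, :3] *= 8  # down in GF_T
    cond = pd.Series(["GF_C"] * 3 + ["GF_T"] * 3, index=[f"GF_{i+1}" for i in range(6)])
    values = pd.DataFrame(base, index=[f"g{i}" for i in range(8)], columns=cond.index)
    return ExpressionMatrix("mRNA", values, cond)


def nb_matrix(rng, n_feat, reps, phi, mu_lo=4.0, mu_hi=10.0, layer="mRNA"):
    """Null NB count matrix: same mean in both conditions."""
    mu = 2.0 ** rng.uniform(mu_lo, mu_hi, n_feat)
    m = np.tile(mu[:, None], (1, 2 * reps))
    if phi == 0:
        y = rng.poisson(m)
    else:
        r = 1.0 / phi
        y = rng.negative_binomial(r, r / (r + m))
    cond = pd.Series(["GF_C"] * reps + ["GF_T"] * reps,
                     index=[f"GF_{i+1}" for i in range(2 * reps)])
    values = pd.DataFrame(y, index=[f"f{i}" for i in range(n_feat)], columns=cond.index)
    return ExpressionMatrix(layer, values, cond)
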