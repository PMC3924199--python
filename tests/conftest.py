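import numpy as np
import pandas as pd
import pytest

from nbpower.pilot_estimation import CountMatrix


def make_count_matrix(counts, n_control=None):
    """CountMatrix from a 2-D array, first half of columns = control."""
    counts = np.asarray(counts)
    m, ns = counts.shape
    if n_control is None:
        n_control = ns // 2
    cols = [f"s{j}" for j in range(ns)]
    groups = pd.Series(
        ["control"] * n_control + ["treatment"] * (ns - n_control), index=cols
    )
    frame = pd.DataFrame(counts, index=[f"g{i}" for i in range(m)], columns=cols)
    return CountMatrix(frame, groups)


@pytest.fixture
def tmm_fixture_counts():
    """Seeded NB matrix with unequal depths and a block of DE genes.

    The same recipe was run through edgeR's calcNormFactors(method="TMM")
    to produce the frozen oracle factors used in the TMM test.
    """
    rng = np.random.default_rng(20240901)
    m = 120
    base = rng.gamma(2.0, 50.0, size=m)
    lib = np.array([0.6, 1.0, 1.4, 0.8, 1.2, 1.0])
    mu = np.outer(base, lib)
    mu[:10, 3:] *= 4.0
    r = 1 / 0.2
    return rng.negative_binomial(r, r / (r + mu))
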