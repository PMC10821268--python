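import numpy as np
import pandas as pd
import pytest

from mitoflux.expression import ExpressionMatrix


@pytest.fixture
def tiny_expr():
    """4 genes x 6 samples, two groups, fixed values."""
    rng = np.random.default_rng(42)
    vals = pd.DataFrame(
        rng.uniform(1.0, 100.0, size=(4, 6)),
        index=["gA", "gB", "gC", "gD"],
        columns=[f"s{i}" for i in range(6)],
    )
    groups = pd.Series(
        ["Control"] * 3 + ["Treated"] * 3, index=vals.columns, name="group"
    )
    return ExpressionMatrix(vals, groups)


def correlated_expr(seed, genes, n, corr):
    """Gaussian-latent lognormal matrix where the listed gene tuples are
    equicorrelated blocks; single group."""
    rng = np.random.default_rng(seed)
    names = [g for block in genes for g in block]
    rows = []
    for block in genes:
        z = rng.standard_normal(n)
        for _ in block:
            x = np.sqrt(corr) * z + np.sqrt(1 - corr) * rng.standard_normal(n)
            rows.append(2.0 ** (5.0 + x))
    vals = pd.DataFrame(rows, index=names,
                        columns=[f"s{i}" for i in range(n)])
    groups = pd.Series(["Control"] * n, index=vals.columns, name="group")
    return ExpressionMatrix(vals, groups)
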