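import numpy as np
import pandas as pd
import pytest

from qtlcascade import linkage as lk
from qtlcascade import synthdata as sd


@pytest.fixture(scope="session")
def fig3():
    return sd.make_fig3_fixture(seed=7)


@pytest.fixture(scope="session")
def chr13_map():
    return sd.default_chr13_map()


@pytest.fixture(scope="session")
def small_map():
    """Six markers over 50 Mbp, 0.5 cM/Mbp."""
    bp = np.arange(0, 50_000_001, 10_000_000, dtype=np.int64)
    return lk.GeneticMap(
        chromosome="chr13",
        markers=tuple(f"m{i}" for i in range(len(bp))),
        position_bp=bp,
        position_cm=bp * 0.5e-6,
    )


@pytest.fixture(scope="session")
def small_cross(small_map):
    spec = sd.CrossSpec(n=200, qtl_bp=20_000_000, additive=1.0, sigma=1.0, seed=3)
    return sd.simulate_backcross(small_map, spec)


@pytest.fixture()
def tiny_expr():
    """4 genes x (3 + 3) samples with known group means on the log2(x+1) scale."""
    log2_levels = {
        "gA": ([5.0, 5.0, 5.0], [3.0, 3.0, 3.0]),   # LFC +2
        "gB": ([4.0, 4.0, 4.0], [4.0, 4.0, 4.0]),   # LFC 0
        "gC": ([2.0, 2.5, 3.0], [4.0, 4.5, 5.0]),   # LFC -2
        "gD": ([6.0, 6.0, 6.0], [5.0, 5.0, 5.0]),   # LFC +1 exactly
    }
    rows = {}
    for g, (a, b) in log2_levels.items():
        rows[g] = [2**v - 1 for v in a + b]
    samples = [f"s{i}" for i in range(6)]
    values = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    groups = pd.Series(["G1"] * 3 + ["G2"] * 3, index=samples)
    from qtlcascade.exprfilter import ExpressionMatrix

    return ExpressionMatrix(values, groups, contrast="tiny")
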