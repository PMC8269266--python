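import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

import ecoassembly as ea


@pytest.fixture
def small_counts() -> pd.DataFrame:
    """6 OTUs x 4 samples with unequal totals."""
    data = {
        "S1": [50, 30, 10, 5, 3, 2],
        "S2": [40, 40, 12, 4, 2, 2],
        "S3": [60, 20, 15, 3, 1, 1],
        "S4": [55, 25, 11, 6, 2, 1],
    }
    return pd.DataFrame(
        data, index=pd.Index([f"OTU_{i:04d}" for i in range(1, 7)], name="otu_id")
    )


@pytest.fixture
def five_tip_tree() -> TreeNode:
    """Hand-built tree with known patristic distances."""
    nwk = "((A:0.1,B:0.2):0.3,(C:0.4,(D:0.1,E:0.1):0.2):0.1);"
    return TreeNode.read(io.StringIO(nwk), format="newick", convert_underscores=False)


@pytest.fixture
def neutral_counts() -> pd.DataFrame:
    """Neutral Sloan draw from a 50-taxon lognormal pool."""
    pool = ea.simulate_metacommunity(50, "lognormal", seed=11)
    return ea.sloan_sample(pool, m=0.3, N=1000, n_samples=20, seed=12)


def brute_force_patristic(tree: TreeNode) -> pd.DataFrame:
    """Naive per-pair path enumeration through the root-ward LCA."""
    tips = list(tree.tips())
    names = [t.name for t in tips]

    def path_to_root(node):
        out = []
        while node.parent is not None:
            out.append(node)
            node = node.parent
        return out

    n = len(tips)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi = path_to_root(tips[i])
            pj = path_to_root(tips[j])
            si = {id(x) for x in pi}
            shared = [x for x in pj if id(x) in si]
            lca_path_j = []
            total = 0.0
            seen = {id(x) for x in shared}
            for x in pi:
                if id(x) in seen:
                    break
                total += x.length or 0.0
            for x in pj:
                if id(x) in seen:
                    break
                total += x.length or 0.0
            d[i, j] = d[j, i] = total
    return pd.DataFrame(d, index=names, columns=names)


def brute_force_bmntd(f_k, f_l, dist) -> float:
    """O(n^2) double loop straight from the definition."""
    total = 0.0
    pk = [i for i in range(len(f_k)) if f_k[i] > 0]
    pl = [j for j in range(len(f_l)) if f_l[j] > 0]
    for i in pk:
        total += f_k[i] * min(dist[i][j] for j in pl)
    for j in pl:
        total += f_l[j] * min(dist[i][j] for i in pk)
    return 0.5 * total


def brute_force_bray(x, y) -> float:
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den
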