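import numpy as np
import pandas as pd
import pytest

import phyloallom as pa


@pytest.fixture(scope="session")
def study():
    return pa.make_study_fixture()


@pytest.fixture(scope="session")
def standin_tree():
    return pa.load_synthetic_consensus_tree()


@pytest.fixture(scope="session")
def log_traits(study):
    return study.log_traits()


@pytest.fixture()
def cherry():
    return pa.parse_newick("(A:1.0,B:1.0);")


@pytest.fixture()
def three_tip():
    return pa.parse_newick("((A:1,B:1):2,C:3);")


def brute_force_vcv(newick: str, order):
    """Independent path-sum oracle: C[i,j] = summed branch lengths shared by
    the root-to-tip paths of i and j."""
    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    paths = {}
    for leaf in t.leaf_node_iter():
        edges = []
        nd = leaf
        while nd.parent_node is not None:
            edges.append(nd)
            nd = nd.parent_node
        paths[leaf.taxon.label] = edges
    n = len(order)
    C = np.zeros((n, n))
    for i, a in enumerate(order):
        for j, b in enumerate(order):
            shared = set(id(e) for e in paths[a]) & set(id(e) for e in paths[b])
            C[i, j] = sum(e.edge.length for e in paths[a] if id(e) in shared)
    return C


@pytest.fixture(scope="session")
def vcv_oracle():
    return brute_force_vcv
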