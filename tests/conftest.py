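import numpy as np
import pytest

import omiat
from omiat import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_otu():
    counts = np.array([[6.0, 2.0, 0.0],
                       [5.0, 5.0, 0.0],
                       [1.0, 3.0, 4.0],
                       [2.0, 2.0, 6.0]])
    return omiat.OtuTable(counts, ["S1", "S2", "S3", "S4"], ["A", "B", "C"])


@pytest.fixture
def small_tree():
    return _tree("((A:1.0,B:2.0):0.5,C:3.0);")


def _tree(newick):
    from skbio import TreeNode

    from omiat.io import validate_tree

    return validate_tree(TreeNode.read([newick]))


@pytest.fixture
def tree_factory():
    return _tree


def planted_dataset(seed=1, n=100, p=71, c=2.0, trait="continuous",
                    cluster="largest"):
    """Synthetic community with one associated PAM cluster = one phylum.

    Returns (AlignedDataset, planted cluster id, associated index set).
    """
    rng = np.random.default_rng(seed)
    tree = sim.synth_tree(p, seed=seed)
    clusters = sim.pam_clusters(tree, k=5)
    params = sim.default_dm_params(p)
    totals = sim.sample_library_sizes(n, seed=rng)
    otu = sim.sample_dm(params, totals, seed=rng)
    labels = np.array([clusters[o] for o in otu.otu_ids])
    sizes = np.bincount(labels)
    planted = int(np.argmax(sizes)) if cluster == "largest" else int(cluster)
    lam = np.flatnonzero(labels == planted)
    beta = np.random.default_rng(seed + 1).uniform(0, c, lam.size)
    design = sim.simulate_outcome(otu, lam, beta, trait, "independent", seed=rng)
    tax = sim.synth_taxonomy(otu.otu_ids, clusters)
    ds = omiat.harmonize(otu, tree, tax, design)
    return ds, planted, lam


@pytest.fixture(scope="session")
def planted():
    return planted_dataset()
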