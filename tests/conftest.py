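import numpy as np
import pytest

from taxoplace.nodelabels import propagate, specificity_mode
from taxoplace.refprep import RegionSlice, build_region_tree
from taxoplace.simulate import FixtureSpec, simulate_fixture
from taxoplace.taxonomy import Lineage, TaxonomyTable
from taxoplace.thresholds import find_thresholds
from taxoplace.tree import RegionTree


def make_lineage(*names):
    return Lineage.from_names(names)


def random_labeled_tree(rng, max_tips=12, n_labels=4):
    """Random rooted binary tree with branch lengths and single-label
    tip taxonomies, for oracle comparisons."""
    from skbio import TreeNode

    n = int(rng.integers(3, max_tips + 1))
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.01, 0.5)))
             for i in range(n)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(length=float(rng.uniform(0.01, 0.5)))
        parent.extend([a, b])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    tax = TaxonomyTable({
        f"t{i}": Lineage.from_names(
            ["D1", "P1", "C1", "O1", "F1",
             f"G{int(rng.integers(n_labels)) + 1}",
             f"G S{int(rng.integers(n_labels)) + 1}"]
        )
        for i in range(n)
    })
    return RegionTree(tree=root, taxonomy=tax)


@pytest.fixture(scope="session")
def fixture64():
    """Noise-free concordant fixture: 16 species x 4 sequences."""
    return simulate_fixture(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def region_slice(fixture64):
    return fixture64.region_slice()


@pytest.fixture(scope="session")
def nj_tree(fixture64, region_slice):
    return build_region_tree(region_slice, fixture64.taxonomy, "internal-nj")


@pytest.fixture(scope="session")
def nj_thresholds(nj_tree):
    return find_thresholds(nj_tree)


@pytest.fixture(scope="session")
def nj_labeling(nj_tree, nj_thresholds):
    return propagate(nj_tree, specificity_mode(nj_thresholds, "specific"))


def subset_slice(sl: RegionSlice, ids) -> RegionSlice:
    keep = set(ids)
    return RegionSlice(start=sl.start, end=sl.end,
                       seqs={i: s for i, s in sl.seqs.items() if i in keep})
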