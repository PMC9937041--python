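"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ponevo.phylo_engine import Alignment, PhyloTree
from ponevo.phylo_engine.alignment import AMINO_ACIDS

# the exhaustive-enumeration likelihood oracle lives in ponevo.studies so
# the acceptance script can use it too; re-exported here for the tests
from ponevo.studies import enumeration_log_likelihood  # noqa: F401


@pytest.fixture
def four_taxon_tree() -> PhyloTree:
    return PhyloTree.from_newick("((t1:0.3,t2:0.1):0.2,(t3:0.4,t4:0.05):0.1);")


@pytest.fixture
def six_taxon_tree() -> PhyloTree:
    return PhyloTree.from_newick(
        "(((a:0.2,b:0.2):0.1,c:0.3):0.1,(d:0.2,e:0.2):0.15,f:0.4);"
    )


@pytest.fixture
def marked_six_taxon_tree() -> PhyloTree:
    """Six taxa with a three-branch foreground clade (a, b and their stem)."""
    return PhyloTree.from_newick(
        "(((a#1:0.2,b#1:0.2)#1:0.1,c:0.3):0.1,(d:0.2,e:0.2):0.15,f:0.4);"
    )


def random_protein_alignment(
    rng: np.random.Generator, names: list[str], n_sites: int, gap_prob: float = 0.1
) -> Alignment:
    chars = list(AMINO_ACIDS) + ["-"]
    p = [(1 - gap_prob) / 20] * 20 + [gap_prob]
    rows = ["".join(rng.choice(chars, size=n_sites, p=p)) for _ in names]
    return Alignment(list(names), rows)


def random_small_tree(rng: np.random.Generator, n_leaves: int) -> PhyloTree:
    """Random binary topology with 2..5 leaves and random branch lengths."""
    nodes = [f"t{i}:{rng.uniform(0.01, 0.8):.4f}" for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.01, 0.5):.4f}")
    return PhyloTree.from_newick(f"({nodes[0]},{nodes[1]});")
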