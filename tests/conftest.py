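"""Shared fixtures and independent oracles for the test suite."""

import itertools

import pytest

from phylokit import parse_newick


WORKED_NEWICK = "((A:1,B:2):1,(C:3,D:4):2);"


@pytest.fixture
def worked_tree():
    """The 4-leaf tree whose statistics are all derivable by hand."""
    return parse_newick(WORKED_NEWICK)


def patristic_oracle(tree):
    """Brute-force tip-to-tip distances via parent-chain path sums.

    Independent of the production implementation: walks each leaf's chain
    of ancestors and drops the shared suffix above the LCA.
    """
    leaves = tree.leaves()

    def chain(leaf):
        path = []
        node = leaf
        while node.parent is not None:
            path.append(node)
            node = node.parent
        return path

    out = {}
    for a, b in itertools.combinations(leaves, 2):
        pa, pb = chain(a), chain(b)
        shared = {id(x) for x in pa} & {id(x) for x in pb}
        dist = sum(x.length for x in pa if id(x) not in shared)
        dist += sum(x.length for x in pb if id(x) not in shared)
        out[frozenset((a.label, b.label))] = dist
    return out
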