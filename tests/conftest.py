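"""Shared fixtures and independent oracle helpers.

The random-tree helpers build topologies as nested Python tuples and
derive Newick strings and clade sets directly from the tuples, so tests
that compare the package's tree handling against them use a genuinely
independent representation.
"""

from __future__ import annotations

import io

import numpy as np
import pytest

from tolprof import (
    SpeciesPanel,
    default_panel,
    load_ontology,
    make_mini_obo,
    make_reference_tree,
)
from tolprof.tol import enumerate_clades


@pytest.fixture(scope="session")
def human_panel():
    return default_panel("human")


@pytest.fixture(scope="session")
def fly_panel():
    return default_panel("fly")


@pytest.fixture(scope="session")
def human_tree(human_panel):
    return make_reference_tree(human_panel)


@pytest.fixture(scope="session")
def human_clades(human_tree):
    return enumerate_clades(human_tree)


@pytest.fixture(scope="session")
def mini_dag():
    return load_ontology(io.StringIO(make_mini_obo()))


# ---------------------------------------------------------------------
# independent tree representation: nested tuples


def random_topology(rng: np.random.Generator, labels: list[str]):
    """A uniformly coalesced random binary rooted topology as tuples."""
    items: list = list(labels)
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        items.append((a, b))
    return items[0]


def topology_to_newick(t) -> str:
    if isinstance(t, str):
        return t
    return "(" + ",".join(topology_to_newick(c) for c in t) + ")"


def topology_leaf_sets(t) -> list[frozenset[str]]:
    """Leaf-name set of every subtree (leaves included) — brute force."""
    if isinstance(t, str):
        return [frozenset({t})]
    out = []
    child_roots = []
    for child in t:
        sets = topology_leaf_sets(child)
        out.extend(sets)
        child_roots.append(sets[-1])  # last entry is the child's own set
    out.append(frozenset().union(*child_roots))
    return out


def topology_leaves(t) -> frozenset[str]:
    return topology_leaf_sets(t)[-1]


def panel_for_topology(t, reference: str) -> SpeciesPanel:
    leaves = sorted(topology_leaves(t))
    return SpeciesPanel(
        reference=reference, targets=tuple(s for s in leaves if s != reference)
    )
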