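"""Tree-of-life consistency of conservation profiles.

A non-universal conservation profile is *TOL consistent* if either the
species carrying a homologue (including the reference species, which
carries the protein by definition) form a monophyletic clade of the
rooted species tree, or the species lacking a homologue do.  A profile
with a single absent species is always consistent, because every leaf is
a (trivial) clade.

The criterion is stricter than Dollo parsimony: a Dollo history needs
one gain and any number of independent losses, whereas TOL consistency
tolerates at most one "block" of absence that is itself a clade.  The
:func:`dollo_loss_count` helper computes the minimum number of losses
under a single-gain model, so the relationship between the two notions
can be measured directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .panel import SpeciesPanel
from .profiles import ProfileSet

__all__ = [
    "TolStatus",
    "TolLabel",
    "RootedSpeciesTree",
    "CladeIndex",
    "read_rooted_tree",
    "enumerate_clades",
    "classify_tol",
    "classify_profile_set",
    "dollo_loss_count",
]


class TolStatus(str, Enum):
    UNIVERSAL = "UNIVERSAL"
    CONSISTENT_PRESENCE_CLADE = "CONSISTENT_PRESENCE_CLADE"
    CONSISTENT_ABSENCE_CLADE = "CONSISTENT_ABSENCE_CLADE"
    INCONSISTENT = "INCONSISTENT"

    @property
    def is_consistent(self) -> bool:
        """Universal and both consistent states count as TOL compatible."""
        return self is not TolStatus.INCONSISTENT


@dataclass(frozen=True)
class TolLabel:
    """Consistency status of one profile, with the witnessing clade."""

    status: TolStatus
    witness_clade: frozenset[str] | None = None

    def __post_init__(self) -> None:
        needs_witness = self.status in (
            TolStatus.CONSISTENT_PRESENCE_CLADE,
            TolStatus.CONSISTENT_ABSENCE_CLADE,
        )
        if needs_witness != (self.witness_clade is not None):
            raise ValueError("witness_clade set iff status is CONSISTENT_*")


class RootedSpeciesTree:
    """A rooted tree whose leaves are exactly the panel's species."""

    def __init__(self, tree: dendropy.Tree, panel: SpeciesPanel) -> None:
        leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        expected = set(panel.all_species)
        if leaves != expected:
            missing = sorted(expected - leaves)
            extra = sorted(leaves - expected)
            raise ValueError(
                f"tree leaves do not match panel: missing {missing}, extra {extra}"
            )
        self.tree = tree
        self.panel = panel

    @property
    def n_leaves(self) -> int:
        return len(self.panel.all_species)

    def leaf_sets(self) -> list[frozenset[str]]:
        """Leaf-name set of every node (leaves included), postorder."""
        sets: dict[int, frozenset[str]] = {}
        out: list[frozenset[str]] = []
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                s = frozenset({node.taxon.label})
            else:
                s = frozenset().union(*(sets[id(c)] for c in node.child_nodes()))
            sets[id(node)] = s
            out.append(s)
        return out

    def mrca_leaf_set(self, species: frozenset[str]) -> frozenset[str]:
        """Leaf set of the most recent common ancestor of ``species``."""
        best: frozenset[str] | None = None
        for s in self.leaf_sets():
            if species <= s and (best is None or len(s) < len(best)):
                best = s
        assert best is not None  # the root covers everything
        return best

    def pruned(self, species: str) -> "RootedSpeciesTree":
        """Copy of the tree with one leaf removed (reference-pruned view).

        The returned tree carries a nominal panel whose only role is the
        leaf roster; profile bit order is not defined for it.
        """
        clone = self.tree.clone(depth=1)
        taxon = clone.taxon_namespace.get_taxon(species)
        clone.prune_taxa([taxon], suppress_unifurcations=True)
        leaves = sorted(
            leaf.taxon.label for leaf in clone.leaf_node_iter()
        )
        pruned_panel = SpeciesPanel(reference=leaves[0], targets=tuple(leaves[1:]))
        return RootedSpeciesTree(clone, pruned_panel)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass(frozen=True)
class CladeIndex:
    """All monophyletic leaf-sets of a rooted tree, for O(1) membership."""

    all_clades: frozenset[frozenset[str]]
    n_leaves: int

    def __contains__(self, leaf_set: frozenset[str]) -> bool:
        return frozenset(leaf_set) in self.all_clades

    @property
    def nontrivial_count(self) -> int:
        """Clades where both the clade and its complement have >= 2 leaves."""
        return sum(1 for c in self.all_clades if 2 <= len(c) <= self.n_leaves - 2)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"clade_id": i, "size": len(c), "members": ",".join(sorted(c))}
            for i, c in enumerate(
                sorted(self.all_clades, key=lambda c: (len(c), sorted(c)))
            )
        ]
        return pd.DataFrame(rows, columns=["clade_id", "size", "members"])


def read_rooted_tree(
    source, panel: SpeciesPanel, outgroup: str | None = "sea_anemone"
) -> RootedSpeciesTree:
    """Read a Newick tree over the panel's species and root it.

    ``source`` may be a path or a Newick string.  If ``outgroup`` is
    given and is not already a child of the root, the tree is re-rooted
    on the outgroup's branch (default: the sea anemone, the only
    non-bilaterian of the metazoan panel).
    """
    text = None
    if isinstance(source, str) and source.lstrip().startswith("("):
        text = source
    if text is None:
        with open(source) as fh:
            text = fh.read()
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        rooting="force-rooted",
        preserve_underscores=True,
    )
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if outgroup is not None and outgroup in leaves:
        root_children = tree.seed_node.child_nodes()
        already = any(
            c.is_leaf() and c.taxon.label == outgroup for c in root_children
        )
        if not already:
            leaf = [
                n for n in tree.leaf_node_iter() if n.taxon.label == outgroup
            ][0]
            tree.reroot_at_edge(leaf.edge, update_bipartitions=False)
    tree.suppress_unifurcations()
    return RootedSpeciesTree(tree, panel)


def enumerate_clades(t: RootedSpeciesTree) -> CladeIndex:
    """Collect every monophyletic leaf-set (one per node) of the tree."""
    return CladeIndex(
        all_clades=frozenset(t.leaf_sets()), n_leaves=t.n_leaves
    )


def classify_tol(
    bits: Sequence[int] | np.ndarray,
    idx: CladeIndex,
    panel: SpeciesPanel,
    *,
    include_reference: bool = True,
) -> TolLabel:
    """Label a profile TOL consistent or not against a clade index.

    The presence set is taken reference-inclusive by default: the
    reference species carries the protein by definition, so presence =
    {targets with bit 1} + {reference} is tested against the clades of
    the full tree.  This is the reading under which, e.g., a human
    profile present in exactly the ten other vertebrates is consistent
    (presence + human = the vertebrate clade) while the paraphyletic
    invertebrates correctly fail the presence test.  With
    ``include_reference=False`` the caller must supply a clade index
    built on the reference-pruned tree.
    """
    arr = np.asarray(bits)
    if arr.shape != (panel.k,):
        raise ValueError(f"profile length {arr.shape} != panel size {panel.k}")
    present = frozenset(
        panel.targets[j] for j in range(panel.k) if arr[j]
    )
    if len(present) == panel.k:
        return TolLabel(TolStatus.UNIVERSAL)
    if include_reference:
        presence = present | {panel.reference}
        universe = panel.all_species
    else:
        presence = present
        universe = frozenset(panel.targets)
    absence = frozenset(universe - presence)
    if presence and presence in idx:
        return TolLabel(TolStatus.CONSISTENT_PRESENCE_CLADE, presence)
    if absence in idx:
        return TolLabel(TolStatus.CONSISTENT_ABSENCE_CLADE, absence)
    return TolLabel(TolStatus.INCONSISTENT)


def classify_profile_set(
    ps: ProfileSet, idx: CladeIndex, *, include_reference: bool = True
) -> pd.DataFrame:
    """Per-protein TOL labels as a tidy table.

    Columns: protein_id, status, witness_clade (comma-joined, empty when
    there is no witness).
    """
    rows = []
    cache: dict[tuple[int, ...], TolLabel] = {}
    for pid, row in zip(ps.protein_ids, ps.matrix):
        key = tuple(int(b) for b in row)
        label = cache.get(key)
        if label is None:
            label = classify_tol(row, idx, ps.panel, include_reference=include_reference)
            cache[key] = label
        rows.append(
            {
                "protein_id": pid,
                "status": label.status.value,
                "witness_clade": ",".join(sorted(label.witness_clade))
                if label.witness_clade
                else "",
            }
        )
    return pd.DataFrame(rows, columns=["protein_id", "status", "witness_clade"])


def dollo_loss_count(
    bits: Sequence[int] | np.ndarray,
    t: RootedSpeciesTree,
    panel: SpeciesPanel | None = None,
) -> int:
    """Minimum losses under a single-gain (Dollo) history of a profile.

    The gain is placed at the most recent common ancestor of the
    presence set (reference included); each maximal subtree under that
    ancestor containing no present species must then be explained by one
    irreversible loss on its stem branch.  Universal profiles need no
    losses.  Every non-universal TOL-consistent profile has at most one
    loss, but not conversely — a presence set scattered inside one clade
    satisfies Dollo with one loss per absent subtree while failing TOL
    consistency.
    """
    panel = panel or t.panel
    arr = np.asarray(bits)
    if arr.shape != (panel.k,):
        raise ValueError("profile length does not match panel")
    presence = frozenset(
        panel.targets[j] for j in range(panel.k) if arr[j]
    ) | {panel.reference}
    # locate the MRCA node in the dendropy tree
    taxa = [
        t.tree.taxon_namespace.get_taxon(s) for s in presence
    ]
    if len(presence) == 1:
        mrca = [
            n
            for n in t.tree.leaf_node_iter()
            if n.taxon.label == next(iter(presence))
        ][0]
    else:
        mrca = t.tree.mrca(taxa=taxa)

    def losses(node) -> int:
        if node.is_leaf():
            return 0  # a present leaf (absent leaves are pruned by caller)
        n = 0
        for child in node.child_nodes():
            child_leaves = {
                leaf.taxon.label for leaf in child.leaf_iter()
            }
            if child_leaves.isdisjoint(presence):
                n += 1  # one loss on the stem of a fully absent subtree
            else:
                n += losses(child)
        return n

    return losses(mrca)
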