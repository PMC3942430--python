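"""Synthetic inputs: gain/loss profiles, annotations, hit tables.

Real conservation-profile studies start from all-vs-all BLAST runs over
complete proteomes; everything here emulates the *outputs* of that step
so the whole pipeline is exercisable without sequence data.  The
generative model for a profile is single-gain/irreversible-loss (Dollo
style) evolution on the rooted species tree:

* with probability ``p_universal`` the protein is ancient and retained
  everywhere (an all-ones profile, emulating the roughly two-thirds of
  real proteomes that are universal at lenient homology thresholds);
* otherwise the gene is gained once on the stem of a clade containing
  the reference species, then lost on branches below the gain with
  per-branch probability ``loss_rate`` (in the default strict mode, at
  most one maximal lost subtree is kept and only when the resulting
  profile stays consistent with the tree — so pre-noise profiles are
  TOL consistent by construction);
* finally each bit flips independently with probability ``flip_noise``,
  modelling homoplasy and spurious/missed homology calls, which may
  break consistency.

The generating clade doubles as a planted cluster label for clustering
recovery tests, and :func:`simulate_annotations` plants term
enrichments in chosen clusters for enrichment recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .panel import SpeciesPanel, default_panel
from .profiles import ProfileSet
from .tol import (
    CladeIndex,
    RootedSpeciesTree,
    TolStatus,
    classify_tol,
    enumerate_clades,
    read_rooted_tree,
)

__all__ = [
    "SimParams",
    "SimTruth",
    "REFERENCE_TREE_NEWICK",
    "make_reference_tree",
    "clades_containing",
    "simulate_profiles",
    "simulate_annotations",
    "write_hit_table",
    "write_roster",
    "make_mini_obo",
]

#: Rooted 18-taxon metazoan topology: sea anemone (cnidarian) is the
#: outgroup; the worm is the outgroup of the remaining bilaterians;
#: insects, other invertebrates, and the vertebrate clade follow.
REFERENCE_TREE_NEWICK = (
    "(sea_anemone,(worm,(((fly,fly_yakuba),bee),"
    "(sea_urchin,(ciona,(zebrafish,((lizard,(chicken,zebra_finch)),"
    "(platypus,(opossum,(cow,((human,chimpanzee),(mouse,rat))))))))))));"
)


def make_reference_tree(panel: SpeciesPanel | None = None) -> RootedSpeciesTree:
    """The packaged 18-taxon rooted species tree (unit branch lengths)."""
    panel = panel or default_panel("human")
    tree = read_rooted_tree(REFERENCE_TREE_NEWICK, panel, outgroup="sea_anemone")
    for edge in tree.tree.preorder_edge_iter():
        if edge.head_node is not tree.tree.seed_node:
            edge.length = 1.0
    return tree


def clades_containing(
    tree: RootedSpeciesTree, species: str, min_size: int = 2
) -> list[frozenset[str]]:
    """Monophyletic clades containing a species, smallest first."""
    clades = [
        c
        for c in enumerate_clades(tree).all_clades
        if species in c and len(c) >= min_size
    ]
    return sorted(clades, key=lambda c: (len(c), sorted(c)))


@dataclass
class SimParams:
    """Generating conditions for synthetic conservation profiles.

    Defaults emulate the empirical mix seen in lenient-threshold
    metazoan profiling: about 65% universal proteins, clade-restricted
    gains for the rest, occasional within-clade losses, and a low
    homoplasy bit-flip rate.
    """

    n_proteins: int = 2000
    p_universal: float = 0.65
    clade_weights: Mapping[frozenset, float] | None = None
    loss_rate: float = 0.2
    flip_noise: float = 0.02
    strict_consistent: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_universal", "loss_rate", "flip_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if self.clade_weights is not None:
            w = np.array(list(self.clade_weights.values()), dtype=float)
            if (w < 0).any() or w.sum() == 0:
                raise ValueError("clade weights must be >= 0 and not all zero")


@dataclass
class SimTruth:
    """Ground truth of a simulation run, one row per protein."""

    table: pd.DataFrame  # protein_id, gain_clade, planted_cluster, n_losses,
    #                      n_flips, true_status
    planted_terms: dict[str, frozenset[str]] = field(default_factory=dict)

    def cluster_labels(self) -> pd.Series:
        return self.table.set_index("protein_id")["planted_cluster"]


def _lose_subtrees(
    rng: np.random.Generator,
    tree: RootedSpeciesTree,
    gain_clade: frozenset[str],
    loss_rate: float,
    strict: bool,
    idx: CladeIndex,
    panel: SpeciesPanel,
) -> tuple[frozenset[str], int]:
    """Apply per-branch losses under the gain node; return (presence, n_losses).

    Losses are maximal lost subtrees: a branch drawn for loss removes
    its whole subtree.  The reference species never loses the gene (the
    protein exists there by definition).  In strict mode at most one
    maximal lost subtree is kept, and only if the post-loss profile is
    still consistent with the tree; otherwise the loss is reverted.
    """
    # candidate subtrees strictly below the gain MRCA, as leaf sets
    node_sets = [
        s
        for s in tree.leaf_sets()
        if s < gain_clade and panel.reference not in s
    ]
    lost: list[frozenset[str]] = []
    # maximal subtrees drawn independently; nested draws collapse upward
    drawn = [s for s in node_sets if rng.random() < loss_rate]
    for s in sorted(drawn, key=len, reverse=True):
        if not any(s <= t for t in lost):
            lost.append(s)
    if strict and lost:
        lost = [lost[0]]
    presence = gain_clade - frozenset().union(*lost) if lost else gain_clade
    if strict and lost:
        bits = np.array(
            [1 if s in presence else 0 for s in panel.targets], dtype=np.uint8
        )
        if not classify_tol(bits, idx, panel).status.is_consistent:
            return gain_clade, 0  # revert: loss would break consistency
    return presence, len(lost)


def simulate_profiles(
    tree: RootedSpeciesTree,
    panel: SpeciesPanel,
    params: SimParams,
) -> tuple[ProfileSet, SimTruth]:
    """Draw conservation profiles by gain/loss evolution on the tree.

    Returns the profile set plus per-protein ground truth: the gain
    clade (the planted cluster), loss and flip counts, and the TOL
    status of the pre-noise profile (always consistent or universal in
    strict mode).
    """
    rng = np.random.default_rng(params.seed)
    idx = enumerate_clades(tree)
    root_clade = frozenset(panel.all_species)
    if params.clade_weights is None:
        clades = clades_containing(tree, panel.reference)
        weights = np.ones(len(clades))
    else:
        clades = [frozenset(c) for c in params.clade_weights]
        for c in clades:
            if c not in idx:
                raise ValueError(f"clade_weights key is not a tree clade: {sorted(c)}")
            if panel.reference not in c:
                raise ValueError(
                    "gain clades must contain the reference species: "
                    f"{sorted(c)}"
                )
        weights = np.array(list(params.clade_weights.values()), dtype=float)
    weights = weights / weights.sum()
    clade_rank = {c: r for r, c in enumerate(sorted(clades, key=lambda c: (len(c), sorted(c))))}

    ids, rows, truth_rows = [], [], []
    for i in range(params.n_proteins):
        pid = f"P{i:05d}"
        if rng.random() < params.p_universal:
            presence = root_clade
            gain = root_clade
            n_losses = 0
        else:
            gain = clades[rng.choice(len(clades), p=weights)]
            presence, n_losses = _lose_subtrees(
                rng, tree, gain, params.loss_rate,
                params.strict_consistent, idx, panel,
            )
        bits = np.array(
            [1 if s in presence else 0 for s in panel.targets], dtype=np.uint8
        )
        true_label = classify_tol(bits, idx, panel)
        flips = rng.random(panel.k) < params.flip_noise
        bits = np.where(flips, 1 - bits, bits).astype(np.uint8)
        ids.append(pid)
        rows.append(bits)
        truth_rows.append(
            {
                "protein_id": pid,
                "gain_clade": ";".join(sorted(gain)),
                "planted_cluster": -1 if gain == root_clade and n_losses == 0
                and len(presence) == len(root_clade) else clade_rank.get(gain, -1),
                "n_losses": n_losses,
                "n_flips": int(flips.sum()),
                "true_status": true_label.status.value,
            }
        )
    ps = ProfileSet(ids, np.array(rows), panel)
    return ps, SimTruth(table=pd.DataFrame(truth_rows))


def simulate_annotations(
    truth: SimTruth,
    terms: Mapping[str, float],
    enrich_spec: Mapping[tuple[int, str], float] | None = None,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Assign ontology terms with planted cluster-specific enrichments.

    ``terms`` maps each term to its baseline frequency q; a protein in
    planted cluster c receives term t with probability min(1, q_t * r)
    when (c, t) is in ``enrich_spec`` (relative risk r >= 1), else q_t.
    Returns direct annotations (protein -> term set).
    """
    enrich_spec = dict(enrich_spec or {})
    for (c, t), r in enrich_spec.items():
        if r < 1:
            raise ValueError("relative risk must be >= 1")
        if t not in terms:
            raise ValueError(f"planted term {t!r} missing from the term table")
        if min(1.0, terms[t] * r) == 1.0 and terms[t] * r > 1.0:
            import warnings

            warnings.warn(
                f"planted probability for {t!r} capped at 1", stacklevel=2
            )
    rng = np.random.default_rng(seed)
    clusters = truth.cluster_labels()
    out: dict[str, set[str]] = {}
    planted: dict[str, set[str]] = {}
    for pid, cluster in clusters.items():
        got: set[str] = set()
        for t, q in terms.items():
            r = enrich_spec.get((int(cluster), t), 1.0)
            if rng.random() < min(1.0, q * r):
                got.add(t)
                if r > 1.0:
                    planted.setdefault(pid, set()).add(t)
        out[pid] = got
    truth.planted_terms = {p: frozenset(s) for p, s in planted.items()}
    return out


def write_annotations(direct: Mapping[str, set[str]], path) -> None:
    """Write direct annotations as a (protein_id, term) TSV."""
    with open(path, "w") as fh:
        for pid in sorted(direct):
            for term in sorted(direct[pid]):
                fh.write(f"{pid}\t{term}\n")


def write_roster(ps: ProfileSet, path) -> None:
    with open(path, "w") as fh:
        for pid in ps.protein_ids:
            fh.write(pid + "\n")


def write_hit_table(ps: ProfileSet, panel: SpeciesPanel, path, seed: int = 0) -> None:
    """Emit a plausible 12-column BLAST tabular file realising a profile set.

    Every 1-bit produces one hit row (bit score uniform in 40..500,
    e-value log-uniform), and with probability 0.3 an extra lower-
    scoring decoy row for the same (query, species) pair, so downstream
    best-hit selection is exercised.  Subject IDs are
    ``species|S<counter>`` so the default prefix resolution applies.
    Profiles round-trip exactly: reading the table back with the
    profile set's roster reproduces the same binary matrix.
    """
    rng = np.random.default_rng(seed)
    counter = 0
    with open(path, "w") as fh:
        for pid, row in zip(ps.protein_ids, ps.matrix):
            for j, bit in enumerate(row):
                if not bit:
                    continue
                species = panel.targets[j]
                n_rows = 2 if rng.random() < 0.3 else 1
                score = rng.uniform(40.0, 500.0)
                for r in range(n_rows):
                    counter += 1
                    sid = f"{species}|S{counter:06d}"
                    bs = score if r == 0 else score * rng.uniform(0.3, 0.9)
                    ev = 10.0 ** (-rng.uniform(1.0, 50.0))
                    length = int(rng.integers(50, 800))
                    pident = round(float(rng.uniform(20, 100)), 2)
                    fh.write(
                        "\t".join(
                            [
                                pid,
                                sid,
                                f"{pident:.2f}",
                                str(length),
                                str(int(rng.integers(0, 100))),
                                str(int(rng.integers(0, 20))),
                                "1",
                                str(length),
                                "1",
                                str(length),
                                f"{ev:.2e}",
                                f"{bs:.1f}",
                            ]
                        )
                        + "\n"
                    )


def make_mini_obo(path=None) -> str:
    """A small synthetic ontology: 30 terms over the three GO namespaces.

    Ten terms per namespace arranged as a root, two mid-level terms and
    seven leaves, including one multi-parent leaf per namespace (the
    graph is a DAG, not a tree) and one alternative ID.  Returns the
    OBO text; writes it to ``path`` when given.
    """
    stanzas = ["format-version: 1.2\nontology: synthetic-mini\n"]
    for ns_idx, ns in enumerate(
        ("biological_process", "molecular_function", "cellular_component")
    ):
        base = ns_idx * 10 + 1
        root = f"GO:{base:07d}"
        mid1 = f"GO:{base + 1:07d}"
        mid2 = f"GO:{base + 2:07d}"
        stanzas.append(
            f"[Term]\nid: {root}\nname: {ns} root\nnamespace: {ns}\n"
        )
        for mid, label in ((mid1, "alpha"), (mid2, "beta")):
            stanzas.append(
                f"[Term]\nid: {mid}\nname: {ns} branch {label}\n"
                f"namespace: {ns}\nis_a: {root} ! root\n"
            )
        for leaf_i in range(7):
            tid = f"GO:{base + 3 + leaf_i:07d}"
            parent = mid1 if leaf_i < 4 else mid2
            extra = ""
            if leaf_i == 6:  # multi-parent leaf: DAG, not a tree
                extra = f"is_a: {mid1} ! second parent\n"
            alt = "alt_id: GO:0099999\n" if (ns_idx == 0 and leaf_i == 0) else ""
            stanzas.append(
                f"[Term]\nid: {tid}\nname: {ns} leaf {leaf_i}\n"
                f"namespace: {ns}\n{alt}is_a: {parent} ! parent\n{extra}"
            )
    text = "\n".join(stanzas)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
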