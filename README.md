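# tolprof

Top-down analysis of protein conservation profiles across a species
panel: conservation classes, tree-of-life consistency, Quantum
Clustering, and GO-term enrichment — with a gain/loss simulator that
generates fully synthetic, ground-truthed inputs for every stage.

## The problem

Given a reference proteome (say, human) and a panel of k other species,
each protein gets a binary **conservation profile**: bit j is 1 iff at
least one homologue was detected in species j (from BLAST tabular hit
lists; any score counts). Proteins with i ones form conservation class
H_i; H_k holds the **universal** proteins, H_0 the **orphans**.
Instead of studying protein families one by one ("bottom up"), the
package partitions the whole proteome hierarchically ("top down"):

1. universal vs non-universal;
2. non-universal profiles that are **TOL consistent** — either the
   homologue-bearing species (reference included) or the
   homologue-lacking species form a monophyletic clade of the rooted
   species tree — vs inconsistent ones;
3. clusters of the TOL-consistent profiles, found by **Quantum
   Clustering**;

and then asks, at every level, which GO terms are over-represented
(hypergeometric two-list test, annotations propagated to all `is_a`
ancestors).

Quantum Clustering places cluster centres at the minima of the
potential V(x) obtained from the Parzen wavefunction
ψ(x) = Σᵢ wᵢ exp(−‖x−xᵢ‖²/2σ²) through the time-independent
Schrödinger relation

    V(x) = E − d/2 + (1 / 2σ²ψ) Σᵢ wᵢ ‖x−xᵢ‖² exp(−‖x−xᵢ‖²/2σ²),

with E fixed so that min V over the data is 0. Profiles are first
SVD-embedded (uncentered, default d = 5) onto the unit sphere, unique
patterns weighted by multiplicity; every point then follows gradient
descent on V into its basin.

## Worked example

```python
import numpy as np
from tolprof import (
    default_panel, make_reference_tree, enumerate_clades, SimParams,
    simulate_profiles, class_distribution, classify_profile_set,
    QuantumClustering,
)

panel = default_panel("human")          # 17 metazoan targets
tree = make_reference_tree(panel)       # rooted 18-taxon tree
idx = enumerate_clades(tree)
print(idx.nontrivial_count)             # 15

ps, truth = simulate_profiles(tree, panel, SimParams(n_proteins=800, seed=7))
table = class_distribution(ps)
print(table.universal_count, table.percent(17))   # 389 48.62

labels = classify_profile_set(ps, idx)
print(labels["status"].value_counts().to_dict())
# {'UNIVERSAL': 389, 'CONSISTENT_PRESENCE_CLADE': 185,
#  'CONSISTENT_ABSENCE_CLADE': 127, 'INCONSISTENT': 99}

consistent = labels.loc[
    labels.status.str.startswith("CONSISTENT"), "protein_id"
]
sub = ps.subset([p for p in consistent if ps[p].sum() > 0])
model = QuantumClustering(sigma=0.4, d=5).fit(sub)
print(model.n_clusters_)                # 2
print(model.stats_frame()[["cluster", "n_proteins", "n_patterns", "MAP_count"]])
```

The 15 is the number of non-trivial monophyletic clades (both sides of
the split ≥ 2 species) of the packaged 18-taxon tree. The class table
shows how many proteins are conserved in all 17 targets (here 389 of
800 = 48.62% after homoplasy noise dilutes the 65% universal gains).
The TOL labels split the non-universal profiles into
clade-compatible and incompatible ones, and the fitted clustering
object carries per-cluster sizes, pattern counts, most-abundant
profiles (MAP) and centres of mass.

The same flow runs from the shell:

```bash
tolprof simulate --n-proteins 800 --seed 7 --outdir bundle/
tolprof run-all --config run.yaml
```

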