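# Methods

## Conservation profiles and classes

A conservation profile is a binary vector over an ordered panel of k
target species (default k = 17, the metazoan panel): bit j = 1 iff the
reference protein has at least one homology hit in species j,
regardless of score. Hit lists are consumed as BLAST tabular output
(`-outfmt 6`, 12 columns); per (query, species) only existence matters,
so the best-hit reduction (highest bit score, ties by file order) can
never change a profile. Tables should be generated with lenient
settings (default scoring, E ≤ 10, maximum alignments retained) so that
distant, low-scoring homologies still populate the vector — the
"homologue present at any score" convention deliberately errs toward
presence, and the later tree-consistency filter is what corrects for
spurious calls. Proteins are classed by popcount: H_i holds proteins
with exactly i ones; H_k is "universal", H_0 "orphan". An explicit
query roster is required so that zero-hit proteins appear as orphans
rather than vanishing.

Percent columns follow the conventions of the two published table
styles they mirror: two decimals for the full class distribution,
nearest integer for subset cross-tabs (essential-gene style).

## The species tree and TOL consistency

The packaged reference tree covers 18 metazoans (7 mammals, 4 other
vertebrates, 7 invertebrates of which 3 are insects), rooted on the sea
anemone — the only non-bilaterian — with the worm as the next outgroup.
Within-clade resolution of a few internal nodes is not load-bearing:
the only topology-level quantity asserted anywhere is the count of
non-trivial clades, which is invariant to such reorderings. A
"non-trivial" clade has ≥ 2 species on both sides of its split; for a
binary root-outgroup tree on n leaves that count is n − 3 (15 for
n = 18). This is the counting under which the trivial leaf-clades
automatically make any single-species absence consistent.

A non-universal profile is TOL consistent iff its presence set — the
1-bit species plus the reference, which carries the protein by
definition — or its absence set is exactly the leaf set of one tree
node. Reference-inclusive evaluation is the default because it is the
reading under which a human profile present in exactly the ten other
vertebrates is consistent (presence + human = the vertebrate clade)
while the paraphyletic invertebrates correctly fail the presence test;
a `prune_reference` option evaluates the presence set in the
reference-pruned tree instead. All-zero profiles classify as
presence-consistent (the reference leaf is a trivial clade).

`dollo_loss_count` puts the single gain at the MRCA of the presence set
and counts maximal absent subtrees below it — the minimum number of
irreversible losses. TOL consistency is strictly stronger than
"≤ 1 loss": every consistent non-universal profile needs at most one
loss, but e.g. presence {reference, mouse, rat} costs one loss
(chimpanzee) while being inconsistent. The test suite checks the
implication on the 18-taxon tree and exact agreement with a brute-force
oracle over loss placements on random trees.

## Quantum clustering

Unique patterns (with multiplicities as weights) are embedded by
uncentered SVD onto the top-d right singular directions and projected
on the unit sphere; d defaults to 5. Mean-centering is deliberately
omitted: the pattern matrix is nonnegative and the unit-sphere
convention expects raw coordinates. Weighting unique patterns is
equivalent to replicating duplicates — scaling ψ leaves V and its
gradient unchanged — so the deduplicated embedding is used throughout
for speed. All-zero patterns have no direction on the sphere and are
rejected by the embedding; the pipeline therefore always excludes
orphans from the clustering stage (they remain in the partition used
as enrichment background).

The potential is

    ψ(x) = Σ_i w_i exp(−‖x−x_i‖²/2σ²)
    V(x) = E − d/2 + (1/2σ²ψ) Σ_i w_i ‖x−x_i‖² exp(−‖x−x_i‖²/2σ²)

with E set once so min_i V(x_i) = 0. The gradient is analytic (checked
against central differences at 1e-5). Descent runs in the ambient
d-space, not constrained to the sphere, matching the original QC
formulation.

Numerical choices for the descent:

* initial step σ/10, per-point adaptive: a move that lowers V is kept
  and the step grows ×1.1, a move that raises V is reverted and the
  step halves. Adaptivity is necessary, not cosmetic — the curvature
  of V scales as 1/σ², so any fixed step is unstable for small σ and
  needs O(σ) iterations for large σ;
* per-iteration displacement capped at σ/2 (trust region; basins are
  wider than σ so the cap cannot change basin membership);
* convergence when the next displacement would fall below
  merge_tol/10; merge_tol defaults to 1e-3; max_iter 2000;
* assignment = single linkage at merge_tol on the converged positions
  (connected components of the ≤ merge_tol graph);
* clusters numbered 1, 2, … by descending protein count, so "cluster
  1" is always the largest;
* MAP (most abundant profile) ties break to the lexicographically
  smallest pattern.

σ is the resolution knob: σ → ∞ yields one cluster, σ → 0 one cluster
per unique pattern (up to embedding collisions at small d). Because no
single canonical value exists, `auto_sigma` scans a grid from above and
returns the largest width achieving a requested cluster count — the
coarsest clustering at that resolution. Stability under perturbation
is quantified by `noise_stability`: Gaussian noise is added to the
full binary matrix before embedding and the adjusted Rand index
between clean and noisy labels is reported (both runs use the
replicated matrix so the comparison isolates the noise).

## Enrichment

Annotations are closed under the true-path rule (a term implies all its
`is_a` ancestors) over an OBO-loaded DAG; obsolete terms are skipped
and alternative IDs resolve to their primaries. For a target list
inside a background list, each term's p-value is the exact upper
hypergeometric tail P(X ≥ b) with X ~ HG(N, B, n) (scipy's
implementation). No multiple-testing correction is applied by default
— results are read against fixed cutoffs (report ≤ 1e-4, "significant"
≤ 1e-5, display "None" above 1e-2), matching list-based GO tools; an
optional Benjamini–Hochberg column is available. Proteins without any
annotation still count in N and n (they dilute enrichment, as those
tools do); `drop_unannotated` gives the alternative. Annotations are
accepted regardless of evidence code. Cross-species comparison is set
algebra on enriched term IDs per namespace (Venn counts).

## The synthetic generator

`simulate_profiles` emulates the empirical strata of lenient-threshold
metazoan profiling with a single-gain / irreversible-loss model plus
i.i.d. bit-flip noise. Defaults (chosen once as field-realistic study
conditions): n = 2000 proteins, p_universal = 0.65 (the roughly
two-thirds universal share of real proteomes), gain clade uniform over
clades containing the reference, per-branch loss probability 0.2,
flip noise ε = 0.02. In the default strict mode at most one maximal
lost subtree is kept and only when the post-loss profile remains
TOL-consistent, so the pre-noise truth is consistent-or-universal by
construction; flips then break consistency at a controlled rate. Note
the observed universal share is p_universal·(1−ε)^k (≈ 0.46 at the
defaults) — noise demotes all-ones profiles; tests of the universal
rate therefore run at ε = 0.

What the generator does *not* emulate: sequence-level similarity
scores (bit scores in the synthetic hit tables are decorative),
correlated detection failures (short or fast-evolving proteins missing
in blocks of species), lineage-specific duplications, and annotation
bias. Passing recovery tests therefore show that the pipeline's
inference machinery is correct under its own generative assumptions,
not that those assumptions capture every property of real proteomes.

`simulate_annotations` plants term enrichments: a protein in planted
cluster c receives term t with probability min(1, q_t·r) when (c, t)
is planted at relative risk r ≥ 1, else q_t. The planted analog of a
real cluster-specific signal closes the loop for enrichment recovery
tests (r = 20, q = 0.02, 300 vs 3000 gives p far below 1e-5; null runs
at r = 1 stay quiet).

`write_hit_table` realises a profile set as a 12-column tabular file —
one row per 1-bit plus occasional lower-scoring decoy rows — and
round-trips exactly through parsing, best-hit reduction and profile
construction.

## Problem sizes

The shipped tests and the acceptance script run on synthetic sets of
200–2000 proteins, exhaustive profile enumerations on random trees of
up to 8 leaves, and 100-repeat null simulations at 3000 background
proteins; these sizes give stable statistics (recovery ARIs vary by
< 0.02 across seeds) while keeping a full run in well under a minute.

## Known limitations

* TOL consistency is a hard membership test; near-miss profiles (one
  stray bit away from a clade) are simply inconsistent — no soft or
  weighted variant is provided.
* The Dollo counter assumes the single gain sits at the presence MRCA;
  histories with gains above the MRCA (plus extra losses) are never
  cheaper under irreversible loss, but they are not enumerated.
* Quantum clustering cost is O(n²d) per descent iteration in the
  number of unique patterns; the intended regime (hundreds to a few
  thousand patterns) is comfortable, tens of thousands are not.
* `auto_sigma` assumes cluster count is monotone in σ on the supplied
  grid; non-monotone pockets at fine grids can make it return a width
  whose neighbours achieve the same count differently.
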