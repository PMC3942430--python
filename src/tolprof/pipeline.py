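"""End-to-end orchestration of the hierarchical profile analysis.

The full run partitions a proteome top-down — universal vs
non-universal, tree-consistent vs inconsistent, clusters of the
consistent set — and tests term enrichment at every level, with the
background conventions of the hierarchy: universal and non-universal
sets against all proteins; consistent/inconsistent sets against the
non-universal proteins; each cluster against the consistent
non-universal set.  Every intermediate is serialized as CSV so stages
can be rerun independently, and a JSON-lines log records parameters and
counts per stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import enrichment as enr
from . import profiles as prof
from . import qc as qcm
from . import tol as tolm
from .panel import SpeciesPanel, default_panel

__all__ = ["RunConfig", "run_full", "fourway_table", "render_p"]


@dataclass
class RunConfig:
    """Paths, thresholds and clustering settings for a full run."""

    hits: str
    roster: str
    tree: str
    obo: str
    annotations: str
    outdir: str
    reference: str = "human"
    panel: SpeciesPanel | None = None
    subset_lists: dict[str, str] = field(default_factory=dict)
    p_report: float = 1e-4
    p_significant: float = 1e-5
    d: int = 5
    sigma: float | None = None
    k_target: int | None = 9
    sigma_grid: tuple[float, ...] = (1.0, 0.8, 0.6, 0.5, 0.4, 0.3, 0.25, 0.2, 0.15, 0.1)
    merge_tol: float = 1e-3
    max_iter: int = 2000
    include_orphans: bool = True
    prune_reference: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_report < 1 and 0 < self.p_significant < 1):
            raise ValueError("p thresholds must lie in (0, 1)")
        if self.panel is None:
            self.panel = default_panel(self.reference)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()[:16]


class _StageLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def event(self, stage: str, **info) -> None:
        with open(self.path, "a") as fh:
            fh.write(json.dumps({"stage": stage, **info}, sort_keys=True) + "\n")


def run_full(cfg: RunConfig) -> dict:
    """Execute profiles -> classes -> TOL labels -> QC -> enrichment.

    Returns a dict of the in-memory results; all tables are also
    written under ``cfg.outdir``.  Deterministic given the config.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = _StageLog(out / "run_log.jsonl")
    panel = cfg.panel

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # annotate failures with the stage name
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrap

    # --- profiles -----------------------------------------------------
    def _profiles():
        roster = prof.read_roster(cfg.roster)
        hits = prof.read_hit_table(cfg.hits, panel)
        best = prof.best_hits(hits)
        ps = prof.build_profiles(best, roster, panel)
        log.event(
            "profiles",
            n_proteins=len(ps),
            n_hits=len(hits),
            hits_hash=_file_hash(cfg.hits),
            seed=cfg.seed,
        )
        return ps

    ps = stage("profiles")(_profiles)

    table = prof.class_distribution(ps)
    table.to_csv(out / "class_table.csv")
    log.event("classes", universal=table.universal_count, orphans=table.orphan_count)

    subset_tables = {}
    for name, path in cfg.subset_lists.items():
        sub = prof.crosstab_subset(ps, prof.read_roster(path))
        sub.to_csv(out / f"subset_{name}.csv")
        subset_tables[name] = sub

    # --- TOL labels ---------------------------------------------------
    def _tol():
        tree = tolm.read_rooted_tree(cfg.tree, panel)
        if cfg.prune_reference:
            idx = tolm.enumerate_clades(tree.pruned(panel.reference))
            labels = tolm.classify_profile_set(ps, idx, include_reference=False)
        else:
            idx = tolm.enumerate_clades(tree)
            labels = tolm.classify_profile_set(ps, idx)
        log.event(
            "tol",
            nontrivial_clades=idx.nontrivial_count,
            counts=labels["status"].value_counts().to_dict(),
        )
        return tree, idx, labels

    tree, idx, tol_labels = stage("tol")(_tol)
    tol_labels.to_csv(out / "tol_labels.csv", index=False)

    status = tol_labels.set_index("protein_id")["status"]
    universal_ids = set(status.index[status == "UNIVERSAL"])
    nonuniv_ids = set(status.index) - universal_ids
    consistent_ids = {
        p
        for p in nonuniv_ids
        if status[p]
        in ("CONSISTENT_PRESENCE_CLADE", "CONSISTENT_ABSENCE_CLADE")
    }
    if not cfg.include_orphans:
        orphan_ids = {
            pid for pid, row in zip(ps.protein_ids, ps.matrix) if row.sum() == 0
        }
        consistent_ids -= orphan_ids
    inconsistent_ids = nonuniv_ids - consistent_ids

    # --- quantum clustering on the consistent non-universal set -------
    def _cluster():
        # all-zero (orphan) profiles cannot be placed on the unit sphere
        # and are always excluded from the clustering stage
        clusterable = sorted(
            p for p in consistent_ids if ps[p].sum() > 0
        )
        sub = ps.subset(clusterable)
        sigma = cfg.sigma if cfg.sigma is not None else (
            "auto",
            cfg.k_target,
            cfg.sigma_grid,
        )
        model = qcm.QuantumClustering(
            sigma=sigma,
            d=min(cfg.d, len(sub.pattern_index), panel.k),
            max_iter=cfg.max_iter,
            merge_tol=cfg.merge_tol,
            seed=cfg.seed,
        ).fit(sub)
        log.event(
            "cluster",
            n_clusters=model.n_clusters_,
            sigma=model.sigma_,
            variance_explained=round(model.embedding_.variance_explained, 4),
        )
        return model

    model = stage("cluster")(_cluster) if consistent_ids else None
    if model is not None:
        assign = model.labels_.rename_axis("protein_id").reset_index()
        assign["pattern"] = [
            "".join(map(str, ps[p])) for p in assign["protein_id"]
        ]
        assign[["protein_id", "pattern", "cluster"]].to_csv(
            out / "cluster_assignments.csv", index=False
        )
        model.stats_frame().to_csv(out / "cluster_stats.csv", index=False)

    # --- enrichment ---------------------------------------------------
    def _enrich():
        dag = enr.load_ontology(cfg.obo)
        ann = enr.propagate(enr.read_annotations(cfg.annotations), dag, on_unknown="skip")
        all_ids = set(ps.protein_ids)
        comparisons = {
            "universal_vs_all": (universal_ids, all_ids),
            "nonuniversal_vs_all": (nonuniv_ids, all_ids),
            "consistent_vs_nonuniversal": (consistent_ids, nonuniv_ids),
            "inconsistent_vs_nonuniversal": (inconsistent_ids, nonuniv_ids),
        }
        if model is not None:
            for cid in sorted(model.labels_.unique()):
                members = set(model.labels_.index[model.labels_ == cid])
                comparisons[f"cluster_{cid}_vs_consistent"] = (
                    members,
                    consistent_ids,
                )
        results = {}
        for name, (target, background) in comparisons.items():
            if not target:
                results[name] = []
                enr.results_frame([]).to_csv(out / f"enrichment_{name}.csv", index=False)
                continue
            res = enr.enrich_two_list(
                target, background, ann, dag=dag, max_p=cfg.p_report
            )
            results[name] = res
            enr.results_frame(res).to_csv(out / f"enrichment_{name}.csv", index=False)
        log.event(
            "enrich",
            tables={k: len(v) for k, v in results.items()},
            p_report=cfg.p_report,
        )
        return results

    results = stage("enrich")(_enrich)

    return {
        "profiles": ps,
        "class_table": table,
        "subset_tables": subset_tables,
        "tree": tree,
        "clade_index": idx,
        "tol_labels": tol_labels,
        "qc": model,
        "enrichment": results,
        "outdir": out,
    }


def render_p(p: float, none_above: float = 1e-2) -> str:
    """Scientific-notation p-value, or ``None`` above the display cutoff."""
    return "None" if p > none_above else f"{p:.2E}"


def fourway_table(
    resA_universal,
    resA_nonuniversal,
    resB_universal,
    resB_nonuniversal,
    labels: tuple[str, str] = ("A", "B"),
    none_above: float = 1e-2,
) -> pd.DataFrame:
    """Term-by-term p-values across two references' universal/non-universal sets.

    Rows are the union of reported terms; entries with p above
    ``none_above`` render as ``"None"`` (no meaningful enrichment).
    """
    cols = {
        f"{labels[0]} universal": resA_universal,
        f"{labels[0]} non-universal": resA_nonuniversal,
        f"{labels[1]} universal": resB_universal,
        f"{labels[1]} non-universal": resB_nonuniversal,
    }
    terms: dict[str, str] = {}
    for res in cols.values():
        for r in res:
            terms.setdefault(r.term, r.name)
    rows = []
    for term in sorted(terms):
        row = {"term": term, "name": terms[term]}
        for col, res in cols.items():
            hit = next((r for r in res if r.term == term), None)
            row[col] = render_p(hit.p_value, none_above) if hit else "None"
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["term", "name", *cols.keys()]
    )
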