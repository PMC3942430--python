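"""Two-list GO enrichment with true-path propagation.

A term is over-represented in a *target* list of proteins relative to a
*background* list if the hypergeometric upper-tail probability

    p = sum_{j >= b} C(B, j) C(N - B, n - j) / C(N, n)

is small, where N is the background size, B the background proteins
annotated with the term (after propagating annotations to all is_a
ancestors — the true-path rule), n the target size, and b the annotated
target proteins.  Raw p-values are reported against fixed cutoffs; no
multiple-testing correction is applied by default, with an optional
Benjamini-Hochberg column for users who want one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "GoDag",
    "AnnotationMap",
    "EnrichmentResult",
    "load_ontology",
    "propagate",
    "enrich_two_list",
    "results_frame",
    "intersect_enriched",
]

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


class GoDag:
    """An is_a DAG of ontology terms with names and namespaces."""

    def __init__(
        self,
        parents: Mapping[str, frozenset[str]],
        names: Mapping[str, str],
        namespaces: Mapping[str, str],
        alt_ids: Mapping[str, str] | None = None,
    ) -> None:
        self.parents = {t: frozenset(p) for t, p in parents.items()}
        for t, ps in self.parents.items():
            unknown = ps - self.parents.keys()
            if unknown:
                raise ValueError(f"term {t} has unknown parents {sorted(unknown)}")
        self.names = dict(names)
        self.namespaces = dict(namespaces)
        self.alt_ids = dict(alt_ids or {})
        g = nx.DiGraph(
            (t, p) for t, ps in self.parents.items() for p in ps
        )
        g.add_nodes_from(self.parents)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle: {cycle}")
        self._graph = g
        self._ancestors: dict[str, frozenset[str]] = {}

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def __len__(self) -> int:
        return len(self.parents)

    def resolve(self, term: str) -> str | None:
        """Map a (possibly alternative) ID to its primary term ID."""
        if term in self.parents:
            return term
        return self.alt_ids.get(term)

    def ancestors(self, term: str) -> frozenset[str]:
        """All is_a ancestors of a term, the term itself included."""
        cached = self._ancestors.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self._graph, term)) | {term}
            self._ancestors[term] = cached
        return cached

    def terms_in_namespace(self, namespace: str | None) -> set[str]:
        if namespace is None:
            return set(self.parents)
        return {t for t, ns in self.namespaces.items() if ns == namespace}


def load_ontology(path) -> GoDag:
    """Load an OBO 1.2 ontology into a :class:`GoDag`.

    Obsolete terms are skipped (obonet drops them; the skipped count is
    not recoverable from the graph and is not needed downstream), and
    alternative IDs resolve to their primary term.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    parents: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    alt: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        is_a = frozenset(
            v for _, v, key in graph.out_edges(term, keys=True) if key == "is_a"
        )
        parents[term] = is_a
        names[term] = data.get("name", term)
        namespaces[term] = data.get("namespace", "biological_process")
        for a in data.get("alt_id", []):
            alt[a] = term
    # drop is_a edges to terms outside the loaded set (e.g. other ontologies)
    parents = {t: ps & parents.keys() for t, ps in parents.items()}
    return GoDag(parents, names, namespaces, alt)


@dataclass
class AnnotationMap:
    """Direct and ancestor-propagated protein-to-term assignments."""

    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]]

    def terms_of(self, protein: str) -> frozenset[str]:
        return self.propagated.get(protein, frozenset())


def read_annotations(path) -> dict[str, set[str]]:
    """Read a two-column (protein_id, term) TSV of direct annotations."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("!"):
                continue
            protein, term = line.split("\t")[:2]
            out.setdefault(protein, set()).add(term)
    return out


def propagate(
    direct: Mapping[str, Iterable[str]],
    dag: GoDag,
    *,
    on_unknown: str = "error",
) -> AnnotationMap:
    """Close direct annotations under the true-path rule.

    Every protein annotated with a term is implicitly annotated with all
    of the term's is_a ancestors.  Unknown terms either raise or are
    skipped with ``on_unknown="skip"``.
    """
    if on_unknown not in ("error", "skip"):
        raise ValueError("on_unknown must be 'error' or 'skip'")
    direct_out: dict[str, frozenset[str]] = {}
    prop: dict[str, frozenset[str]] = {}
    for protein, terms in direct.items():
        resolved = []
        for t in terms:
            primary = dag.resolve(t)
            if primary is None:
                if on_unknown == "error":
                    raise KeyError(f"unknown ontology term {t!r}")
                continue
            resolved.append(primary)
        direct_out[protein] = frozenset(resolved)
        closure: set[str] = set()
        for t in resolved:
            closure |= dag.ancestors(t)
        prop[protein] = frozenset(closure)
    return AnnotationMap(direct=direct_out, propagated=prop)


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of one term in a target vs a background."""

    term: str
    name: str
    namespace: str
    N: int
    B: int
    n: int
    b: int
    enrichment: float
    p_value: float

    def __post_init__(self) -> None:
        if self.b > min(self.n, self.B):
            raise ValueError("b cannot exceed min(n, B)")


def hypergeom_tail(N: int, B: int, n: int, b: int) -> float:
    """P(X >= b) for X ~ Hypergeometric(N, B, n); equals 1 when b = 0."""
    if b == 0:
        return 1.0
    return float(hypergeom.sf(b - 1, N, B, n))


def enrich_two_list(
    target: Iterable[str],
    background: Iterable[str],
    ann: AnnotationMap,
    namespace: str | None = None,
    *,
    dag: GoDag | None = None,
    max_p: float = 1.0,
    significant_p: float = 1e-5,
    drop_unannotated: bool = False,
) -> list[EnrichmentResult]:
    """Two-list enrichment of every annotated term, sorted by p-value.

    Proteins without any annotation still count in N and n by default —
    they dilute enrichment, matching how list-based GO tools treat
    unannotated genes; ``drop_unannotated`` restricts both lists to
    annotated proteins.  ``max_p`` filters the report (terms with
    p-value above it are omitted); ``significant_p`` only sets the
    conventional significance cutoff recorded by downstream tables.
    """
    target = set(target)
    background = set(background)
    if not target or not background:
        raise ValueError("target and background must be non-empty")
    if not target <= background:
        raise ValueError("target list must be a subset of the background list")
    if drop_unannotated:
        background = {p for p in background if ann.terms_of(p)}
        target = {p for p in target if ann.terms_of(p)}
        if not target or not background:
            raise ValueError("no annotated proteins left after filtering")
    N, n = len(background), len(target)
    term_bg: dict[str, int] = {}
    term_tg: dict[str, int] = {}
    for p in background:
        in_target = p in target
        for t in ann.terms_of(p):
            term_bg[t] = term_bg.get(t, 0) + 1
            if in_target:
                term_tg[t] = term_tg.get(t, 0) + 1
    results: list[EnrichmentResult] = []
    for term, B in term_bg.items():
        if dag is not None and namespace is not None:
            if dag.namespaces.get(term) != namespace:
                continue
        b = term_tg.get(term, 0)
        p = hypergeom_tail(N, B, n, b)
        if p > max_p:
            continue
        results.append(
            EnrichmentResult(
                term=term,
                name=dag.names.get(term, term) if dag else term,
                namespace=dag.namespaces.get(term, "") if dag else "",
                N=N,
                B=B,
                n=n,
                b=b,
                enrichment=(b / n) / (B / N),
                p_value=p,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def results_frame(
    results: Iterable[EnrichmentResult], *, bh_column: bool = False
) -> pd.DataFrame:
    """Tabulate enrichment results (optionally with a BH-adjusted column)."""
    cols = ["term", "name", "namespace", "N", "B", "n", "b", "enrichment", "p_value"]
    df = pd.DataFrame([vars(r) for r in results], columns=cols)
    if bh_column and len(df):
        m = len(df)
        order = df["p_value"].rank(method="first").astype(int)
        bh = df["p_value"] * m / order
        # enforce monotonicity from the largest p downwards
        df["p_bh"] = bh.iloc[::-1].cummin().iloc[::-1].clip(upper=1.0)
    return df


def intersect_enriched(
    resA: Iterable[EnrichmentResult],
    resB: Iterable[EnrichmentResult],
    threshold: float,
) -> dict[str, tuple[int, int, int]]:
    """Venn counts (only-A, shared, only-B) of enriched terms per namespace."""
    def passing(res) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for r in res:
            if r.p_value <= threshold:
                out.setdefault(r.namespace, set()).add(r.term)
        return out

    a, b = passing(resA), passing(resB)
    out: dict[str, tuple[int, int, int]] = {}
    for ns in sorted(set(a) | set(b)):
        sa, sb = a.get(ns, set()), b.get(ns, set())
        out[ns] = (len(sa - sb), len(sa & sb), len(sb - sa))
    return out
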