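"""Binary conservation profiles from tabular homology hit lists.

A conservation profile of a reference protein is a binary vector over a
target species panel: bit ``j`` is 1 iff at least one homologue of the
protein was detected in ``panel.targets[j]`` (regardless of score).
Proteins with i ones belong to conservation class ``H_i``; class ``H_k``
(all ones) holds the *universal* proteins, class ``H_0`` the *orphans*.

Input is BLAST tabular output (``-outfmt 6``: twelve tab-separated
columns).  Hit generation itself (running BLASTP) is out of scope; these
tables are consumed, not produced.  Tables generated with lenient
defaults (E <= 10, maximum alignments retained) reproduce the intended
"homologue present at any score" semantics.
"""

from __future__ import annotations

import logging
from collections.abc import Callable, Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import SpeciesPanel

logger = logging.getLogger(__name__)

__all__ = [
    "HitRecord",
    "ProfileSet",
    "ClassTable",
    "read_hit_table",
    "read_roster",
    "best_hits",
    "build_profiles",
    "assign_class",
    "class_distribution",
    "crosstab_subset",
]


@dataclass(frozen=True)
class HitRecord:
    """One homology hit: a reference protein matching a subject protein."""

    query_id: str
    subject_species: str
    subject_id: str
    bit_score: float
    e_value: float


def _prefix_resolver(subject_id: str) -> str:
    """Default species resolution: the token before the first ``|``."""
    return subject_id.split("|", 1)[0]


def read_hit_table(
    path,
    panel: SpeciesPanel,
    species_map: Mapping[str, str] | Callable[[str], str] | None = None,
    *,
    species_column: bool = False,
    skip_unknown: bool = False,
) -> list[HitRecord]:
    """Parse a 12-column BLAST tabular file into :class:`HitRecord` rows.

    BLAST tabular output carries no taxon labels, so the subject species
    must be recovered from the subject ID.  Three conventions are
    supported:

    * ``species_column=True`` — a 13th column holds the species name;
    * ``species_map`` — a mapping (or callable) from subject ID (full ID
      first, then the ``|``-prefix) to a species name;
    * neither — the token before the first ``|`` in the subject ID *is*
      the species name.

    Rows that resolve to a species outside the target panel are dropped
    (their count is logged).  Rows whose species cannot be resolved at
    all raise, unless ``skip_unknown`` is set.
    """
    records: list[HitRecord] = []
    n_dropped = 0
    n_cols = 13 if species_column else 12
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < n_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols} tab-separated "
                    f"columns, got {len(fields)}"
                )
            query_id, subject_id = fields[0], fields[1]
            try:
                e_value = float(fields[10])
                bit_score = float(fields[11])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed numeric field ({exc})"
                ) from None
            if species_column:
                species: str | None = fields[12]
            elif species_map is not None:
                if callable(species_map):
                    species = species_map(subject_id)
                else:
                    species = species_map.get(
                        subject_id, species_map.get(_prefix_resolver(subject_id))
                    )
            else:
                prefix = _prefix_resolver(subject_id)
                species = prefix if prefix in panel.all_species else None
            if species is None:
                if skip_unknown:
                    n_dropped += 1
                    continue
                raise ValueError(
                    f"{path}:{lineno}: cannot resolve species of subject "
                    f"{subject_id!r} (pass species_map or skip_unknown=True)"
                )
            if species not in panel.targets:
                n_dropped += 1
                continue
            records.append(
                HitRecord(
                    query_id=query_id,
                    subject_species=species,
                    subject_id=subject_id,
                    bit_score=bit_score,
                    e_value=e_value,
                )
            )
    if n_dropped:
        logger.info("read_hit_table: dropped %d out-of-panel rows", n_dropped)
    return records


def read_roster(path) -> list[str]:
    """Read a one-ID-per-line roster of query protein IDs."""
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if len(set(ids)) != len(ids):
        raise ValueError("roster contains duplicate protein IDs")
    return ids


def best_hits(
    hits: Iterable[HitRecord],
) -> dict[tuple[str, str], HitRecord]:
    """Keep, per (query, species), the hit with the highest bit score.

    Ties are broken by first occurrence in file order; profile presence
    is unaffected by the tie-break since only existence matters.
    """
    best: dict[tuple[str, str], HitRecord] = {}
    for rec in hits:
        key = (rec.query_id, rec.subject_species)
        cur = best.get(key)
        if cur is None or rec.bit_score > cur.bit_score:
            best[key] = rec
    return best


class ProfileSet:
    """A protein-by-species binary matrix with pattern multiplicities.

    The central container of the analysis: rows are reference proteins,
    columns the panel's target species in panel order.  Identical rows
    ("patterns") are tracked with their multiplicity because downstream
    clustering weights unique patterns by how many proteins share them.
    """

    def __init__(
        self,
        protein_ids: Sequence[str],
        matrix: np.ndarray,
        panel: SpeciesPanel,
    ) -> None:
        matrix = np.asarray(matrix, dtype=np.uint8)
        if matrix.ndim != 2 or matrix.shape != (len(protein_ids), panel.k):
            raise ValueError(
                f"matrix shape {matrix.shape} does not match "
                f"{len(protein_ids)} proteins x {panel.k} targets"
            )
        if not np.isin(matrix, (0, 1)).all():
            raise ValueError("profile matrix must be binary")
        if len(set(protein_ids)) != len(protein_ids):
            raise ValueError("duplicate protein IDs")
        self.protein_ids = list(protein_ids)
        self.matrix = matrix
        self.panel = panel
        self._id_index = {p: i for i, p in enumerate(self.protein_ids)}

    def __len__(self) -> int:
        return len(self.protein_ids)

    def __getitem__(self, protein_id: str) -> np.ndarray:
        return self.matrix[self._id_index[protein_id]]

    @property
    def pattern_index(self) -> dict[tuple[int, ...], list[str]]:
        """Unique pattern -> IDs of the proteins sharing it (file order)."""
        idx: dict[tuple[int, ...], list[str]] = {}
        for pid, row in zip(self.protein_ids, self.matrix):
            idx.setdefault(tuple(int(b) for b in row), []).append(pid)
        return idx

    def unique_patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """(patterns, multiplicities) in order of first occurrence."""
        idx = self.pattern_index
        pats = np.array(list(idx.keys()), dtype=np.uint8)
        mult = np.array([len(v) for v in idx.values()], dtype=np.int64)
        return pats, mult

    def classes(self) -> np.ndarray:
        """Conservation class H_i (= row popcount) for every protein."""
        return self.matrix.sum(axis=1).astype(np.int64)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=list(self.panel.targets))
        df.insert(0, "protein_id", self.protein_ids)
        return df

    def to_csv(self, path) -> None:
        """Write the profile matrix (protein_id + one 0/1 column per species)."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, panel: SpeciesPanel) -> "ProfileSet":
        df = pd.read_csv(path, dtype={"protein_id": str})
        missing = set(panel.targets) - set(df.columns)
        if missing:
            raise ValueError(f"profile CSV lacks species columns: {sorted(missing)}")
        matrix = df[list(panel.targets)].to_numpy()
        return cls(df["protein_id"].tolist(), matrix, panel)

    def subset(self, protein_ids: Sequence[str]) -> "ProfileSet":
        rows = [self._id_index[p] for p in protein_ids]
        return ProfileSet(list(protein_ids), self.matrix[rows], self.panel)


def build_profiles(
    best: Mapping[tuple[str, str], HitRecord],
    all_query_ids: Sequence[str],
    panel: SpeciesPanel,
) -> ProfileSet:
    """Binary profiles from best hits, over an explicit query roster.

    The roster is required so that proteins with no hit at all still get
    an (all-zero, orphan) profile: absence of rows in the hit table must
    be distinguishable from absence of the protein.
    """
    roster = set(all_query_ids)
    stray = {q for (q, _s) in best if q not in roster}
    if stray:
        raise ValueError(
            f"{len(stray)} query IDs in hits are missing from the roster, "
            f"e.g. {sorted(stray)[:3]}"
        )
    matrix = np.zeros((len(all_query_ids), panel.k), dtype=np.uint8)
    col = {s: j for j, s in enumerate(panel.targets)}
    row = {q: i for i, q in enumerate(all_query_ids)}
    for (q, s) in best:
        matrix[row[q], col[s]] = 1
    return ProfileSet(list(all_query_ids), matrix, panel)


def assign_class(bits: Sequence[int] | np.ndarray) -> int:
    """Conservation class H_i of a profile: its number of 1-bits."""
    arr = np.asarray(bits)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("profile must be binary")
    return int(arr.sum())


@dataclass
class ClassTable:
    """Counts and percentages of proteins per conservation class H_i.

    ``counts[i]`` is the number of proteins with homologues in exactly
    ``i`` target species, for i = 0..k.
    """

    counts: np.ndarray
    decimals: int = 2
    n_missing_subset_ids: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or (self.counts < 0).any():
            raise ValueError("counts must be a 1-D nonnegative vector")

    @classmethod
    def from_counts(
        cls, counts: Mapping[int, int] | Sequence[int], k: int | None = None
    ) -> "ClassTable":
        """Build from a {class: count} mapping or a dense count vector."""
        if isinstance(counts, Mapping):
            if k is None:
                k = max(counts)
            dense = np.zeros(k + 1, dtype=np.int64)
            for i, c in counts.items():
                dense[i] = c
            return cls(dense)
        return cls(np.asarray(counts, dtype=np.int64))

    @property
    def k(self) -> int:
        return len(self.counts) - 1

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def universal_count(self) -> int:
        """Proteins in class H_k (homologues in every target species)."""
        return int(self.counts[-1])

    @property
    def orphan_count(self) -> int:
        return int(self.counts[0])

    @property
    def non_universal_count(self) -> int:
        return self.total - self.universal_count

    def percent(self, i: int) -> float:
        """Percentage of class H_i, rounded to ``decimals`` places."""
        return float(np.round(100.0 * self.counts[i] / self.total, self.decimals))

    def percents(self) -> np.ndarray:
        return np.round(100.0 * self.counts / self.total, self.decimals)

    def to_frame(self) -> pd.DataFrame:
        """Table with classes in descending order (universal first)."""
        order = np.arange(self.k, -1, -1)
        return pd.DataFrame(
            {
                "class": order,
                "count": self.counts[order],
                "percent": self.percents()[order],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def class_distribution(ps: ProfileSet, decimals: int = 2) -> ClassTable:
    """Distribution of proteins over conservation classes H_0..H_k."""
    if len(ps) == 0:
        raise ValueError("empty ProfileSet")
    counts = np.bincount(ps.classes(), minlength=ps.panel.k + 1)
    return ClassTable(counts, decimals=decimals)


def crosstab_subset(
    ps: ProfileSet, subset_ids: Iterable[str], decimals: int = 0
) -> ClassTable:
    """Class distribution restricted to a subset of proteins.

    IDs absent from the profile set are dropped (their count is recorded
    on the result and logged).  Percentages are relative to the subset
    size; the default integer rounding matches essential-gene style
    summary tables.
    """
    subset = list(dict.fromkeys(subset_ids))
    present = [p for p in subset if p in ps._id_index]
    n_missing = len(subset) - len(present)
    if n_missing:
        logger.warning("crosstab_subset: %d subset IDs not in profile set", n_missing)
    if not present:
        raise ValueError("no subset IDs present in the profile set")
    table = class_distribution(ps.subset(present), decimals=decimals)
    table.n_missing_subset_ids = n_missing
    return table
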