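"""Gene participation counts, pairwise pathway overlaps and group summaries.

Once the network entries are fixed, each query gene's involvement is the
number of entries whose gene sets contain it (its participation count);
convergence between two entries is read off the genes they share; and
entries are summarized by a user-supplied grouping scheme (class:
function vs disease; group: e.g. cell signaling, cancer).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .geneset_io import QueryGeneList
from .redundancy import Entry


class AnnotationError(ValueError):
    """Invalid annotation input."""


@dataclass
class MembershipMatrix:
    """Boolean gene x entry membership (query gene in entry's union genes).

    Thin wrapper over a pandas DataFrame with genes as the index and entry
    names as columns; column sums are the per-entry query-gene counts.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise AnnotationError("membership matrix has duplicate gene or entry names")
        self.data = self.data.astype(bool)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def entries(self) -> list[str]:
        return list(self.data.columns)

    def entry_gene_counts(self) -> pd.Series:
        return self.data.sum(axis=0).astype(int)


def membership_from_entries(query: QueryGeneList, entries: Sequence[Entry]) -> MembershipMatrix:
    """Tabulate which query genes fall in which entry's union gene set."""
    data = pd.DataFrame(
        {e.name: [g in e.union_genes for g in query.symbols] for e in entries},
        index=list(query.symbols),
    )
    return MembershipMatrix(data=data)


def read_membership_tsv(path: str | Path) -> MembershipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return MembershipMatrix(data=df.astype(int).astype(bool))


def write_membership_tsv(matrix: MembershipMatrix, path: str | Path) -> Path:
    path = Path(path)
    matrix.data.astype(int).to_csv(path, sep="\t")
    return path


@dataclass
class ParticipationTable:
    """Per-gene pathway-participation counts with a display view.

    ``counts`` covers every gene in the matrix; ``display`` keeps genes
    with count strictly greater than ``display_min``, sorted by count
    descending then gene name.
    """

    counts: pd.Series
    display_min: int

    @property
    def display(self) -> pd.Series:
        view = self.counts[self.counts > self.display_min]
        order = sorted(view.index, key=lambda g: (-view[g], g))
        return view.loc[order]


def gene_participation(matrix: MembershipMatrix, display_min: int = 4) -> ParticipationTable:
    """Count, for each gene, the entries containing it."""
    if matrix.data.empty:
        raise AnnotationError("membership matrix is empty")
    counts = matrix.data.sum(axis=1).astype(int)
    order = sorted(counts.index, key=lambda g: (-counts[g], g))
    return ParticipationTable(counts=counts.loc[order], display_min=display_min)


def pairwise_overlap_genes(entry_a: str, entry_b: str, matrix: MembershipMatrix) -> frozenset[str]:
    """Query genes shared by two entries (symmetric; A vs A is A's column)."""
    for name in (entry_a, entry_b):
        if name not in matrix.data.columns:
            raise AnnotationError(f"unknown entry {name!r}")
    both = matrix.data[entry_a] & matrix.data[entry_b]
    return frozenset(matrix.data.index[both])


def entity_participation(
    entity_map: Mapping[str, Iterable[str]], entries: Sequence[str]
) -> tuple[dict[str, int], list[str]]:
    """Count, per entity (e.g. a compound like Ca2+), how many of the given
    entries its annotation names.  Entity annotations naming unknown
    entries are dropped; the dropped names are returned as warnings."""
    known = set(entries)
    counts: dict[str, int] = {}
    warnings: list[str] = []
    for entity, names in entity_map.items():
        hits = set()
        for nm in names:
            if nm in known:
                hits.add(nm)
            else:
                warnings.append(f"entity {entity!r}: unknown entry {nm!r} dropped")
        counts[entity] = len(hits)
    return counts, warnings


@dataclass(frozen=True)
class GroupAssignment:
    klass: str                  # "function" or "disease"
    group: str
    subgroup: str = ""


@dataclass
class GroupingScheme:
    """Per-entry class/group/subgroup assignment (data, not code)."""

    assignments: dict[str, GroupAssignment] = field(default_factory=dict)

    def __getitem__(self, name: str) -> GroupAssignment:
        return self.assignments[name]

    def __contains__(self, name: str) -> bool:
        return name in self.assignments


def _percent(count: int, total: int) -> float:
    """Percentage with one decimal place, half-up (prints 22.5 for 9/40)."""
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class GroupSummary:
    total: int
    class_counts: dict[str, int]
    class_percent: dict[str, float]
    group_counts: dict[tuple[str, str], int]
    group_percent: dict[tuple[str, str], float]


def classify_and_summarize(entries: Sequence[str], scheme: GroupingScheme) -> GroupSummary:
    """Count entries per class and per (class, group), with percentages of
    the total.  Every entry must be covered by the scheme."""
    uncovered = [e for e in entries if e not in scheme]
    if uncovered:
        raise AnnotationError(f"entries missing from grouping scheme: {uncovered}")
    total = len(entries)
    if total == 0:
        raise AnnotationError("no entries to summarize")
    class_counts: dict[str, int] = {}
    group_counts: dict[tuple[str, str], int] = {}
    for e in entries:
        a = scheme[e]
        class_counts[a.klass] = class_counts.get(a.klass, 0) + 1
        key = (a.klass, a.group)
        group_counts[key] = group_counts.get(key, 0) + 1
    return GroupSummary(
        total=total,
        class_counts=class_counts,
        class_percent={c: _percent(n, total) for c, n in class_counts.items()},
        group_counts=group_counts,
        group_percent={g: _percent(n, total) for g, n in group_counts.items()},
    )


def read_grouping_scheme(path: str | Path) -> GroupingScheme:
    """Read a grouping scheme TSV with columns entry, class, group and
    optional subgroup."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"entry", "class", "group"}
    if not required.issubset(df.columns):
        raise AnnotationError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    assignments = {}
    for _, row in df.iterrows():
        assignments[row["entry"]] = GroupAssignment(
            klass=row["class"],
            group=row["group"],
            subgroup=row["subgroup"] if "subgroup" in df.columns else "",
        )
    return GroupingScheme(assignments=assignments)


def write_group_summary_tsv(summary: GroupSummary, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("level\tclass\tgroup\tcount\tpercent\n")
        for klass in sorted(summary.class_counts):
            fh.write(
                f"class\t{klass}\t\t{summary.class_counts[klass]}\t{summary.class_percent[klass]}\n"
            )
        for (klass, group) in sorted(summary.group_counts):
            fh.write(
                f"group\t{klass}\t{group}\t{summary.group_counts[(klass, group)]}\t"
                f"{summary.group_percent[(klass, group)]}\n"
            )
    return path


def write_participation_tsv(table: ParticipationTable, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene\tn_pathways\n")
        for gene, count in table.counts.items():
            fh.write(f"{gene}\t{count}\n")
    return path
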