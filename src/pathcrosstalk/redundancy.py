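"""Redundancy control: merge highly overlapping enriched pathways.

Curated pathway databases name many near-duplicate gene sets (e.g. a
dozen cancer pathways sharing most of their genes).  Left in place these
inflate network statistics, so pairs whose membership overlap exceeds a
Max/Min threshold pair are linked and the connected components of the
link graph are collapsed into single "collections".  A collection's
p-value is that of its dominant (lowest-p) member.

The pairwise link rule: with r_A = |A∩B|/|A| and r_B = |A∩B|/|B|, the
pair is linked when max(r_A, r_B) >= max_threshold and
min(r_A, r_B) >= min_threshold.  Merging is transitive via connected
components, which makes the result independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import networkx as nx

from .enrichment import EnrichmentTable
from .geneset_io import GeneSet, GeneSetCollection


class RedundancyError(ValueError):
    """Invalid redundancy-merge parameters or inputs."""


@dataclass(frozen=True)
class RedundancyParams:
    max_threshold: float = 0.85
    min_threshold: float = 0.10

    def __post_init__(self) -> None:
        for name, v in (("max", self.max_threshold), ("min", self.min_threshold)):
            if not 0.0 <= v <= 1.0:
                raise RedundancyError(f"{name}_threshold must lie in [0, 1], got {v}")
        if self.min_threshold > self.max_threshold:
            raise RedundancyError(
                f"min_threshold {self.min_threshold} exceeds max_threshold {self.max_threshold}"
            )


@dataclass(frozen=True)
class PathwayEntry:
    """A pathway that survived redundancy control unmerged."""

    name: str
    union_genes: frozenset[str]
    p_value: float

    @property
    def members(self) -> tuple[str, ...]:
        return (self.name,)

    @property
    def is_collection(self) -> bool:
        return False


@dataclass(frozen=True)
class MergedCollection:
    """Two or more pathways collapsed into one entry.

    ``p_value`` is the dominant member's (the minimum over members) and
    ``union_genes`` the union of member gene sets.
    """

    name: str
    members: tuple[str, ...]
    union_genes: frozenset[str]
    dominant_member: str
    p_value: float

    @property
    def is_collection(self) -> bool:
        return True


Entry = Union[PathwayEntry, MergedCollection]


def overlap_ratios(A: GeneSet, B: GeneSet) -> tuple[float, float]:
    """Overlap of two gene sets as a fraction of each: (|A∩B|/|A|, |A∩B|/|B|)."""
    if len(A) == 0 or len(B) == 0:
        raise RedundancyError("overlap ratio of an empty gene set is undefined")
    shared = len(A.members & B.members)
    return shared / len(A), shared / len(B)


def collection_stats(
    members: Sequence[tuple[str, float, GeneSet]], name: str | None = None
) -> MergedCollection:
    """Summarize a member list into a :class:`MergedCollection`.

    Dominant member = argmin p (ties by name); the collection's p-value is
    the dominant's; union_genes is the union of member sets.  The default
    name is ``"collection: "`` + the alphabetically first member.
    """
    if not members:
        raise RedundancyError("collection requires at least one member")
    ordered = sorted(members, key=lambda t: t[0])
    dominant = min(ordered, key=lambda t: (t[1], t[0]))
    union: set[str] = set()
    for _, _, gs in ordered:
        union |= gs.members
    return MergedCollection(
        name=name if name is not None else f"collection: {ordered[0][0]}",
        members=tuple(t[0] for t in ordered),
        union_genes=frozenset(union),
        dominant_member=dominant[0],
        p_value=dominant[1],
    )


def reduce_redundancy(
    table: EnrichmentTable,
    sets: GeneSetCollection,
    params: RedundancyParams = RedundancyParams(),
    collection_names: Mapping[frozenset, str] | None = None,
) -> list[Entry]:
    """Collapse redundant pathways in an enrichment table into collections.

    Every table row must have its gene set in ``sets``.  Pairs passing the
    Max/Min link rule are joined; connected components with >= 2 members
    become :class:`MergedCollection` entries, singletons pass through as
    :class:`PathwayEntry`.  Linking is repeated on the merged unions until
    a fixpoint, so re-running on the output makes no further merges.
    Output is sorted by entry p-value ascending,
    ties by name.  ``collection_names`` optionally maps a frozenset of
    member names to a display name (the study hand-named its collections,
    e.g. "collection cancer").
    """
    missing = [r.set_name for r in table.rows if r.set_name not in sets]
    if missing:
        raise RedundancyError(f"table rows without gene sets: {missing}")
    p_by_name = {r.set_name: r.p_value for r in table.rows}

    # iterate to a fixpoint: merged unions may newly exceed the thresholds
    # against other entries, so linking is repeated on the grouped unions
    # until no component grows (this makes the operation idempotent)
    groups: list[list[str]] = [[r.set_name] for r in table.rows]
    while True:
        unions = [
            frozenset().union(*(sets[m].members for m in g)) for g in groups
        ]
        link = nx.Graph()
        link.add_nodes_from(range(len(groups)))
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                shared = len(unions[i] & unions[j])
                rA = shared / len(unions[i])
                rB = shared / len(unions[j])
                if max(rA, rB) >= params.max_threshold and min(rA, rB) >= params.min_threshold:
                    link.add_edge(i, j)
        components = list(nx.connected_components(link))
        if len(components) == len(groups):
            break
        groups = sorted(
            (sorted(m for idx in comp for m in groups[idx]) for comp in components),
            key=lambda g: g[0],
        )

    entries: list[Entry] = []
    for names in groups:
        if len(names) == 1:
            nm = names[0]
            entries.append(
                PathwayEntry(
                    name=nm, union_genes=sets[nm].members, p_value=p_by_name[nm]
                )
            )
        else:
            override = None
            if collection_names:
                override = collection_names.get(frozenset(names))
            entries.append(
                collection_stats(
                    [(nm, p_by_name[nm], sets[nm]) for nm in names], name=override
                )
            )
    entries.sort(key=lambda e: (e.p_value, e.name))
    return entries


def entries_as_collection(
    entries: Sequence[Entry], collection_name: str = "merged"
) -> GeneSetCollection:
    """View merged entries as a plain gene-set collection (entry -> union
    genes), e.g. to re-run redundancy control on its own output."""
    return GeneSetCollection(
        collection_name=collection_name,
        sets=[
            GeneSet(name=e.name, description="", members=e.union_genes)
            for e in entries
        ],
    )


def write_entries_tsv(entries: Sequence[Entry], path: str | Path) -> Path:
    """Write merged entries as TSV: name, type, members, p-value, gene count."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("name\ttype\tmembers\tp_value\tn_genes\n")
        for e in entries:
            kind = "collection" if e.is_collection else "pathway"
            fh.write(
                f"{e.name}\t{kind}\t{';'.join(e.members)}\t{e.p_value:.6g}\t{len(e.union_genes)}\n"
            )
    return path
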