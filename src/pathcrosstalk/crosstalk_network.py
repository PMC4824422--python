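"""Pathway crosstalk network: build, degree statistics, hub ranking, export.

KEGG draws the name of an interacting pathway inside a pathway's map;
each such embedded cross-reference is evidence the two pathways
functionally interact.  Tabulating these references over a fixed entry
list yields an undirected pathway-pathway network.  Rules:

* a reference in either direction creates one undirected edge;
* repeated references between the same pair collapse to one edge;
* a pathway referencing any member of a merged collection interacts with
  the collection; references among members of one collection are internal
  and create no edge;
* references whose context is ``listed_only`` (a pathway name merely
  listed in a map, e.g. the cancer subtypes at the foot of "Pathways in
  cancer") are excluded, as are explicitly excluded (source, displayed)
  pairs;
* references to pathways outside the entry list are dropped — the network
  is defined only over the enriched entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .redundancy import Entry

EMBEDDED = "embedded"
LISTED_ONLY = "listed_only"


class NetworkError(ValueError):
    """Invalid crosstalk-network input."""


@dataclass(frozen=True)
class CrossRefRecord:
    """One pathway-map cross-reference: ``displayed_pathway`` appears in the
    map of ``source_map``.  ``context`` is ``embedded`` for a genuine
    in-map interaction or ``listed_only`` for a mere listing."""

    source_map: str
    displayed_pathway: str
    context: str = EMBEDDED

    def __post_init__(self) -> None:
        if self.context not in (EMBEDDED, LISTED_ONLY):
            raise NetworkError(f"unknown crossref context {self.context!r}")
        if self.context == EMBEDDED and self.source_map == self.displayed_pathway:
            raise NetworkError(
                f"embedded crossref from {self.source_map!r} to itself"
            )


@dataclass
class CrosstalkNetwork:
    """Undirected pathway network over merged entries.

    Backed by a :class:`networkx.Graph`; node attributes carry the entry's
    p-value, query-gene count, collection membership and (optionally)
    class/group annotations.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    def degree(self, name: str) -> int:
        return self.graph.degree[name]


@dataclass(frozen=True)
class NodeStats:
    name: str
    interaction_count: int


def build_network(
    crossrefs: Iterable[CrossRefRecord],
    entries: Sequence[Entry],
    exclusions: Iterable[tuple[str, str]] = (),
    node_attrs: dict[str, dict] | None = None,
) -> CrosstalkNetwork:
    """Assemble the crosstalk network over ``entries`` from cross-references.

    ``exclusions`` are (source_map, displayed_pathway) pairs to ignore in
    addition to ``listed_only`` records.  ``node_attrs`` optionally adds
    per-entry attributes (e.g. class/group) onto the nodes.
    """
    names = [e.name for e in entries]
    if len(set(names)) != len(names):
        raise NetworkError("entry names are not pairwise distinct")
    member_to_entry: dict[str, str] = {}
    for e in entries:
        member_to_entry[e.name] = e.name
        for m in e.members:
            member_to_entry.setdefault(m, e.name)

    g = nx.Graph()
    for e in entries:
        attrs = dict(
            p_value=e.p_value,
            is_collection=e.is_collection,
            members=";".join(e.members),
            n_genes=len(e.union_genes),
        )
        if node_attrs and e.name in node_attrs:
            attrs.update(node_attrs[e.name])
        g.add_node(e.name, **attrs)

    excluded = {(s, d) for s, d in exclusions}
    for rec in crossrefs:
        if rec.context != EMBEDDED:
            continue
        if (rec.source_map, rec.displayed_pathway) in excluded:
            continue
        src = member_to_entry.get(rec.source_map)
        dst = member_to_entry.get(rec.displayed_pathway)
        if src is None or dst is None or src == dst:
            continue
        g.add_edge(src, dst)
    return CrosstalkNetwork(graph=g)


def interaction_counts(net: CrosstalkNetwork) -> list[NodeStats]:
    """Per-node degree (the pathway's interaction count), in name order."""
    return [NodeStats(name=n, interaction_count=net.graph.degree[n]) for n in net.nodes]


def rank_hubs(stats: Sequence[NodeStats]) -> list[NodeStats]:
    """Order nodes by interaction count descending, ties by name ascending;
    the first entry is the network's hub."""
    if not stats:
        raise NetworkError("cannot rank an empty statistics list")
    return sorted(stats, key=lambda s: (-s.interaction_count, s.name))


# ---------------------------------------------------------------------------
# I/O: crossref tables, adjacency matrices, network export
# ---------------------------------------------------------------------------

def read_crossref_tsv(path: str | Path) -> list[CrossRefRecord]:
    """Read cross-references from a TSV with columns source_map,
    displayed_pathway and optional context (defaults to embedded)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"source_map", "displayed_pathway"}
    if not required.issubset(df.columns):
        raise NetworkError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    records = []
    for row in df.itertuples(index=False):
        ctx = getattr(row, "context", EMBEDDED)
        if not isinstance(ctx, str) or not ctx:
            ctx = EMBEDDED
        records.append(
            CrossRefRecord(
                source_map=row.source_map,
                displayed_pathway=row.displayed_pathway,
                context=ctx,
            )
        )
    return records


def read_adjacency_matrix(path: str | Path) -> pd.DataFrame:
    """Read a square 0/1 interaction matrix (entry names as header row and
    first column), validating symmetry and an empty diagonal."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_adjacency(df, label=str(path))


def validate_adjacency(df: pd.DataFrame, label: str = "adjacency") -> pd.DataFrame:
    if list(df.index) != list(df.columns):
        raise NetworkError(f"{label}: row and column names differ")
    values = df.to_numpy()
    if not (values == values.T).all():
        raise NetworkError(f"{label}: matrix is not symmetric")
    if values.diagonal().any():
        raise NetworkError(f"{label}: nonzero diagonal (self-interaction)")
    if not ((values == 0) | (values == 1)).all():
        raise NetworkError(f"{label}: entries must be 0/1")
    return df.astype(int)


def adjacency_to_crossrefs(adjacency: pd.DataFrame) -> list[CrossRefRecord]:
    """Expand a symmetric 0/1 matrix into one embedded record per unordered
    interacting pair (upper triangle)."""
    adjacency = validate_adjacency(adjacency)
    names = list(adjacency.index)
    records = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if adjacency.at[a, b]:
                records.append(CrossRefRecord(source_map=a, displayed_pathway=b))
    return records


EXPORT_FORMATS = ("edgelist", "sif", "graphml")


def export_network(net: CrosstalkNetwork, path: str | Path, format: str = "edgelist") -> Path:
    """Write the network as an edge-list TSV, a SIF file, or GraphML.

    Edge list: header ``source\\ttarget`` plus one sorted row per edge
    (re-import reproduces the edge set).  SIF: ``node crosstalk node`` per
    edge, isolated nodes as bare lines.  GraphML keeps node attributes.
    """
    path = Path(path)
    if format == "edgelist":
        with path.open("w", encoding="utf-8") as fh:
            fh.write("source\ttarget\n")
            for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
                fh.write(f"{a}\t{b}\n")
    elif format == "sif":
        with path.open("w", encoding="utf-8") as fh:
            for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
                fh.write(f"{a}\tcrosstalk\t{b}\n")
            for n in net.nodes:
                if net.graph.degree[n] == 0:
                    fh.write(f"{n}\n")
    elif format == "graphml":
        nx.write_graphml(net.graph, path)
    else:
        raise NetworkError(f"unknown export format {format!r}; expected {EXPORT_FORMATS}")
    return path


def import_edge_list(path: str | Path) -> set[frozenset]:
    """Read back an exported edge-list TSV as a set of unordered pairs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {frozenset((r.source, r.target)) for r in df.itertuples(index=False)}
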