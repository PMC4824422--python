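"""Reading, writing and normalization of gene lists and gene-set collections.

Gene sets travel in GMT format (one set per line: name, description, then
member symbols, tab-separated), the interchange format used by MSigDB and
most enrichment tools.  Query gene lists are plain text, one symbol per
line.  All symbols are normalized to an uppercase, whitespace-trimmed
canonical form; no alias or HGNC resolution is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple


class GeneSetError(ValueError):
    """Malformed gene-set input (bad symbol, bad GMT line, duplicate name)."""


def normalize_symbol(raw: str) -> str:
    """Canonicalize a gene symbol: strip surrounding whitespace, uppercase.

    Raises :class:`GeneSetError` if the result is empty or contains
    internal whitespace (a symbol is a single token).
    """
    token = raw.strip().upper()
    if not token:
        raise GeneSetError(f"empty gene symbol: {raw!r}")
    if any(ch.isspace() for ch in token):
        raise GeneSetError(f"gene symbol contains internal whitespace: {raw!r}")
    return token


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (e.g. one KEGG pathway or GO term)."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise GeneSetError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.members


@dataclass
class GeneSetCollection:
    """An ordered collection of uniquely named gene sets."""

    collection_name: str
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise GeneSetError(f"duplicate set names in collection: {dup}")
        self._by_name = {s.name: s for s in self.sets}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def universe(self) -> frozenset[str]:
        """Union of all member genes across the collection."""
        out: set[str] = set()
        for s in self.sets:
            out |= s.members
        return frozenset(out)


@dataclass(frozen=True)
class QueryGeneList:
    """An ordered, duplicate-free query gene list (e.g. the SFARI ASD genes)."""

    symbols: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise GeneSetError("query gene list contains duplicates")

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self) -> Iterator[str]:
        return iter(self.symbols)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.symbols)


class RestrictionResult(NamedTuple):
    query: QueryGeneList
    n_retained: int
    n_dropped: int
    dropped: tuple[str, ...]


def make_query(symbols: Iterable[str], provenance: str = "") -> QueryGeneList:
    """Normalize symbols, collapse duplicates, keep first-occurrence order."""
    seen: dict[str, None] = {}
    for raw in symbols:
        seen.setdefault(normalize_symbol(raw), None)
    if not seen:
        raise GeneSetError("empty query")
    return QueryGeneList(symbols=tuple(seen), provenance=provenance)


def read_gmt(path: str | Path, collection_name: str | None = None) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Each non-blank line must carry at least three tab-separated fields:
    set name, description (may be empty), and one or more gene symbols.
    Duplicate genes within a line are collapsed; a duplicate set name is
    an error.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GeneSetError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name, description = fields[0].strip(), fields[1]
            members = frozenset(
                normalize_symbol(g) for g in fields[2:] if g.strip()
            )
            if not members:
                raise GeneSetError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(name=name, description=description, members=members))
    return GeneSetCollection(
        collection_name=collection_name if collection_name is not None else path.stem,
        sets=sets,
    )


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    """Write a collection in GMT format; members are written sorted so the
    output is byte-stable.  ``read_gmt`` of the result reproduces the input
    collection (set order, names, descriptions, memberships)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in collection.sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")
    return path


def read_gene_list(path: str | Path, provenance: str | None = None) -> QueryGeneList:
    """Read a one-symbol-per-line gene list; blank lines ignored.

    Symbols are normalized and de-duplicated, preserving the order of first
    occurrence.  An empty result is an error.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        raw = [line.strip() for line in fh]
    symbols = [r for r in raw if r]
    if not symbols:
        raise GeneSetError(f"empty query: {path} has no non-blank lines")
    return make_query(symbols, provenance=provenance if provenance is not None else str(path))


def restrict_to_universe(
    query: QueryGeneList, universe: Iterable[str]
) -> RestrictionResult:
    """Intersect a query list with a background universe, preserving order.

    Query genes absent from the universe are dropped (they cannot
    contribute to any overlap and would distort the effective query size).
    Returns the restricted list plus retained/dropped bookkeeping.
    """
    uni = frozenset(universe)
    if not uni:
        raise GeneSetError("universe is empty")
    kept = tuple(s for s in query.symbols if s in uni)
    dropped = tuple(s for s in query.symbols if s not in uni)
    if not kept:
        raise GeneSetError("query disjoint from universe")
    restricted = QueryGeneList(symbols=kept, provenance=query.provenance)
    return RestrictionResult(
        query=restricted, n_retained=len(kept), n_dropped=len(dropped), dropped=dropped
    )
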