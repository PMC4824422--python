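"""End-to-end orchestration: query -> enrichment -> merge -> network -> summaries.

:func:`run_analysis` drives the in-memory pipeline; :func:`run_pipeline`
wraps it with file I/O (a YAML/dict config of paths and parameters, TSV
and graph outputs, and a JSON run report).  Later stages degrade
gracefully: without a cross-reference input the network stages are
skipped with a warning, and earlier outputs are still written.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import __version__
from .annotation import (
    GroupingScheme,
    GroupSummary,
    MembershipMatrix,
    ParticipationTable,
    classify_and_summarize,
    entity_participation,
    gene_participation,
    membership_from_entries,
    read_grouping_scheme,
    write_group_summary_tsv,
    write_membership_tsv,
    write_participation_tsv,
)
from .crosstalk_network import (
    CrossRefRecord,
    CrosstalkNetwork,
    NodeStats,
    adjacency_to_crossrefs,
    build_network,
    export_network,
    interaction_counts,
    rank_hubs,
    read_adjacency_matrix,
    read_crossref_tsv,
)
from .enrichment import (
    EnrichmentTable,
    UniverseSpec,
    enrich_collection,
    select_top,
    write_enrichment_tsv,
)
from .geneset_io import (
    GeneSetCollection,
    QueryGeneList,
    read_gene_list,
    read_gmt,
    restrict_to_universe,
)
from .redundancy import (
    Entry,
    RedundancyParams,
    reduce_redundancy,
    write_entries_tsv,
)

logger = logging.getLogger("pathcrosstalk")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """File-based pipeline configuration.

    ``gmt_paths`` lists one or more gene-set collections; the first is the
    pathway collection the network is built from.  ``crossref_path`` (TSV
    of source_map / displayed_pathway / context) or ``adjacency_path``
    (square 0/1 matrix) feeds the network stage; with neither, network
    stages are skipped.
    """

    query_path: str
    gmt_paths: list[str]
    universe_size: int
    out_dir: str
    universe_symbols_path: str | None = None
    crossref_path: str | None = None
    adjacency_path: str | None = None
    grouping_path: str | None = None
    entity_map_path: str | None = None
    exclusions: list[tuple[str, str]] = field(default_factory=list)
    #: display names for expected merged collections: name -> member list
    collection_names: dict[str, list[str]] = field(default_factory=dict)
    top_k: int = 50
    fdr_threshold: float = 0.05
    max_overlap: float = 0.85
    min_overlap: float = 0.10
    display_min: int = 4
    seed: int = 0
    log_level: str = "INFO"


@dataclass
class AnalysisResult:
    query: QueryGeneList
    n_dropped: int
    enrichment: dict[str, EnrichmentTable]
    selected: EnrichmentTable
    entries: list[Entry]
    network: CrosstalkNetwork | None
    hub_ranking: list[NodeStats] | None
    membership: MembershipMatrix
    participation: ParticipationTable
    entity_counts: dict[str, int] | None
    summary: GroupSummary | None
    warnings: list[str] = field(default_factory=list)


@dataclass
class RunReport:
    stage_counts: dict[str, int]
    warnings: list[str]
    manifest: list[str]
    parameters: dict
    version: str
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "stage_counts": self.stage_counts,
                "warnings": self.warnings,
                "manifest": self.manifest,
                "parameters": self.parameters,
                "version": self.version,
                "seed": self.seed,
            },
            indent=2,
            sort_keys=True,
        )


def run_analysis(
    query: QueryGeneList,
    collections: Sequence[GeneSetCollection],
    universe: UniverseSpec,
    universe_symbols: Iterable[str] | None = None,
    crossrefs: Sequence[CrossRefRecord] | None = None,
    exclusions: Iterable[tuple[str, str]] = (),
    grouping: GroupingScheme | None = None,
    entity_map: Mapping[str, Iterable[str]] | None = None,
    precomputed_screen: EnrichmentTable | None = None,
    top_k: int = 50,
    fdr_threshold: float = 0.05,
    redundancy: RedundancyParams = RedundancyParams(),
    collection_names: Mapping[frozenset, str] | None = None,
    display_min: int = 4,
) -> AnalysisResult:
    """Run the full in-memory analysis.

    The first collection is the pathway collection: its top enriched sets
    (or ``precomputed_screen``, when the screen was run elsewhere) are
    merged, networked and annotated.  Additional collections are enriched
    and reported but not networked (the GO screens play this role).
    """
    warnings: list[str] = []

    if universe_symbols is not None:
        restricted = restrict_to_universe(query, universe_symbols)
        query = restricted.query
        n_dropped = restricted.n_dropped
        if n_dropped:
            warnings.append(f"{n_dropped} query genes absent from the universe were dropped")
    else:
        n_dropped = 0

    if not collections:
        raise PipelineError("enrich: no gene-set collections supplied")
    pathway_collection = collections[0]

    enrichment: dict[str, EnrichmentTable] = {}
    for coll in collections:
        logger.info("enriching %s (%d sets)", coll.collection_name, len(coll))
        enrichment[coll.collection_name] = enrich_collection(query, coll, universe)

    screen = (
        precomputed_screen
        if precomputed_screen is not None
        else enrichment[pathway_collection.collection_name]
    )
    selected = select_top(screen, top_k=top_k, fdr_threshold=fdr_threshold)
    logger.info("selected %d of %d screened sets", len(selected), len(screen))

    entries = reduce_redundancy(
        selected, pathway_collection, redundancy, collection_names=collection_names
    )
    logger.info("redundancy merge: %d sets -> %d entries", len(selected), len(entries))

    network = None
    hub_ranking = None
    if crossrefs is not None:
        network = build_network(crossrefs, entries, exclusions=exclusions)
        hub_ranking = rank_hubs(interaction_counts(network))
    else:
        warnings.append("no cross-reference input: network stages skipped")

    membership = membership_from_entries(query, entries)
    participation = gene_participation(membership, display_min=display_min)

    entity_counts = None
    if entity_map is not None:
        entity_counts, entity_warnings = entity_participation(
            entity_map, [e.name for e in entries]
        )
        warnings.extend(entity_warnings)

    summary = None
    if grouping is not None:
        summary = classify_and_summarize([e.name for e in entries], grouping)

    return AnalysisResult(
        query=query,
        n_dropped=n_dropped,
        enrichment=enrichment,
        selected=selected,
        entries=entries,
        network=network,
        hub_ranking=hub_ranking,
        membership=membership,
        participation=participation,
        entity_counts=entity_counts,
        summary=summary,
        warnings=warnings,
    )


def _read_entity_map(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Entity map TSV: columns entity, entries (semicolon-joined)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        row.entity: tuple(row.entries.split(";")) if row.entries else ()
        for row in df.itertuples(index=False)
    }


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the file-based pipeline and write all outputs.

    Outputs under ``config.out_dir``: one enrichment TSV per collection,
    the merged-entry TSV, network exports (edge list, SIF, GraphML) when a
    network input is configured, membership/participation TSVs, the group
    summary TSV, and ``run_report.json``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    stage_counts: dict[str, int] = {}

    def _stage(name: str):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(f"{name}: {exc}") from exc
        return wrap

    query = _stage("load query")(read_gene_list, config.query_path)
    collections = [
        _stage("load gene sets")(read_gmt, p) for p in config.gmt_paths
    ]
    universe = UniverseSpec(N=config.universe_size, source="configured")
    universe_symbols = None
    if config.universe_symbols_path:
        universe_symbols = _stage("load universe")(
            read_gene_list, config.universe_symbols_path
        ).as_set()

    crossrefs = None
    if config.crossref_path:
        crossrefs = _stage("load crossrefs")(read_crossref_tsv, config.crossref_path)
    elif config.adjacency_path:
        adjacency = _stage("load adjacency")(read_adjacency_matrix, config.adjacency_path)
        crossrefs = adjacency_to_crossrefs(adjacency)

    grouping = None
    if config.grouping_path:
        grouping = _stage("load grouping")(read_grouping_scheme, config.grouping_path)
    entity_map = None
    if config.entity_map_path:
        entity_map = _stage("load entity map")(_read_entity_map, config.entity_map_path)

    result = _stage("analysis")(
        run_analysis,
        query,
        collections,
        universe,
        universe_symbols=universe_symbols,
        crossrefs=crossrefs,
        exclusions=config.exclusions,
        grouping=grouping,
        entity_map=entity_map,
        top_k=config.top_k,
        fdr_threshold=config.fdr_threshold,
        redundancy=RedundancyParams(config.max_overlap, config.min_overlap),
        collection_names={
            frozenset(members): name
            for name, members in config.collection_names.items()
        },
        display_min=config.display_min,
    )

    stage_counts["query_genes"] = len(result.query)
    stage_counts["query_genes_dropped"] = result.n_dropped
    for name, table in result.enrichment.items():
        safe = name.replace("/", "_").replace(" ", "_")
        path = write_enrichment_tsv(table, out / f"enrichment_{safe}.tsv")
        manifest.append(str(path))
        stage_counts[f"enriched_sets_{safe}"] = len(table)
    stage_counts["selected_sets"] = len(result.selected)
    stage_counts["network_entries"] = len(result.entries)
    manifest.append(str(write_entries_tsv(result.entries, out / "merged_entries.tsv")))

    if result.network is not None:
        stage_counts["network_edges"] = len(result.network.edges)
        for fmt, suffix in (("edgelist", "tsv"), ("sif", "sif"), ("graphml", "graphml")):
            manifest.append(
                str(export_network(result.network, out / f"network.{suffix}", format=fmt))
            )
    manifest.append(str(write_membership_tsv(result.membership, out / "membership.tsv")))
    manifest.append(
        str(write_participation_tsv(result.participation, out / "participation.tsv"))
    )
    if result.summary is not None:
        manifest.append(
            str(write_group_summary_tsv(result.summary, out / "group_summary.tsv"))
        )
    if result.entity_counts is not None:
        path = out / "entity_participation.tsv"
        with path.open("w", encoding="utf-8") as fh:
            fh.write("entity\tn_entries\n")
            for entity, count in sorted(result.entity_counts.items()):
                fh.write(f"{entity}\t{count}\n")
        manifest.append(str(path))

    report = RunReport(
        stage_counts=stage_counts,
        warnings=result.warnings,
        manifest=manifest,
        parameters={
            "universe_size": config.universe_size,
            "top_k": config.top_k,
            "fdr_threshold": config.fdr_threshold,
            "max_overlap": config.max_overlap,
            "min_overlap": config.min_overlap,
            "display_min": config.display_min,
        },
        version=__version__,
        seed=config.seed,
    )
    report_path = out / "run_report.json"
    report_path.write_text(report.to_json() + "\n", encoding="utf-8")
    report.manifest.append(str(report_path))
    return report
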