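"""Seeded synthetic-data generators with planted ground truth.

Every stage of the pipeline can be exercised without external databases:

* :func:`make_pathway_db` — a gene-set collection over an artificial
  universe, optionally with planted redundancy clusters realizing target
  overlap ratios;
* :func:`make_query` — a query list with chosen sets planted at a given
  fold-enrichment (at fold 1 the query is an exactly uniform draw, so
  null p-values are uniform up to discreteness);
* :func:`make_crossrefs` — a random cross-reference table with an
  optional planted hub of exact target degree.

All generators are pure functions of (config, seed): stage RNGs are
spawned from the scenario seed with fixed stage tags, so each stage is
independently reproducible and identical seeds give identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .crosstalk_network import CrossRefRecord
from .geneset_io import GeneSet, GeneSetCollection, QueryGeneList


class ScenarioError(ValueError):
    """Infeasible or inconsistent scenario configuration."""


_STAGE_DB = 1
_STAGE_QUERY = 2
_STAGE_CROSSREF = 3


@dataclass(frozen=True)
class ClusterSpec:
    """A planted redundancy cluster: ``n_members`` sets arranged as a star
    whose satellite/hub overlap ratios target (ratio_major, ratio_minor),
    with ``satellite_size`` genes per satellite."""

    n_members: int
    ratio_major: float
    ratio_minor: float
    satellite_size: int = 60

    def __post_init__(self) -> None:
        if self.n_members < 2:
            raise ScenarioError("a cluster needs at least 2 members")
        for r in (self.ratio_major, self.ratio_minor):
            if not 0.0 < r <= 1.0:
                raise ScenarioError(f"overlap ratio {r} outside (0, 1]")
        if self.ratio_minor > self.ratio_major:
            raise ScenarioError("ratio_minor exceeds ratio_major")


@dataclass(frozen=True)
class ScenarioConfig:
    N: int = 20_000                 # universe size
    M: int = 25                     # number of gene sets
    set_size_range: tuple[int, int] = (50, 300)
    size_law: str = "uniform"       # "uniform" | "loguniform"
    planted_enriched: tuple[tuple[int, float], ...] = ()   # (set index, fold)
    planted_clusters: tuple[ClusterSpec, ...] = ()
    query_size: int = 500
    crossref_density: float = 0.05  # probability per ordered non-hub pair
    planted_hub: tuple[int, int] | None = None             # (entry index, degree)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.query_size > self.N:
            raise ScenarioError("query size exceeds universe size")
        if not 0.0 <= self.crossref_density <= 1.0:
            raise ScenarioError("crossref density outside [0, 1]")
        for idx, fold in self.planted_enriched:
            if idx >= self.M:
                raise ScenarioError(f"planted set index {idx} >= M={self.M}")
            if fold < 1.0:
                raise ScenarioError(f"enrichment fold {fold} < 1")
        if self.size_law not in ("uniform", "loguniform"):
            raise ScenarioError(f"unknown size law {self.size_law!r}")


@dataclass
class GroundTruth:
    enriched_sets: list[str] = field(default_factory=list)
    clusters: list[list[str]] = field(default_factory=list)
    realized_ratios: list[list[tuple[float, float]]] = field(default_factory=list)
    hub: tuple[str, int] | None = None


def _rng(config: ScenarioConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def gene_universe(config: ScenarioConfig) -> list[str]:
    return [f"G{i:06d}" for i in range(config.N)]


def make_pathway_db(config: ScenarioConfig) -> tuple[GeneSetCollection, GroundTruth]:
    """Sample M gene sets from the universe, realizing planted clusters.

    Cluster members occupy the leading set indices (one star per cluster);
    remaining sets are independent uniform draws with sizes from the
    configured size law.  Realized satellite/hub overlap ratios land
    within +-0.05 of the targets (integer rounding aside, they are exact).
    """
    rng = _rng(config, _STAGE_DB)
    genes = np.array(gene_universe(config))
    truth = GroundTruth()
    sets: list[GeneSet] = []

    for ci, spec in enumerate(config.planted_clusters):
        shared = int(round(spec.ratio_major * spec.satellite_size))
        hub_size = int(round(shared / spec.ratio_minor))
        if hub_size > config.N:
            raise ScenarioError(
                f"cluster {ci}: hub size {hub_size} exceeds universe {config.N}"
            )
        hub_members = rng.choice(genes, size=hub_size, replace=False)
        hub_name = f"CLUSTER{ci}_HUB"
        member_names = [hub_name]
        cluster_sets = [GeneSet(hub_name, "planted cluster hub", frozenset(hub_members))]
        outside = np.setdiff1d(genes, hub_members, assume_unique=False)
        ratios: list[tuple[float, float]] = []
        for si in range(spec.n_members - 1):
            core = rng.choice(hub_members, size=shared, replace=False)
            private = rng.choice(outside, size=spec.satellite_size - shared, replace=False)
            name = f"CLUSTER{ci}_SAT{si}"
            members = frozenset(core) | frozenset(private)
            cluster_sets.append(GeneSet(name, "planted cluster satellite", members))
            member_names.append(name)
            inter = len(members & cluster_sets[0].members)
            ratios.append((inter / len(members), inter / hub_size))
        if len(cluster_sets) + len(sets) > config.M:
            raise ScenarioError("planted clusters require more sets than M")
        sets.extend(cluster_sets)
        truth.clusters.append(member_names)
        truth.realized_ratios.append(ratios)

    lo, hi = config.set_size_range
    while len(sets) < config.M:
        if config.size_law == "uniform":
            size = int(rng.integers(lo, hi + 1))
        else:
            size = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        size = min(size, config.N)
        members = rng.choice(genes, size=size, replace=False)
        sets.append(GeneSet(f"SET{len(sets):03d}", "random set", frozenset(members)))

    truth.enriched_sets = [
        sets[idx].name for idx, fold in config.planted_enriched if fold > 1.0
    ]
    return GeneSetCollection(collection_name="synthetic", sets=sets), truth


def make_query(config: ScenarioConfig, db: GeneSetCollection) -> QueryGeneList:
    """Draw a query of ``query_size`` genes with planted fold-enrichment.

    Genes of a set planted at fold rho > 1 are included independently with
    probability min(1, rho * n / N); the remainder of the query is a
    uniform draw from the rest of the universe.  With no planted set (or
    all folds equal to 1) the query is an exactly uniform sample, so the
    generator is null-calibrated by construction.
    """
    n = config.query_size
    if n <= 0:
        raise ScenarioError("query size must be positive")
    rng = _rng(config, _STAGE_QUERY)
    genes = gene_universe(config)

    tilt: dict[str, float] = {}
    for idx, fold in config.planted_enriched:
        if fold <= 1.0:
            continue
        p = min(1.0, fold * n / config.N)
        for g in db.sets[idx].members:
            tilt[g] = max(tilt.get(g, 0.0), p)

    chosen: list[str] = []
    if tilt:
        for g in sorted(tilt):
            if rng.random() < tilt[g]:
                chosen.append(g)
        if len(chosen) > n:
            raise ScenarioError(
                f"planted enrichment forces {len(chosen)} picks > query size {n}"
            )
    remaining = [g for g in genes if g not in set(chosen)]
    fill = rng.choice(np.array(remaining), size=n - len(chosen), replace=False)
    symbols = sorted(set(chosen) | set(fill.tolist()))
    return QueryGeneList(symbols=tuple(symbols), provenance=f"synthetic seed={config.seed}")


def make_crossrefs(
    config: ScenarioConfig, entries: Sequence[str]
) -> tuple[list[CrossRefRecord], GroundTruth]:
    """Random cross-reference records over the entry names.

    If a hub is planted, it receives exactly its target degree and no
    other record touches it; the remaining ordered pairs are included
    independently at ``crossref_density``.
    """
    if not entries:
        raise ScenarioError("entries must be non-empty")
    rng = _rng(config, _STAGE_CROSSREF)
    truth = GroundTruth()
    records: list[CrossRefRecord] = []
    names = list(entries)
    hub_name = None
    if config.planted_hub is not None:
        hub_idx, degree = config.planted_hub
        if hub_idx >= len(names):
            raise ScenarioError(f"hub index {hub_idx} out of range")
        if degree > len(names) - 1:
            raise ScenarioError(
                f"hub degree {degree} exceeds {len(names) - 1} possible partners"
            )
        hub_name = names[hub_idx]
        others = [nm for nm in names if nm != hub_name]
        partners = rng.choice(np.array(others), size=degree, replace=False)
        for p in sorted(partners.tolist()):
            records.append(CrossRefRecord(source_map=hub_name, displayed_pathway=p))
        truth.hub = (hub_name, degree)
    for a in names:
        if a == hub_name:
            continue
        for b in names:
            if b == a or b == hub_name:
                continue
            if rng.random() < config.crossref_density:
                records.append(CrossRefRecord(source_map=a, displayed_pathway=b))
    return records, truth
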