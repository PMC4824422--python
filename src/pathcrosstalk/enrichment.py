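"""Hypergeometric over-representation analysis with BH-FDR control.

The overlap between a query gene list of size n and a gene set of size K,
drawn from a universe of N genes, is scored with the upper-tail
hypergeometric probability P(X >= k) — the convention used by MSigDB's
"Compute Overlaps" tool (the observed count is included in the tail).
Tails are accumulated in log space so probabilities far below the double
underflow limit remain exact on the log scale.

Because the background universe size N is rarely reported alongside
published enrichment tables, :func:`calibrate_universe` back-solves an
integer N from printed (K, k, p) rows by least squares on log10 p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .geneset_io import GeneSetCollection, QueryGeneList


class EnrichmentError(ValueError):
    """Invalid enrichment parameters or inputs."""


@dataclass(frozen=True)
class UniverseSpec:
    """Background gene universe: its size N and a free-text provenance label."""

    N: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.N < 1:
            raise EnrichmentError(f"universe size must be positive, got {self.N}")


@dataclass
class EnrichmentRow:
    set_name: str
    K: int                     # genes in gene set
    k: int                     # query genes in gene set
    n: int                     # query size
    N: int                     # universe size
    p_value: float
    q_value: float = float("nan")
    overlap_genes: frozenset[str] = frozenset()
    rank: int = 0


@dataclass
class EnrichmentTable:
    """Rows sorted by p ascending (ties by set name), with 1-based ranks.

    ``m`` is the number of tests the BH correction was computed over; it can
    exceed ``len(rows)`` when only the top rows of a larger screen are kept.
    """

    rows: list[EnrichmentRow] = field(default_factory=list)
    m: int = 0

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def __getitem__(self, i: int) -> EnrichmentRow:
        return self.rows[i]

    def set_names(self) -> list[str]:
        return [r.set_name for r in self.rows]


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail overlap probability P(X >= k), X ~ Hypergeom(N, K, n).

    Parameters follow the ORA convention: N universe size, K set size,
    n query size, k observed overlap.  Computed as a log-space sum of
    log-pmf terms over k..min(K, n), so the log of the tail is accurate
    even when the tail itself underflows a double; the returned float is
    the tail (0.0 only on true underflow below ~1e-308).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise EnrichmentError(f"require 0 <= K,n <= N; got K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise EnrichmentError(f"require 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k <= max(0, K + n - N):
        return 1.0  # overlap of at least k is forced by pigeonhole
    support = np.arange(k, min(K, n) + 1)
    log_tail = logsumexp(hypergeom.logpmf(support, N, K, n))
    return float(min(1.0, np.exp(log_tail)))


def log10_hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """log10 of :func:`hypergeom_tail`; safe for astronomically small tails."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise EnrichmentError(f"invalid parameters k={k}, K={K}, n={n}, N={N}")
    if k <= max(0, K + n - N):
        return 0.0
    support = np.arange(k, min(K, n) + 1)
    return float(min(0.0, logsumexp(hypergeom.logpmf(support, N, K, n)) / np.log(10)))


def bh_adjust(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    ``m`` is the total number of tests; it defaults to ``len(p_values)``
    but may be larger, as when only the smallest p-values of a screen were
    retained.  Output order matches input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise EnrichmentError("p-values must lie in (0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise EnrichmentError(f"m={m} is smaller than the number of p-values ({p.size})")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q.tolist()


def enrich_collection(
    query: QueryGeneList,
    collection: GeneSetCollection,
    universe: UniverseSpec,
) -> EnrichmentTable:
    """Score every set in a collection against the query.

    The query must already be restricted to the universe.  One row per set;
    rows are sorted by p ascending with ties broken by set name, q-values
    use m = collection size, and ranks are 1-based.
    """
    if len(collection) == 0:
        raise EnrichmentError("empty collection")
    qset = query.as_set()
    n = len(query)
    if n > universe.N:
        raise EnrichmentError(f"query size {n} exceeds universe size {universe.N}")
    rows: list[EnrichmentRow] = []
    for s in collection:
        if len(s) > universe.N:
            raise EnrichmentError(
                f"gene set {s.name!r} (K={len(s)}) exceeds universe size {universe.N}"
            )
        overlap = frozenset(qset & s.members)
        rows.append(
            EnrichmentRow(
                set_name=s.name,
                K=len(s),
                k=len(overlap),
                n=n,
                N=universe.N,
                p_value=hypergeom_tail(len(overlap), len(s), n, universe.N),
                overlap_genes=overlap,
            )
        )
    rows.sort(key=lambda r: (r.p_value, r.set_name))
    qs = bh_adjust([r.p_value for r in rows], m=len(rows))
    for i, (row, qv) in enumerate(zip(rows, qs), start=1):
        row.q_value = qv
        row.rank = i
    return EnrichmentTable(rows=rows, m=len(rows))


def select_top(
    table: EnrichmentTable, top_k: int = 50, fdr_threshold: float = 0.05
) -> EnrichmentTable:
    """Keep rows with q below the FDR threshold, truncated to the first
    ``top_k`` by rank.  ``m`` is carried over unchanged so the retained
    q-values keep their original correction."""
    if top_k < 1:
        raise EnrichmentError(f"top_k must be >= 1, got {top_k}")
    kept = [r for r in table.rows if r.q_value < fdr_threshold][:top_k]
    return EnrichmentTable(rows=kept, m=table.m)


@dataclass
class CalibrationResult:
    universe: UniverseSpec
    residuals: list[float]          # per-row log10(p_hat) - log10(p_printed)
    candidates: tuple[int, int]     # interval of N values fitting within tolerance
    ambiguous: bool
    poor_fit: bool                  # True when some |residual| >= 1 log10 unit


def calibrate_universe(
    rows: Sequence[tuple[int, int, float]],
    n: int,
    search_range: tuple[int, int] = (10_000, 60_000),
    coarse_step: int = 50,
) -> CalibrationResult:
    """Back-solve the integer universe size N from printed (K, k, p) rows.

    Minimizes the summed squared difference between computed and printed
    log10 p over a coarse grid, then refines to step 1 around the coarse
    optimum.  ``candidates`` is the contiguous interval of N around the
    optimum whose every row matches the printed p within 2-significant-
    figure rounding; the fit is flagged ambiguous when that interval has
    more than one element (always the case for a single row), and
    poor_fit when even the best N leaves a residual of one log10 unit.
    """
    if len(rows) < 1:
        raise EnrichmentError("calibration requires at least one (K, k, p) row")
    lo, hi = search_range
    k_max = max(K for K, _, _ in rows)
    lo = max(lo, k_max, n)
    if hi < lo:
        raise EnrichmentError(f"search range {search_range} excludes all feasible N")
    target = np.log10([p for _, _, p in rows])

    def sse(Ns: np.ndarray) -> np.ndarray:
        total = np.zeros(Ns.shape, dtype=float)
        for (K, k, _), t in zip(rows, target):
            total += (np.log10(hypergeom.sf(k - 1, Ns, K, n)) - t) ** 2
        return total

    coarse = np.arange(lo, hi + 1, coarse_step)
    n_star = int(coarse[np.argmin(sse(coarse))])
    fine = np.arange(max(lo, n_star - coarse_step), min(hi, n_star + coarse_step) + 1)
    fine_sse = sse(fine)
    best = int(fine[np.argmin(fine_sse)])

    resid = [
        log10_hypergeom_tail(k, K, n, best) - t for (K, k, _), t in zip(rows, target)
    ]
    # 2-significant-figure rounding admits ~2.5% relative slack per row
    tol = np.log10(1.025)
    within = np.ones(fine.shape, dtype=bool)
    for (K, k, _), t in zip(rows, target):
        within &= np.abs(np.log10(hypergeom.sf(k - 1, fine, K, n)) - t) <= tol
    good = fine[within]
    if good.size:
        lo_c, hi_c = int(good.min()), int(good.max())
    else:
        lo_c = hi_c = best
    return CalibrationResult(
        universe=UniverseSpec(N=best, source=f"calibrated from {len(rows)} printed rows"),
        residuals=resid,
        candidates=(lo_c, hi_c),
        ambiguous=hi_c > lo_c,
        poor_fit=any(abs(r) >= 1.0 for r in resid),
    )


def fit_effective_m(
    p_values: Sequence[float], q_values: Sequence[float], ranks: Sequence[int]
) -> int:
    """Recover the number of tests m behind a printed BH-adjusted table.

    For rows where the step-up minimum is not binding, q = m * p / rank, so
    m is estimated as the rounded geometric mean of q * rank / p.
    """
    vals = [q * r / p for p, q, r in zip(p_values, q_values, ranks)]
    if not vals:
        raise EnrichmentError("need at least one (p, q, rank) row")
    return int(round(float(np.exp(np.mean(np.log(vals))))))


def write_enrichment_tsv(table: EnrichmentTable, path: str | Path) -> Path:
    """Write an enrichment table as TSV: rank, set name, K, k, p, q and the
    overlapping genes semicolon-joined (sorted for byte stability)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(
            "rank\tset_name\tgenes_in_set\tquery_genes_in_set\tp_value\tq_value\toverlap_genes\n"
        )
        for r in table.rows:
            fh.write(
                f"{r.rank}\t{r.set_name}\t{r.K}\t{r.k}\t{r.p_value:.6g}\t"
                f"{r.q_value:.6g}\t{';'.join(sorted(r.overlap_genes))}\n"
            )
    return path
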