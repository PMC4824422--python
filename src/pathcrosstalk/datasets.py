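"""Bundled reference data: the SFARI ASD gene-list pathway-network scenario.

This module packages, as code-generated text-scale data, the study
conditions for an autism spectrum disorder (ASD) gene-list analysis: the
December-2014 SFARI Human Gene Module list (667 symbols, 659 of which
are found in the MSigDB v4.0 universe), the 40-entry enriched-KEGG
pathway network with its published summary statistics (per-entry query
gene counts, enrichment p-values, interaction degrees, class/group
assignments), reference GO enrichment rows, the per-gene pathway
participation counts, and the neuroactive ligand-receptor gene list.

Gene-level and pathway-level detail beyond those summary statistics
(which genes sit in which pathway, which specific pathway pairs
interact, the non-dominant members' p-values inside merged collections)
is NOT public at that granularity, so it is reconstructed synthetically:
deterministic builders emit matrices and gene sets that are constrained
to reproduce every summary number above exactly, but whose remaining
degrees of freedom are filled with synthetic placeholder genes and a
canonical (Havel–Hakimi) degree-sequence realization.  Every such object
is labelled synthetic in its docstring.
"""

from __future__ import annotations

from functools import lru_cache

import pandas as pd

from .annotation import GroupAssignment, GroupingScheme, MembershipMatrix
from .enrichment import EnrichmentRow, EnrichmentTable, UniverseSpec, bh_adjust
from .geneset_io import GeneSet, GeneSetCollection, QueryGeneList

# ---------------------------------------------------------------------------
# Published summary constants
# ---------------------------------------------------------------------------

#: MSigDB v4.0 "Compute Overlaps" background universe (calibratable from the
#: GO BP reference rows below; see enrichment.calibrate_universe).
MSIGDB_V4_UNIVERSE = UniverseSpec(N=45_956, source="MSigDB v4.0 gene universe")

#: Query size after restriction to the universe (659 of 667 SFARI symbols).
SFARI_TOTAL = 667
SFARI_IN_UNIVERSE = 659

#: The 40 pathway-network entries:
#: (name, class, group, interaction degree, ASD gene count, p-value)
NETWORK_ENTRIES: list[tuple[str, str, str, int, int, float]] = [
    # class "function"
    ("Calcium signaling pathway",               "function", "Cell signaling", 12, 35, 2.84e-29),
    ("MAPK signaling pathway",                  "function", "Cell signaling", 20, 22, 6.59e-11),
    ("Cell adhesion molecules (CAMs)",          "function", "Cell signaling",  1, 16, 1.14e-10),
    ("Wnt signaling pathway",                   "function", "Cell signaling",  9, 15, 5.70e-09),
    ("mTOR signaling pathway",                  "function", "Cell signaling",  4, 10, 3.16e-09),
    ("Vascular smooth muscle contraction",      "function", "Cell signaling",  1, 14, 1.28e-09),
    ("ErbB signaling pathway",                  "function", "Cell signaling",  5, 11, 5.07e-08),
    ("ECM-receptor interaction",                "function", "Cell signaling",  4, 10, 3.66e-07),
    ("GnRH signaling pathway",                  "function", "Cell signaling",  3, 10, 2.05e-06),
    ("Focal adhesion",                          "function", "Cell structure / Transport", 5, 21, 1.98e-12),
    ("Gap junction",                            "function", "Cell structure / Transport", 4, 14, 4.50e-11),
    ("Regulation of actin cytoskeleton",        "function", "Cell structure / Transport", 8, 18, 2.97e-09),
    ("Adherens junction",                       "function", "Cell structure / Transport", 5, 11, 1.04e-08),
    ("Endocytosis",                             "function", "Cell structure / Transport", 0, 15, 7.61e-08),
    ("Melanogenesis",                           "function", "Metabolism", 4, 16, 1.62e-12),
    ("Lysine degradation",                      "function", "Metabolism", 1,  8, 1.93e-07),
    ("Ubiquitin mediated proteolysis",          "function", "Metabolism", 6, 13, 1.11e-07),
    ("Tyrosine metabolism",                     "function", "Metabolism", 2,  7, 2.11e-06),
    ("Phenylalanine metabolism",                "function", "Metabolism", 1,  5, 4.38e-06),
    ("Aldosterone-regulated sodium reabsorption", "function", "Metabolism", 1, 7, 2.11e-06),
    ("Tryptophan metabolism",                   "function", "Metabolism", 0,  7, 1.49e-06),
    ("Arginine and proline metabolism",         "function", "Metabolism", 1,  7, 1.19e-05),
    ("Neuroactive ligand-receptor interaction", "function", "Neural", 2, 41, 2.87e-29),
    ("Long-term potentiation",                  "function", "Neural", 3, 17, 1.46e-16),
    ("Neurotrophin signaling pathway",          "function", "Neural", 4, 17, 4.06e-12),
    ("Long-term depression",                    "function", "Neural", 1, 11, 4.88e-09),
    ("Axon guidance",                           "function", "Neural", 2, 13, 4.96e-08),
    ("Leukocyte transendothelial migration",    "function", "Immune", 3, 10, 8.35e-06),
    ("Chemokine signaling pathway",             "function", "Immune", 4, 12, 2.19e-05),
    ("B cell receptor signaling pathway",       "function", "Immune", 4,  8, 1.24e-05),
    # class "disease"
    ("Collection cancer",                       "disease", "Cancer", 9, 37, 2.95e-18),
    ("Renal cell carcinoma",                    "disease", "Cancer", 2, 11, 4.88e-09),
    ("Thyroid cancer",                          "disease", "Cancer", 3,  7, 1.43e-07),
    ("Glioma",                                  "disease", "Cancer", 4,  8, 4.21e-06),
    ("Arrhythmogenic right ventricular cardiomyopathy (ARVC)", "disease", "Cardiac disease", 3, 12, 9.21e-10),
    ("Collection cardiac disease",              "disease", "Cardiac disease", 1, 13, 7.64e-10),
    ("Type II diabetes mellitus",               "disease", "Metabolic disease", 0, 8, 3.29e-07),
    ("Alzheimer's disease",                     "disease", "Neurodegenerative disease", 2, 13, 1.15e-06),
    ("Amyotrophic lateral sclerosis (ALS)",     "disease", "Neurodegenerative disease", 1, 7, 1.05e-05),
    ("Huntington's disease",                    "disease", "Neurodegenerative disease", 1, 12, 1.68e-05),
]

COLLECTION_CANCER_MEMBERS = (
    "Acute myeloid leukemia",
    "Bladder cancer",
    "Chronic myeloid leukemia",
    "Colorectal cancer",
    "Endometrial cancer",
    "Melanoma",
    "Non-small cell lung cancer",
    "Pathways in cancer",
    "Prostate cancer",
    "Small cell lung cancer",
)

COLLECTION_CARDIAC_MEMBERS = (
    "Dilated cardiomyopathy",
    "Hypertrophic cardiomyopathy (HCM)",
)

#: Dominant (lowest-p) member chosen for each merged collection.  The
#: published table prints only the collection-level p; the dominant
#: identity here is a synthetic assignment.
DOMINANT_CANCER = "Pathways in cancer"
DOMINANT_CARDIAC = "Dilated cardiomyopathy"

#: MSigDB v4.0 C2:CP KEGG collection size (number of tests behind the
#: KEGG screen).
KEGG_COLLECTION_SIZE = 186

#: Reference GO enrichment rows (gene-set name, K, k, p, q), from the
#: MSigDB v4.0 Compute Overlaps screen of the 659-gene SFARI query.
GO_BP_ROWS: list[tuple[str, int, int, float, float]] = [
    ("NERVOUS_SYSTEM_DEVELOPMENT",            385,  75, 2.08e-61, 1.72e-58),
    ("MULTICELLULAR_ORGANISMAL_DEVELOPMENT", 1049, 100, 1.58e-51, 6.50e-49),
    ("SYSTEM_DEVELOPMENT",                    861,  91, 1.29e-50, 3.55e-48),
    ("ANATOMICAL_STRUCTURE_DEVELOPMENT",     1013,  96, 3.30e-49, 6.80e-47),
    ("SIGNAL_TRANSDUCTION",                  1634, 106, 4.95e-39, 8.17e-37),
    ("SYSTEM_PROCESS",                        563,  57, 7.73e-31, 1.06e-28),
    ("CENTRAL_NERVOUS_SYSTEM_DEVELOPMENT",    123,  30, 2.94e-28, 3.46e-26),
    ("BIOPOLYMER_METABOLIC_PROCESS",         1684,  92, 3.38e-28, 3.48e-26),
    ("NEUROLOGICAL_SYSTEM_PROCESS",           379,  45, 1.78e-27, 1.63e-25),
    ("CELL_DEVELOPMENT",                      577,  52, 8.13e-26, 6.71e-24),
    ("TRANSMISSION_OF_NERVE_IMPULSE",         189,  32, 9.78e-25, 7.33e-23),
    ("SYNAPTIC_TRANSMISSION",                 174,  30, 1.64e-23, 1.13e-21),
    ("BIOPOLYMER_MODIFICATION",               650,  50, 8.04e-22, 5.10e-20),
    ("CELL_CELL_SIGNALING",                   404,  40, 1.33e-21, 7.68e-20),
    ("PROTEIN_MODIFICATION_PROCESS",          631,  49, 1.40e-21, 7.68e-20),
]

GO_CC_ROWS: list[tuple[str, int, int, float, float]] = [
    ("PLASMA_MEMBRANE",             1426, 125, 1.19e-60, 2.77e-58),
    ("PLASMA_MEMBRANE_PART",        1158, 112, 1.62e-58, 1.88e-56),
    ("MEMBRANE",                    1994, 142, 7.02e-58, 5.45e-56),
    ("MEMBRANE_PART",               1670, 127, 1.23e-54, 7.15e-53),
    ("INTRINSIC_TO_PLASMA_MEMBRANE", 991,  91, 1.78e-45, 8.31e-44),
    ("INTEGRAL_TO_PLASMA_MEMBRANE",  977,  90, 4.39e-45, 1.70e-43),
    ("INTRINSIC_TO_MEMBRANE",       1348, 102, 2.20e-43, 7.31e-42),
    ("INTEGRAL_TO_MEMBRANE",        1330, 100, 2.81e-42, 8.19e-41),
    ("CYTOPLASM",                   2131, 112, 6.37e-33, 1.65e-31),
    ("CYTOPLASMIC_PART",            1383,  75, 7.47e-23, 1.74e-21),
    ("PROTEIN_COMPLEX",              816,  53, 9.26e-20, 1.96e-18),
    ("MACROMOLECULAR_COMPLEX",       945,  57, 1.14e-19, 2.21e-18),
    ("NUCLEUS",                     1430,  71, 1.47e-19, 2.64e-18),
    ("CYTOSKELETON",                 367,  31, 4.18e-15, 6.96e-14),
    ("INTRACELLULAR_ORGANELLE_PART", 1192, 56, 1.31e-14, 2.03e-13),
]

GO_MF_ROWS: list[tuple[str, int, int, float, float]] = [
    ("RECEPTOR_ACTIVITY",                        583, 55, 3.07e-28, 1.21e-25),
    ("TRANSMEMBRANE_RECEPTOR_ACTIVITY",          418, 43, 8.59e-24, 1.70e-21),
    ("G_PROTEIN_COUPLED_RECEPTOR_ACTIVITY",      191, 22, 7.92e-14, 9.15e-12),
    ("PHOSPHOTRANSFERASE_ACTIVITY_ALCOHOL_GROUP_AS_ACCEPTOR", 334, 28, 1.08e-13, 9.15e-12),
    ("PROTEIN_KINASE_ACTIVITY",                  285, 26, 1.16e-13, 9.15e-12),
    ("KINASE_ACTIVITY",                          369, 29, 2.02e-13, 1.34e-11),
    ("IDENTICAL_PROTEIN_BINDING",                304, 26, 5.18e-13, 2.93e-11),
    ("RHODOPSIN_LIKE_RECEPTOR_ACTIVITY",         134, 18, 1.02e-12, 5.07e-11),
    ("CATION_CHANNEL_ACTIVITY",                  119, 17, 1.57e-12, 6.92e-11),
    ("GATED_CHANNEL_ACTIVITY",                   122, 17, 2.38e-12, 9.42e-11),
    ("METAL_ION_TRANSMEMBRANE_TRANSPORTER_ACTIVITY", 147, 18, 5.09e-12, 1.83e-10),
    ("TRANSFERASE_ACTIVITY_TRANSFERRING_PHOSPHORUS_CONTAINING_GROUPS", 424, 29, 6.34e-12, 1.96e-10),
    ("ION_CHANNEL_ACTIVITY",                     149, 18, 6.42e-12, 1.96e-10),
    ("TRANSMEMBRANE_TRANSPORTER_ACTIVITY",       375, 27, 1.05e-11, 2.97e-10),
    ("SUBSTRATE_SPECIFIC_CHANNEL_ACTIVITY",      156, 18, 1.41e-11, 3.71e-10),
    ("CYTOSKELETAL_PROTEIN_BINDING",             159, 18, 1.94e-11, 4.81e-10),
]

#: Per-gene pathway-participation counts (genes participating in >= 4 of
#: the 40 network entries).
PARTICIPATION_COUNTS: dict[str, int] = {
    "MAPK1": 23, "MAPK3": 23, "HRAS": 18, "PRKCB": 17, "BRAF": 14,
    "PIK3CG": 13, "PIK3R2": 13, "PLCB1": 11, "GSK3B": 10, "CACNA1C": 9,
    "CTNNB1": 8, "CACNA1D": 8, "CACNA1F": 7, "CREBBP": 7, "EP300": 7,
    "ITGA4": 7, "GNAS": 7, "TCF7L2": 6, "MET": 6, "ITGB7": 6, "GRM5": 6,
    "GRIN1": 6, "ADCY5": 5, "ITGB3": 5, "GRM1": 5, "GRIN2A": 5,
    "GRIN2B": 5, "NTRK1": 4, "BCL2": 4, "CTNNA3": 4, "RPS6KA2": 4,
    "RPS6KA3": 4, "MAOA": 4, "MAOB": 4,
}

#: ASD genes in the neuroactive ligand-receptor interaction pathway (41).
NEUROACTIVE_GENES = (
    "GRM5", "GRM1", "GRIN1", "GRIN2A", "DRD1", "HTR2A", "ADORA2A",
    "AVPR1A", "CHRM3", "ADRB2", "CHRNA7", "GRPR", "HTR7", "OXTR",
    "P2RX4", "PTGER3", "GRIN2B", "DRD2", "GRID2", "LEP", "GRM4",
    "AGTR2", "CHRNB3", "CNR1", "CNR2", "ADORA3", "DRD3", "GABRA1",
    "GABRA3", "GABRA4", "GABRB1", "GABRB3", "GLRA2", "GRID1", "GRIK2",
    "GRM8", "HTR1B", "MC4R", "OPRM1", "GABRQ", "THRA",
)

#: The 8 ASD genes shared by the MAPK and calcium signaling pathways.
MAPK_CALCIUM_OVERLAP = frozenset(
    {"CACNA1H", "CACNA1G", "CACNA1I", "CACNA1D", "CACNA1B", "CACNA1C",
     "CACNA1F", "PRKCB"}
)

_CALCIUM = "Calcium signaling pathway"
_MAPK = "MAPK signaling pathway"
_NEURO = "Neuroactive ligand-receptor interaction"

#: ASD genes known to sit in the calcium signaling pathway.
_CALCIUM_SEED = ("PRKCB", "PLCB1", "CACNA1C", "CACNA1D", "CACNA1F")
#: Most-participating ASD genes, all members of the MAPK signaling pathway.
_MAPK_SEED = ("MAPK1", "MAPK3", "HRAS", "PRKCB", "BRAF")


def entry_names() -> list[str]:
    return [name for name, *_ in NETWORK_ENTRIES]


def entry_query_gene_counts() -> dict[str, int]:
    return {name: k for name, _, _, _, k, _ in NETWORK_ENTRIES}


def entry_degrees() -> dict[str, int]:
    return {name: d for name, _, _, d, _, _ in NETWORK_ENTRIES}


def entry_p_values() -> dict[str, float]:
    return {name: p for name, _, _, _, _, p in NETWORK_ENTRIES}


def grouping_scheme() -> GroupingScheme:
    """Class/group assignment of the 40 network entries."""
    return GroupingScheme(
        assignments={
            name: GroupAssignment(klass=klass, group=group)
            for name, klass, group, _, _, _ in NETWORK_ENTRIES
        }
    )


# ---------------------------------------------------------------------------
# SFARI query list and universe (gene symbols beyond the published tables
# are synthetic placeholders)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _real_symbols() -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for g in list(PARTICIPATION_COUNTS) + list(NEUROACTIVE_GENES) + sorted(MAPK_CALCIUM_OVERLAP):
        seen.setdefault(g, None)
    return tuple(seen)


def sfari_query() -> QueryGeneList:
    """The 667-symbol ASD query list (synthetic stand-in).

    The 74 symbols appearing in the published participation, overlap and
    neuroactive tables are real; the remainder are synthetic placeholders
    (``ASD0001`` ...), since the full original list is an external
    download.
    """
    real = _real_symbols()
    fillers = [f"ASD{i:04d}" for i in range(1, SFARI_TOTAL - len(real) + 1)]
    return QueryGeneList(symbols=real + tuple(fillers), provenance="SFARI Human Gene Module, Dec 2014 (synthetic stand-in)")


def universe_symbols() -> frozenset[str]:
    """Universe membership for restriction: all query symbols except 8.

    Which 8 of the 667 SFARI symbols were absent from MSigDB v4.0 is not
    public; the last 8 synthetic placeholders are marked absent so that
    659 of 667 are retained.  (The universe *size* used for p-values is
    ``MSIGDB_V4_UNIVERSE.N``, not the size of this symbol set.)
    """
    q = sfari_query()
    return frozenset(q.symbols[: SFARI_IN_UNIVERSE])


# ---------------------------------------------------------------------------
# Synthetic membership matrix (S2-style stand-in)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def membership_matrix() -> MembershipMatrix:
    """Gene x entry membership matrix over the 659 in-universe query genes
    and the 40 network entries (synthetic reconstruction).

    Deterministically constructed to satisfy, exactly:

    * per-entry column sums equal the published ASD-gene counts;
    * the published per-gene participation counts (34 genes);
    * the neuroactive ligand-receptor column contains exactly the 41
      published genes;
    * the MAPK / calcium signaling columns intersect in exactly the 8
      published genes;
    * every other gene participates in at most 3 entries (below the
      published table's display threshold).

    Gene-entry placements not pinned by those constraints are synthetic.
    """
    entries = entry_names()
    capacity = entry_query_gene_counts()
    placed: dict[str, set[str]] = {g: set() for g in sfari_query().symbols[:SFARI_IN_UNIVERSE]}

    def place(gene: str, entry: str) -> None:
        if entry in placed[gene]:
            raise AssertionError(f"double placement of {gene} in {entry}")
        if capacity[entry] <= 0:
            raise AssertionError(f"capacity exhausted for {entry}")
        placed[gene].add(entry)
        capacity[entry] -= 1

    # seeds: published gene-pathway memberships
    for g in NEUROACTIVE_GENES:
        place(g, _NEURO)
    for g in sorted(MAPK_CALCIUM_OVERLAP):
        place(g, _MAPK)
        place(g, _CALCIUM)
    for g in _MAPK_SEED:
        if _MAPK not in placed[g]:
            place(g, _MAPK)
    for g in _CALCIUM_SEED:
        if _CALCIUM not in placed[g]:
            place(g, _CALCIUM)

    def allowed(gene: str) -> list[str]:
        out = []
        for e in entries:
            if e == _NEURO or capacity[e] <= 0 or e in placed[gene]:
                continue
            # keep the MAPK/calcium intersection exactly the published 8
            if gene not in MAPK_CALCIUM_OVERLAP:
                if e == _MAPK and _CALCIUM in placed[gene]:
                    continue
                if e == _CALCIUM and _MAPK in placed[gene]:
                    continue
            out.append(e)
        return out

    # published participation counts: fill each gene's remaining quota into
    # the allowed columns with the largest remaining capacity
    quotas = sorted(
        PARTICIPATION_COUNTS.items(),
        key=lambda kv: (-(kv[1] - len(placed[kv[0]])), kv[0]),
    )
    for gene, target in quotas:
        need = target - len(placed[gene])
        if need < 0:
            raise AssertionError(f"{gene} overplaced: {placed[gene]}")
        # one placement at a time: placing into MAPK removes calcium from
        # the allowed set (and vice versa) for genes outside the published
        # intersection
        for _ in range(need):
            options = sorted(allowed(gene), key=lambda e: (-capacity[e], e))
            if not options:
                raise AssertionError(f"cannot place {gene}: no remaining column")
            place(gene, options[0])

    # synthetic filler genes absorb the remaining column capacity, at most
    # 3 entries each so none reaches the published display threshold
    filler_iter = iter(
        g for g in sfari_query().symbols[:SFARI_IN_UNIVERSE]
        if g not in PARTICIPATION_COUNTS and not placed[g]
    )
    while any(capacity[e] > 0 for e in entries):
        gene = next(filler_iter)
        options = sorted(
            (e for e in entries if capacity[e] > 0 and e != _NEURO),
            key=lambda e: (-capacity[e], e),
        )
        chosen = options[:3]
        if _MAPK in chosen and _CALCIUM in chosen:
            chosen = [e for e in chosen if e != _CALCIUM]
        for e in chosen:
            place(gene, e)

    data = pd.DataFrame(
        {e: [e in placed[g] for g in placed] for e in entries},
        index=list(placed),
    )
    matrix = MembershipMatrix(data=data)
    counts = matrix.entry_gene_counts()
    expected = entry_query_gene_counts()
    assert all(counts[e] == expected[e] for e in entries), "column sums violated"
    return matrix


# ---------------------------------------------------------------------------
# Synthetic enriched-KEGG gene sets (top-50 screen stand-in)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def enriched_kegg() -> tuple[GeneSetCollection, EnrichmentTable]:
    """The 50 enriched KEGG gene sets and their screen table (synthetic).

    Pathway names, query-gene contents (via :func:`membership_matrix`) and
    the 38 singleton + 2 dominant p-values are the published ones; the
    non-query filler genes, the member-wise split inside the two merged
    collections, and the 10 non-dominant members' p-values are synthetic.
    The overlap structure is built so that redundancy merging at
    Max=0.85 / Min=0.10 reproduces exactly the published 10-member cancer
    and 2-member cardiac collections and nothing else.
    """
    matrix = membership_matrix()
    col_genes = {
        e: frozenset(matrix.data.index[matrix.data[e]]) for e in matrix.entries
    }
    p_vals = entry_p_values()

    sets: list[GeneSet] = []
    p_by_set: dict[str, float] = {}

    singletons = [
        name for name in entry_names()
        if name not in ("Collection cancer", "Collection cardiac disease")
    ]
    for idx, name in enumerate(singletons):
        q = sorted(col_genes[name])
        fillers = [f"KEGG{idx:02d}_F{i:03d}" for i in range(3 * len(q) + 10)]
        sets.append(GeneSet(name, "synthetic KEGG stand-in", frozenset(q) | frozenset(fillers)))
        p_by_set[name] = p_vals[name]

    # cancer star: the dominant pathway holds every collection query gene
    # plus 263 fillers; each satellite shares 45 of those fillers (ratio
    # 45/50 = 0.90 vs itself, 45/300 = 0.15 vs the dominant)
    cancer_q = sorted(col_genes["Collection cancer"])
    hub_fill = [f"CANCER_F{i:03d}" for i in range(300 - len(cancer_q))]
    sets.append(GeneSet(DOMINANT_CANCER, "synthetic KEGG stand-in", frozenset(cancer_q) | frozenset(hub_fill)))
    p_by_set[DOMINANT_CANCER] = p_vals["Collection cancer"]
    satellites = [m for m in COLLECTION_CANCER_MEMBERS if m != DOMINANT_CANCER]
    sat_p = [1.3e-16, 4.1e-15, 2.2e-14, 8.7e-13, 3.5e-12, 1.9e-11, 6.4e-10, 2.8e-09, 9.9e-09]
    for i, (member, p) in enumerate(zip(satellites, sat_p)):
        start = (i * 26) % len(hub_fill)
        core = [hub_fill[(start + j) % len(hub_fill)] for j in range(40)]
        # each satellite also carries 5 of the collection's query genes (all
        # held by the dominant pathway, so ratios and the union are intact)
        qshare = [cancer_q[(5 * i + j) % len(cancer_q)] for j in range(5)]
        private = [f"CANCER_S{i}_P{j}" for j in range(5)]
        members = frozenset(core) | frozenset(qshare) | frozenset(private)
        sets.append(GeneSet(member, "synthetic KEGG stand-in", members))
        p_by_set[member] = p

    # cardiac pair: 60 genes each, 55 shared (ratio 55/60 = 0.917 both ways)
    cardiac_q = sorted(col_genes["Collection cardiac disease"])
    shared_fill = [f"CARDIAC_F{i:03d}" for i in range(55 - len(cardiac_q))]
    shared = frozenset(cardiac_q) | frozenset(shared_fill)
    sets.append(GeneSet(DOMINANT_CARDIAC, "synthetic KEGG stand-in",
                        shared | frozenset(f"CARDIAC_DCM_P{j}" for j in range(5))))
    p_by_set[DOMINANT_CARDIAC] = p_vals["Collection cardiac disease"]
    other_cardiac = COLLECTION_CARDIAC_MEMBERS[1]
    sets.append(GeneSet(other_cardiac, "synthetic KEGG stand-in",
                        shared | frozenset(f"CARDIAC_HCM_P{j}" for j in range(5))))
    p_by_set[other_cardiac] = 5.2e-09

    collection = GeneSetCollection(collection_name="enriched KEGG top 50 (synthetic stand-in)", sets=sets)

    query_genes = universe_symbols()
    rows = [
        EnrichmentRow(
            set_name=s.name,
            K=len(s),
            k=len(s.members & query_genes),
            n=SFARI_IN_UNIVERSE,
            N=MSIGDB_V4_UNIVERSE.N,
            p_value=p_by_set[s.name],
            overlap_genes=frozenset(s.members & query_genes),
        )
        for s in sets
    ]
    rows.sort(key=lambda r: (r.p_value, r.set_name))
    qs = bh_adjust([r.p_value for r in rows], m=KEGG_COLLECTION_SIZE)
    for i, (row, qv) in enumerate(zip(rows, qs), start=1):
        row.q_value = qv
        row.rank = i
    return collection, EnrichmentTable(rows=rows, m=KEGG_COLLECTION_SIZE)


def collection_name_overrides() -> dict[frozenset, str]:
    """Display names for the two published merged collections."""
    return {
        frozenset(COLLECTION_CANCER_MEMBERS): "Collection cancer",
        frozenset(COLLECTION_CARDIAC_MEMBERS): "Collection cardiac disease",
    }


# ---------------------------------------------------------------------------
# Synthetic pathway-interaction matrix (S3-style stand-in)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def interaction_adjacency() -> pd.DataFrame:
    """Symmetric 0/1 interaction matrix over the 40 entries (synthetic).

    A deterministic Havel–Hakimi realization of the published interaction
    degree sequence: every entry's degree matches its published count
    (MAPK signaling 20, calcium signaling 12, ...), while the specific
    interacting pairs are a canonical synthetic choice.
    """
    degrees = entry_degrees()
    residual = dict(degrees)
    edges: set[frozenset] = set()
    while True:
        order = sorted(residual, key=lambda n: (-residual[n], n))
        top = order[0]
        d = residual[top]
        if d == 0:
            break
        partners = [n for n in order[1:] if residual[n] > 0][:d]
        if len(partners) < d:
            raise ValueError("degree sequence is not graphical")
        residual[top] = 0
        for p in partners:
            residual[p] -= 1
            edges.add(frozenset((top, p)))
    names = entry_names()
    adj = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for e in edges:
        a, b = sorted(e)
        adj.at[a, b] = 1
        adj.at[b, a] = 1
    got = adj.sum(axis=1).to_dict()
    assert got == degrees, "realized degrees deviate from the published counts"
    return adj


# ---------------------------------------------------------------------------
# Entity (compound) participation map
# ---------------------------------------------------------------------------

def calcium_entity_map() -> dict[str, tuple[str, ...]]:
    """Ca2+ (KEGG compound C00076) annotation over the network entries
    (synthetic stand-in reproducing the published 23-of-40 participation).

    The published analysis reports the calcium ion participating in 23 of
    the 40 entries; which 23 is not listed, so the stand-in selects the
    23 entries with the most ASD genes (ties by name), anchored on the
    calcium signaling pathway itself.
    """
    counts = entry_query_gene_counts()
    ranked = sorted(counts, key=lambda e: (-counts[e], e))
    chosen = set(ranked[:23])
    chosen.add(_CALCIUM)
    while len(chosen) > 23:
        chosen.remove(next(e for e in reversed(ranked) if e in chosen and e != _CALCIUM))
    return {"Ca2+ (C00076)": tuple(sorted(chosen))}


def go_reference_tables() -> dict[str, list[tuple[str, int, int, float, float]]]:
    """Reference GO enrichment rows keyed by sub-ontology (BP/CC/MF)."""
    return {"BP": list(GO_BP_ROWS), "CC": list(GO_CC_ROWS), "MF": list(GO_MF_ROWS)}
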