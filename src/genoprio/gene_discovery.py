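"""Gene-list generation: phenotype expansion, known-gene query, and the four
candidate-gene generators (cross-species, homology, interaction network,
tissue expression).

Every operation is a pure function of its inputs and the store; outputs carry
a per-gene support count that feeds validity scoring.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .errors import GenoprioError
from .evidence_store.store import EvidenceStore

GENE_LIST_SOURCES = (
    "king",
    "exphenosion",
    "mouse",
    "zebrafish",
    "homology",
    "ppi",
    "expression",
    "user",
)


@dataclass
class GeneList:
    """A set of genes from one evidence source with per-gene multiplicity."""

    source: str
    per_gene_count: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.source not in GENE_LIST_SOURCES:
            raise GenoprioError(f"unknown gene-list source {self.source!r}")
        for gene, count in self.per_gene_count.items():
            if count < 1:
                raise GenoprioError(f"count for {gene} must be >= 1, got {count}")

    @property
    def genes(self) -> set[str]:
        return set(self.per_gene_count)


def expand_phenotype(
    term_ids: Iterable[str], levels: int, store: EvidenceStore
) -> tuple[set[str], GeneList]:
    """Walk up to ``levels`` superclass steps and collect annotated genes.

    Returns the expanded term set (inputs plus ancestors within reach) and a
    gene list whose per-gene count is the number of expanded terms annotating
    the gene.
    """
    term_ids = set(term_ids)
    if levels < 0:
        raise GenoprioError("levels must be >= 0")
    unknown = sorted(t for t in term_ids if t not in store.terms)
    if unknown:
        raise GenoprioError(f"unknown ontology terms: {unknown}")

    reached = set(term_ids)
    frontier = set(term_ids)
    for _ in range(levels):
        frontier = {
            parent
            for term in frontier
            for parent in store.terms[term].parent_ids
        } - reached
        if not frontier:
            break
        reached |= frontier

    counts: dict[str, int] = {}
    for term in reached:
        for gene in store.term_genes.get(term, ()):
            counts[gene] = counts.get(gene, 0) + 1
    return reached, GeneList("exphenosion", counts)


def king_query(disease_ids: Iterable[str], store: EvidenceStore) -> GeneList:
    """Known genes for the diseases; count = number of distinct sources."""
    disease_ids = set(disease_ids)
    if not disease_ids:
        raise GenoprioError("disease_ids must be nonempty")
    known_diseases = {rec.disease_id for rec in store.disease_genes}
    for disease in sorted(disease_ids - known_diseases):
        warnings.warn(f"disease {disease} not present in any disease-gene source")
    sources: dict[str, set[str]] = {}
    for rec in store.disease_genes:
        if rec.disease_id in disease_ids:
            sources.setdefault(rec.gene, set()).add(rec.source)
    return GeneList("king", {gene: len(srcs) for gene, srcs in sources.items()})


def cross_species_candidates(
    disease_ids: Iterable[str], organism: str, store: EvidenceStore
) -> GeneList:
    """Human genes whose orthologue models the disease in the organism."""
    disease_ids = set(disease_ids)
    counts: dict[str, int] = {}
    for rec in store.orthologs:
        if rec.organism == organism and rec.disease_id in disease_ids:
            counts[rec.human_gene] = counts.get(rec.human_gene, 0) + 1
    return GeneList(organism, counts)


def paralogue_candidates(known_genes: Iterable[str], store: EvidenceStore) -> GeneList:
    """Paralogues of the known genes, excluding the known genes themselves;
    count = number of known genes pointing at the candidate."""
    known = set(known_genes)
    if not known:
        raise GenoprioError("known_genes must be nonempty")
    counts: dict[str, int] = {}
    for gene in known:
        for partner in store.paralogues.get(gene, ()):
            if partner not in known:
                counts[partner] = counts.get(partner, 0) + 1
    return GeneList("homology", counts)


def ppi_candidates(
    known_genes: Iterable[str], levels: int, store: EvidenceStore
) -> GeneList:
    """Genes within ``levels`` interaction hops of any known gene.

    The seed genes themselves are excluded; count = number of seeds within
    reach of the candidate.
    """
    known = set(known_genes)
    if levels < 1:
        raise GenoprioError("levels must be >= 1")
    graph = store.interaction_graph()
    counts: dict[str, int] = {}
    for seed in known:
        if seed not in graph:
            continue
        distances = nx.single_source_shortest_path_length(graph, seed, cutoff=levels)
        for gene, dist in distances.items():
            if gene in known or dist == 0:
                continue
            counts[gene] = counts.get(gene, 0) + 1
    return GeneList("ppi", counts)


def expression_candidates(
    tissues: Iterable[str], cutoff: float, store: EvidenceStore
) -> GeneList:
    """Genes expressed at >= cutoff TPM in at least one requested tissue;
    count = number of qualifying tissues."""
    tissues = set(tissues)
    if cutoff < 0:
        raise GenoprioError("cutoff must be >= 0")
    available = store.tissues()
    for tissue in sorted(tissues - available):
        warnings.warn(f"tissue {tissue!r} has no expression records in the store")
    counts: dict[str, int] = {}
    for (gene, tissue), level in store.expression.items():
        if tissue in tissues and level >= cutoff:
            counts[gene] = counts.get(gene, 0) + 1
    return GeneList("expression", counts)
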