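"""Gene-validity scoring: consolidate gene lists into a weighted evidence
matrix, score and classify genes, and annotate variant records.

The score is the weighted count sum ``score(g) = sum_s weight(s) * count(g, s)``,
linear in both weights and counts. A gene is ``known`` when the known-gene
rule fires (by default: it appears in the known-gene source at all),
``candidate`` when its score reaches the candidate threshold, and ``novel``
otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import GenoprioError
from .gene_discovery import GeneList
from .io_formats.records import VariantRecord

KNOWN = "known"
CANDIDATE = "candidate"
NOVEL = "novel"


@dataclass
class GeneEvidenceMatrix:
    genes: set[str]
    membership: dict[tuple[str, str], int]  # (gene, source) -> count, 0 if absent
    weights: dict[str, float]

    def count(self, gene: str, source: str) -> int:
        return self.membership.get((gene, source), 0)

    @property
    def sources(self) -> set[str]:
        return {source for (_, source) in self.membership}


@dataclass
class ValidityResult:
    gene: str
    score: float
    status: str  # known | candidate | novel
    evidence_breakdown: dict[str, float] = field(default_factory=dict)


def build_matrix(
    gene_lists: Iterable[GeneList], weights: Mapping[str, float]
) -> GeneEvidenceMatrix:
    """Union the gene lists into a genes × sources count matrix.

    At most one list per source is accepted; a duplicate would make the
    weighting ambiguous.
    """
    seen_sources: set[str] = set()
    membership: dict[tuple[str, str], int] = {}
    genes: set[str] = set()
    for gene_list in gene_lists:
        if gene_list.source in seen_sources:
            raise GenoprioError(
                f"duplicate gene list for source {gene_list.source!r}"
            )
        seen_sources.add(gene_list.source)
        if gene_list.source not in weights:
            raise GenoprioError(
                f"no weight configured for source {gene_list.source!r}"
            )
        for gene, count in gene_list.per_gene_count.items():
            membership[(gene, gene_list.source)] = count
            genes.add(gene)
    return GeneEvidenceMatrix(
        genes=genes,
        membership=membership,
        weights={s: float(weights[s]) for s in seen_sources},
    )


def score_genes(
    matrix: GeneEvidenceMatrix,
    known_rule: str = "king",
    candidate_threshold: float = 1.0,
) -> list[ValidityResult]:
    """Score every gene in the matrix and classify known/candidate/novel."""
    if candidate_threshold < 0:
        raise GenoprioError("candidate_threshold must be >= 0")
    results = []
    for gene in sorted(matrix.genes):
        breakdown = {}
        for source, weight in matrix.weights.items():
            count = matrix.count(gene, source)
            if count:
                breakdown[source] = weight * count
        score = sum(breakdown.values())
        if matrix.count(gene, known_rule) >= 1:
            status = KNOWN
        elif score >= candidate_threshold:
            status = CANDIDATE
        else:
            status = NOVEL
        results.append(ValidityResult(gene, score, status, breakdown))
    return results


def _fmt(value: float) -> str:
    return f"{value:g}"


def annotate_validity(
    records: Sequence[VariantRecord], results: Iterable[ValidityResult]
) -> list[dict[str, str]]:
    """Per-record INFO annotations: score, status, and per-source evidence.

    Records whose gene has no validity result (or no gene at all) score 0 and
    are labelled novel.
    """
    by_gene = {res.gene: res for res in results}
    annotations: list[dict[str, str]] = []
    for rec in records:
        res = by_gene.get(rec.gene) if rec.gene else None
        if res is None:
            annotations.append({"VALIDITY_SCORE": "0", "GENE_STATUS": NOVEL})
            continue
        ann = {"VALIDITY_SCORE": _fmt(res.score), "GENE_STATUS": res.status}
        for source, contribution in sorted(res.evidence_breakdown.items()):
            ann[f"EV_{source.upper()}"] = _fmt(contribution)
        annotations.append(ann)
    return annotations


VALIDITY_INFO_DEFS = {
    "VALIDITY_SCORE": ("1", "Float", "Weighted gene-disease validity score"),
    "GENE_STATUS": ("1", "String", "Gene classification: known/candidate/novel"),
}


def write_validity_tsv(results: Iterable[ValidityResult], path) -> None:
    with open(path, "wt") as fh:
        fh.write("gene\tscore\tstatus\n")
        for res in sorted(results, key=lambda r: (-r.score, r.gene)):
            fh.write(f"{res.gene}\t{_fmt(res.score)}\t{res.status}\n")


def read_validity_tsv(path) -> list[ValidityResult]:
    results = []
    with open(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            results.append(
                ValidityResult(row["gene"], float(row["score"]), row["status"])
            )
    return results
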