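"""Row types for the local evidence tables."""
from __future__ import annotations

from dataclasses import dataclass

ORGANISMS = ("mouse", "zebrafish")
DISEASE_SOURCES = ("omim", "orphanet", "medgen", "clinvar")
SIGNIFICANCE_LABELS = (
    "pathogenic",
    "likely_pathogenic",
    "uncertain",
    "likely_benign",
    "benign",
)


@dataclass(frozen=True)
class OntologyTerm:
    term_id: str
    name: str
    parent_ids: frozenset[str]


@dataclass(frozen=True)
class DiseaseGeneRecord:
    disease_id: str
    gene: str
    source: str  # one of DISEASE_SOURCES


@dataclass(frozen=True)
class OrthologPhenotypeRecord:
    disease_id: str
    human_gene: str
    organism: str  # one of ORGANISMS


@dataclass(frozen=True)
class ExpressionRecord:
    gene: str
    tissue: str
    level: float  # TPM, >= 0


@dataclass(frozen=True)
class GeneConstraint:
    gene: str
    pli: float | None
    haploinsufficient: bool | None


@dataclass(frozen=True)
class KnownVariantRecord:
    """A previously interpreted variant, keyed by protein change, genomic
    coordinates, or both."""

    gene: str
    aa_ref: str | None
    aa_pos: int | None
    aa_alt: str | None
    chrom: str | None
    pos: int | None
    ref: str | None
    alt: str | None
    significance: str  # one of SIGNIFICANCE_LABELS
    star_quality: int

    @property
    def protein_key(self) -> tuple[str, int, str] | None:
        if self.aa_ref is None or self.aa_pos is None or self.aa_alt is None:
            return None
        return (self.aa_ref, self.aa_pos, self.aa_alt)

    @property
    def genomic_key(self) -> tuple[str, int, str, str] | None:
        if None in (self.chrom, self.pos, self.ref, self.alt):
            return None
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class DomainRecord:
    gene: str
    aa_start: int
    aa_end: int
    hotspot: bool  # enriched for pathogenic variation, no benign variation
    repeat: bool = False  # repetitive region without known function

    def contains(self, aa_pos: int) -> bool:
        return self.aa_start <= aa_pos <= self.aa_end
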