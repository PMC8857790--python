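"""Trio handling: pedigree → trio contexts, per-variant de novo detection."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ..errors import ConfigError
from ..io_formats.records import HET, HOM_ALT, HOM_REF, PedigreeRecord, VariantRecord


@dataclass(frozen=True)
class TrioContext:
    child_id: str
    father_id: str
    mother_id: str


def find_trios(
    pedigree: Iterable[PedigreeRecord], vcf_samples: Sequence[str]
) -> list[TrioContext]:
    """Trios are children whose two parents both resolve to VCF samples."""
    samples = set(vcf_samples)
    trios = []
    for rec in pedigree:
        if (
            rec.father_id
            and rec.mother_id
            and rec.sample_id in samples
            and rec.father_id in samples
            and rec.mother_id in samples
        ):
            trios.append(TrioContext(rec.sample_id, rec.father_id, rec.mother_id))
    return trios


def validate_trio(trio: TrioContext, vcf_samples: Sequence[str]) -> None:
    missing = [
        s
        for s in (trio.child_id, trio.father_id, trio.mother_id)
        if s not in set(vcf_samples)
    ]
    if missing:
        raise ConfigError(f"trio samples absent from VCF: {missing}")


def detect_de_novo(variant: VariantRecord, trio: TrioContext) -> bool:
    """True iff the child carries the allele and both parents are confidently
    homozygous reference; any missing genotype vetoes the call."""
    child = variant.genotypes.get(trio.child_id)
    father = variant.genotypes.get(trio.father_id)
    mother = variant.genotypes.get(trio.mother_id)
    return child in (HET, HOM_ALT) and father == HOM_REF and mother == HOM_REF
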