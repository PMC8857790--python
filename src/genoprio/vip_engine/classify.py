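"""Classify a record collection and emit the three output VCFs."""
from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

from ..errors import ConfigError
from ..evidence_store.store import EvidenceStore
from ..io_formats.config import RunConfig
from ..io_formats.records import VariantRecord
from ..io_formats.vcf import write_vcf
from .combine import LIKELY_PATHOGENIC, PATHOGENIC
from .criteria import ACMGAssessment, evaluate_record
from .trio import TrioContext, validate_trio

ACMG_INFO_DEFS = {
    "ACMG_CALL": ("1", "String", "Five-tier pathogenicity call"),
    "ACMG_CRITERIA": (".", "String", "Evidence criteria that fired"),
    "ACMG_JUSTIFICATION": (".", "String", "Justification per fired criterion"),
    "DENOVO": ("0", "Flag", "Variant is de novo in the analyzed trio"),
}


def assessment_annotations(assessment: ACMGAssessment) -> dict[str, object]:
    fired = assessment.true_criteria()
    ann: dict[str, object] = {
        "ACMG_CALL": assessment.call,
        "ACMG_CRITERIA": ",".join(fired) if fired else ".",
    }
    if fired:
        ann["ACMG_JUSTIFICATION"] = "|".join(
            f"{c}:{assessment.justifications.get(c, '')}" for c in fired
        )
    if assessment.de_novo:
        ann["DENOVO"] = True
    return ann


def classify_vcf(
    records: Sequence[VariantRecord],
    store: EvidenceStore,
    config: RunConfig,
    trio: TrioContext | None = None,
    out_prefix=None,
    extra_annotations: Sequence[Mapping[str, object]] | None = None,
    extra_info_defs: Mapping[str, tuple[str, str, str]] | None = None,
) -> tuple[list[ACMGAssessment], dict[str, Path]]:
    """Assess every record; when ``out_prefix`` is given write the three
    files: de novo subset (trio only), P/LP subset, and all records.

    ``extra_annotations`` (e.g. validity scores) are merged into the INFO of
    every written file.
    """
    if trio is not None and records:
        validate_trio(trio, list(records[0].genotypes))
    assessments = [
        evaluate_record(rec, store, config, trio=trio) for rec in records
    ]

    files: dict[str, Path] = {}
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        info_defs = dict(ACMG_INFO_DEFS)
        if extra_info_defs:
            info_defs.update(extra_info_defs)

        annotations = []
        for i, assessment in enumerate(assessments):
            ann = dict(extra_annotations[i]) if extra_annotations else {}
            acmg = assessment_annotations(assessment)
            denovo_flag = acmg.pop("DENOVO", None)
            ann.update(acmg)
            if denovo_flag:
                ann["DENOVO"] = ""  # Flag key: written without a value
            annotations.append(ann)

        def subset(indexes, suffix):
            path = out_prefix.with_name(out_prefix.name + suffix)
            write_vcf(
                [records[i] for i in indexes],
                path,
                annotations=[annotations[i] for i in indexes],
                info_defs=info_defs,
                samples=list(records[0].genotypes) if records else None,
                key_map=config.info_key_map,
            )
            return path

        all_indexes = list(range(len(records)))
        files["all"] = subset(all_indexes, ".all.vcf")
        files["plp"] = subset(
            [
                i
                for i in all_indexes
                if assessments[i].call in (PATHOGENIC, LIKELY_PATHOGENIC)
            ],
            ".plp.vcf",
        )
        if trio is not None:
            files["denovo"] = subset(
                [i for i in all_indexes if assessments[i].de_novo], ".denovo.vcf"
            )
    return assessments, files


def write_assessments_tsv(
    records: Sequence[VariantRecord],
    assessments: Sequence[ACMGAssessment],
    path,
) -> None:
    with open(path, "wt") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\tcall\tcriteria\tde_novo\n")
        for rec, assessment in zip(records, assessments):
            fired = ",".join(assessment.true_criteria()) or "."
            de_novo = (
                "." if assessment.de_novo is None else str(assessment.de_novo).lower()
            )
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.ref}\t{rec.alt}\t"
                f"{rec.gene or '.'}\t{assessment.call}\t{fired}\t{de_novo}\n"
            )
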