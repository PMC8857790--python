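"""End-to-end orchestration: discovery → validity → classification → ranking.

Accepts one VCF (singleton/trio) or several (cohort). Every stage logs its
input/output counts; errors are re-raised with the stage name attached. The
whole run is deterministic for fixed inputs and configuration.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ..causality_ranker import (
    RankedVariant,
    assign_bins,
    rank_variants,
    scatter_export,
    write_ranked_tsv,
)
from ..errors import GenoprioError, PipelineError
from ..evidence_store.store import EvidenceStore
from ..gene_discovery import (
    GeneList,
    cross_species_candidates,
    expand_phenotype,
    expression_candidates,
    king_query,
    paralogue_candidates,
    ppi_candidates,
)
from ..validity_engine import (
    VALIDITY_INFO_DEFS,
    ValidityResult,
    annotate_validity,
    build_matrix,
    score_genes,
    write_validity_tsv,
)
from ..vip_engine.classify import classify_vcf, write_assessments_tsv
from ..vip_engine.criteria import ACMGAssessment
from ..vip_engine.trio import TrioContext, find_trios
from .config import RunConfig
from .ped import read_ped
from .records import VariantRecord
from .vcf import read_vcf

logger = logging.getLogger("genoprio")


@dataclass
class SampleResult:
    label: str
    records: list[VariantRecord]
    assessments: list[ACMGAssessment]
    ranked: list[RankedVariant]
    trio: TrioContext | None
    files: dict[str, Path] = field(default_factory=dict)


@dataclass
class PipelineResult:
    ranked: list[RankedVariant]  # pooled, ranked across all inputs
    per_sample: dict[str, SampleResult]
    gene_lists: list[GeneList]
    validity: dict[str, ValidityResult]
    files: dict[str, Path] = field(default_factory=dict)


def _split_curies(phenotypes: Iterable[str]) -> tuple[set[str], set[str]]:
    hp, mondo = set(), set()
    for curie in phenotypes:
        if curie.upper().startswith("HP:"):
            hp.add(curie)
        elif curie.upper().startswith("MONDO:"):
            mondo.add(curie)
        else:
            raise GenoprioError(f"unrecognized phenotype/disease CURIE {curie!r}")
    return hp, mondo


def discover_gene_lists(
    config: RunConfig,
    store: EvidenceStore,
    phenotypes: Iterable[str] = (),
    tissues: Iterable[str] = (),
    user_genes: Iterable[str] = (),
) -> list[GeneList]:
    """Run every applicable discovery module and return its gene list."""
    hp_terms, diseases = _split_curies(phenotypes)
    gene_lists: list[GeneList] = []
    if hp_terms:
        _, exphenosion = expand_phenotype(hp_terms, config.exphenosion_levels, store)
        gene_lists.append(exphenosion)
    known: set[str] = set()
    if diseases:
        king = king_query(diseases, store)
        gene_lists.append(king)
        known = king.genes
        for organism in ("mouse", "zebrafish"):
            gene_lists.append(cross_species_candidates(diseases, organism, store))
    if known:
        gene_lists.append(paralogue_candidates(known, store))
        gene_lists.append(ppi_candidates(known, config.ppi_levels, store))
    tissues = set(tissues)
    if tissues:
        gene_lists.append(
            expression_candidates(tissues, config.expression_cutoff, store)
        )
    user_genes = list(user_genes)
    if user_genes:
        gene_lists.append(GeneList("user", {g: 1 for g in user_genes}))
    for gl in gene_lists:
        logger.info("discovery: source=%s genes=%d", gl.source, len(gl.genes))
    return gene_lists


def run_pipeline(
    config: RunConfig,
    vcf,
    store: EvidenceStore,
    ped=None,
    phenotypes: Iterable[str] = (),
    tissues: Iterable[str] = (),
    user_genes: Iterable[str] = (),
    out_dir=None,
    plot: bool = False,
) -> PipelineResult:
    """Execute the full interpretation workflow.

    ``vcf`` may be a single path or a list of paths (cohort mode); the pooled
    ranking uses the same ordering key as per-sample ranking, with each
    variant labelled by its source sample.
    """
    vcf_paths = [Path(p) for p in ([vcf] if isinstance(vcf, (str, Path)) else vcf)]
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    # --- gene discovery + validity ---------------------------------------
    try:
        gene_lists = discover_gene_lists(
            config, store, phenotypes=phenotypes, tissues=tissues,
            user_genes=user_genes,
        )
    except GenoprioError as exc:
        raise PipelineError("gene_discovery", str(exc)) from exc

    validity: dict[str, ValidityResult] = {}
    if gene_lists:
        try:
            matrix = build_matrix(gene_lists, config.module_weights)
            results = score_genes(
                matrix,
                known_rule=config.known_gene_rule,
                candidate_threshold=config.candidate_threshold,
            )
            validity = {res.gene: res for res in results}
            logger.info("validity: scored %d genes", len(validity))
        except GenoprioError as exc:
            raise PipelineError("validity_engine", str(exc)) from exc
    else:
        logger.info("validity: no phenotype or gene input; stage skipped")

    pedigree = read_ped(ped) if ped is not None else []

    # --- per-input classification and ranking ----------------------------
    per_sample: dict[str, SampleResult] = {}
    files: dict[str, Path] = {}
    pooled: list[RankedVariant] = []
    for path in vcf_paths:
        label = path.stem
        try:
            records = read_vcf(path, key_map=config.info_key_map)
        except GenoprioError as exc:
            raise PipelineError("io_formats", f"{path}: {exc}") from exc
        samples = list(records[0].genotypes) if records else []
        trios = find_trios(pedigree, samples)
        trio = trios[0] if trios else None
        logger.info(
            "vip: input=%s records=%d trio=%s", label, len(records),
            trio.child_id if trio else "none",
        )
        try:
            validity_ann = annotate_validity(records, validity.values())
            assessments, sample_files = classify_vcf(
                records,
                store,
                config,
                trio=trio,
                out_prefix=(out_dir / label) if out_dir is not None else None,
                extra_annotations=validity_ann,
                extra_info_defs=VALIDITY_INFO_DEFS,
            )
        except GenoprioError as exc:
            raise PipelineError("vip_engine", f"{path}: {exc}") from exc
        try:
            ranked = rank_variants(assign_bins(records, assessments, validity,
                                               sample=label))
        except GenoprioError as exc:
            raise PipelineError("causality_ranker", f"{path}: {exc}") from exc
        logger.info(
            "causality: input=%s binned=%d", label,
            sum(1 for rv in ranked if rv.bin is not None),
        )
        if out_dir is not None:
            sample_files["ranked"] = write_ranked_tsv(
                ranked, out_dir / f"{label}.ranked.tsv"
            )
            write_assessments_tsv(
                records, assessments, out_dir / f"{label}.assessments.tsv"
            )
        per_sample[label] = SampleResult(
            label=label, records=records, assessments=assessments,
            ranked=ranked, trio=trio, files=sample_files,
        )
        pooled.extend(ranked)

    pooled = rank_variants(pooled)
    if out_dir is not None:
        files["ranked"] = write_ranked_tsv(pooled, out_dir / "cohort.ranked.tsv")
        files["scatter"] = out_dir / "cohort.scatter.tsv"
        scatter_export(
            pooled,
            tsv_path=files["scatter"],
            plot_path=(out_dir / "cohort.scatter.png") if plot else None,
        )
        if validity:
            files["validity"] = out_dir / "validity.tsv"
            write_validity_tsv(validity.values(), files["validity"])
    logger.info("pipeline: pooled ranking holds %d variants", len(pooled))
    return PipelineResult(
        ranked=pooled,
        per_sample=per_sample,
        gene_lists=gene_lists,
        validity=validity,
        files=files,
    )
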