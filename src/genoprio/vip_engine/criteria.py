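"""Per-criterion evaluators.

Each evaluator returns ``(flag, justification)``; the justification is a
human-readable string present exactly when the flag is true. Evaluators never
raise on missing evidence — absent data yields a false flag (with a note kept
separately where informative).
"""
from __future__ import annotations

from dataclasses import dataclass, field

from ..evidence_store.store import EvidenceStore
from ..io_formats.config import RunConfig
from ..io_formats.records import (
    FRAMESHIFT,
    NONFRAMESHIFT,
    STOPGAIN,
    STOPLOSS,
    SYNONYMOUS,
    VariantRecord,
)
from .combine import ALL_CRITERIA, combine_criteria
from .trio import TrioContext, detect_de_novo

#: consequence classes treated as null variants (complete loss of product)
NULL_CONSEQUENCES = frozenset({FRAMESHIFT, STOPGAIN})


@dataclass
class ACMGAssessment:
    """Criterion flags, justifications, and the combined call for one variant."""

    flags: dict[str, bool]
    justifications: dict[str, str]
    call: str
    de_novo: bool | None = None  # None when no trio was available
    notes: dict[str, str] = field(default_factory=dict)

    def true_criteria(self) -> list[str]:
        return [c for c in ALL_CRITERIA if self.flags.get(c)]


def eval_pvs1(
    v: VariantRecord, store: EvidenceStore, config: RunConfig
) -> tuple[bool, str | None]:
    """Null variant in a loss-of-function-intolerant gene."""
    is_null = v.exonic_func in NULL_CONSEQUENCES or v.func_class == "splicing"
    if not is_null or v.gene is None:
        return False, None
    gc = store.constraint.get(v.gene)
    if gc is None:
        return False, "no constraint data"
    if gc.pli is not None and gc.pli >= config.pli_cutoff:
        kind = v.exonic_func if v.exonic_func in NULL_CONSEQUENCES else "splicing"
        return True, f"{kind} variant in {v.gene} (pLI {gc.pli:g} >= {config.pli_cutoff:g})"
    if gc.haploinsufficient is True:
        kind = v.exonic_func if v.exonic_func in NULL_CONSEQUENCES else "splicing"
        return True, f"{kind} variant in haploinsufficient gene {v.gene}"
    return False, None


def eval_frequency_criteria(
    v: VariantRecord, config: RunConfig
) -> dict[str, tuple[bool, str | None]]:
    """Frequency band: at most one of PM2 / BS1 / BA1 fires."""
    af = v.pop_af
    out = {"PM2": (False, None), "BS1": (False, None), "BA1": (False, None)}
    if af is None:
        out["PM2"] = (True, "absent from population controls")
    elif af < config.pm2_maf_cutoff:
        out["PM2"] = (True, f"MAF {af:g} < {config.pm2_maf_cutoff:g}")
    elif af >= config.ba1_maf_cutoff:
        out["BA1"] = (True, f"MAF {af:g} >= {config.ba1_maf_cutoff:g}")
    elif af >= config.bs1_maf_cutoff:
        out["BS1"] = (True, f"MAF {af:g} >= {config.bs1_maf_cutoff:g}")
    return out


def eval_clinvar_criteria(
    v: VariantRecord, store: EvidenceStore
) -> dict[str, tuple[bool, str | None]]:
    """Known-variant lookups: same protein change (PS1), same residue (PM5),
    and exact genomic matches from a reputable source (PP5 / BP6)."""
    out = {
        "PS1": (False, None),
        "PM5": (False, None),
        "PP5": (False, None),
        "BP6": (False, None),
    }
    if v.gene is not None and v.aa_change is not None:
        aa = v.aa_change
        pathogenic = [
            kv
            for kv in store.known_variants_by_gene(v.gene)
            if kv.significance == "pathogenic"
            and kv.aa_ref == aa.aa_ref
            and kv.aa_pos == aa.aa_pos
        ]
        same = [kv for kv in pathogenic if kv.aa_alt == aa.aa_alt]
        if same:
            out["PS1"] = (
                True,
                f"protein change p.{aa.aa_ref}{aa.aa_pos}{aa.aa_alt} previously "
                "established as pathogenic",
            )
        elif pathogenic:
            alts = ",".join(sorted(kv.aa_alt or "?" for kv in pathogenic))
            out["PM5"] = (
                True,
                f"different pathogenic change (p.{aa.aa_ref}{aa.aa_pos}{alts}) "
                "at the same residue",
            )
    matches = [
        kv for kv in store.known_variants_by_key(v.key) if kv.star_quality >= 1
    ]
    has_path = any(
        kv.significance in ("pathogenic", "likely_pathogenic") for kv in matches
    )
    has_benign = any(
        kv.significance in ("benign", "likely_benign") for kv in matches
    )
    if has_path and not has_benign:
        out["PP5"] = (True, "reputable source reports this exact variant pathogenic")
    elif has_benign and not has_path:
        out["BP6"] = (True, "reputable source reports this exact variant benign")
    return out


def eval_structural_criteria(
    v: VariantRecord, store: EvidenceStore
) -> dict[str, tuple[bool, str | None]]:
    """Domain and protein-length criteria: PM1, PM4, BP3, BP7."""
    out = {
        "PM1": (False, None),
        "PM4": (False, None),
        "BP3": (False, None),
        "BP7": (False, None),
    }
    domains = store.domains.get(v.gene, ()) if v.gene else ()
    if v.aa_change is not None:
        pos = v.aa_change.aa_pos
        for dom in domains:
            if dom.hotspot and dom.contains(pos):
                out["PM1"] = (
                    True,
                    f"residue {pos} in mutational hotspot domain "
                    f"[{dom.aa_start},{dom.aa_end}]",
                )
                break
    if v.exonic_func in (NONFRAMESHIFT, STOPLOSS):
        out["PM4"] = (True, f"protein length change ({v.exonic_func})")
    if v.exonic_func == SYNONYMOUS:
        out["BP7"] = (True, "synonymous variant")
    if v.exonic_func == NONFRAMESHIFT and v.aa_change is not None:
        pos = v.aa_change.aa_pos
        for dom in domains:
            if dom.repeat and not dom.hotspot and dom.contains(pos):
                out["BP3"] = (
                    True,
                    f"in-frame change in repeat region [{dom.aa_start},{dom.aa_end}]",
                )
                break
    return out


def evaluate_record(
    v: VariantRecord,
    store: EvidenceStore,
    config: RunConfig,
    trio: TrioContext | None = None,
    external_flags: dict[str, bool] | None = None,
) -> ACMGAssessment:
    """Run every evaluator, fold in trio evidence, and combine into a call.

    ``external_flags`` lets a caller assert criteria this engine has no data
    for (segregation, functional assays, ...); they are accepted verbatim.
    """
    flags = {c: False for c in ALL_CRITERIA}
    justifications: dict[str, str] = {}
    notes: dict[str, str] = {}

    def apply(criterion: str, result: tuple[bool, str | None]) -> None:
        flag, text = result
        flags[criterion] = flag
        if flag and text:
            justifications[criterion] = text
        elif not flag and text:
            notes[criterion] = text

    apply("PVS1", eval_pvs1(v, store, config))
    for criterion, result in eval_frequency_criteria(v, config).items():
        apply(criterion, result)
    for criterion, result in eval_clinvar_criteria(v, store).items():
        apply(criterion, result)
    for criterion, result in eval_structural_criteria(v, store).items():
        apply(criterion, result)

    de_novo: bool | None = None
    if trio is not None:
        de_novo = detect_de_novo(v, trio)
        if de_novo and config.ps2_from_de_novo:
            apply(
                "PS2",
                (True, "de novo: child carries the allele, both parents hom-ref"),
            )

    if external_flags:
        for criterion, flag in external_flags.items():
            if criterion not in flags:
                continue
            flags[criterion] = bool(flag)
            if flag:
                justifications.setdefault(criterion, "externally supplied")
            else:
                justifications.pop(criterion, None)

    return ACMGAssessment(
        flags=flags,
        justifications=justifications,
        call=combine_criteria(flags),
        de_novo=de_novo,
        notes=notes,
    )
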