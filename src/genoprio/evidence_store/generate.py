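"""Seeded synthetic evidence stores and trio VCF fixtures.

Everything here is deterministic given the seed, so the same call produces
byte-identical tables/VCFs — the property the test suite and the acceptance
runs rely on.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..errors import GenerationError
from ..io_formats.config import RunConfig
from ..io_formats.ped import write_ped
from ..io_formats.records import (
    FRAMESHIFT,
    HET,
    HOM_ALT,
    HOM_REF,
    NONSYNONYMOUS,
    STOPLOSS,
    SYNONYMOUS,
    AAChange,
    PedigreeRecord,
    VariantRecord,
)
from ..io_formats.vcf import write_vcf
from .store import EvidenceStore
from .types import (
    DISEASE_SOURCES,
    DiseaseGeneRecord,
    DomainRecord,
    GeneConstraint,
    KnownVariantRecord,
    OntologyTerm,
    OrthologPhenotypeRecord,
)

# fixed layout constants shared between store and fixture generation
_HOTSPOT_INTERVAL = (60, 80)
_REPEAT_INTERVAL = (200, 260)
_KNOWN_PATH_AA = ("R", 100, "Q")
_KNOWN_PATH_OFFSET = 500
_KNOWN_BENIGN_OFFSET = 600
_PLANT_OFFSET = 1000
_BACKGROUND_OFFSET = 50_000
_DEFAULT_AA = ("A", 150, "V")


def gene_locus(gene: str) -> tuple[str, int]:
    """Deterministic genomic anchor for a synthetic gene symbol."""
    m = re.search(r"(\d+)$", gene)
    index = int(m.group(1)) if m else sum(map(ord, gene))
    chrom = f"chr{(index % 22) + 1}"
    return chrom, 1_000_000 + index * 10_000


def generate_store(
    seed: int,
    n_genes: int = 120,
    n_terms: int = 30,
    n_diseases: int = 3,
    n_known_per_disease: int = 4,
    n_layers: int = 4,
    tissues: tuple[str, ...] = ("heart", "brain", "liver"),
    mean_degree: float = 3.0,
    expression_prob: float = 0.7,
) -> tuple[EvidenceStore, dict]:
    """Build a seeded store plus a ground-truth manifest.

    The manifest records, per disease, which genes were planted as known (and
    in which of the four disease-gene sources) and which as cross-species
    candidates, so tests can assert recovery against it.
    """
    if min(n_genes, n_terms, n_diseases, n_known_per_disease, n_layers) < 1:
        raise GenerationError("all sizes must be >= 1")
    rng = np.random.default_rng(seed)

    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    diseases = [f"MONDO:{7000000 + i}" for i in range(n_diseases)]
    store = EvidenceStore()
    manifest: dict = {
        "seed": int(seed),
        "genes": genes,
        "diseases": {},
        "tissues": list(tissues),
    }

    # ontology: a layered DAG, acyclic by construction
    term_ids = [f"HP:{1000000 + i}" for i in range(n_terms)]
    layers: list[list[str]] = [[term_ids[0]]]
    rest = term_ids[1:]
    per_layer = max(1, len(rest) // max(1, n_layers - 1))
    for layer_index in range(1, n_layers):
        chunk = rest[(layer_index - 1) * per_layer:] if layer_index == n_layers - 1 \
            else rest[(layer_index - 1) * per_layer: layer_index * per_layer]
        if chunk:
            layers.append(chunk)
    terms: dict[str, OntologyTerm] = {
        layers[0][0]: OntologyTerm(layers[0][0], "root phenotype", frozenset())
    }
    for layer_index in range(1, len(layers)):
        for tid in layers[layer_index]:
            n_parents = int(rng.integers(1, min(2, len(layers[layer_index - 1])) + 1))
            parents = rng.choice(layers[layer_index - 1], size=n_parents, replace=False)
            terms[tid] = OntologyTerm(tid, f"phenotype {tid}", frozenset(map(str, parents)))
    store.terms = terms
    manifest["term_layers"] = [list(layer) for layer in layers]

    term_genes = {}
    for tid in term_ids:
        size = int(rng.integers(1, 5))
        chosen = rng.choice(genes, size=size, replace=False)
        term_genes[tid] = frozenset(map(str, chosen))
    store.term_genes = term_genes

    # disease-gene sources + cross-species candidates
    disease_gene_records: set[DiseaseGeneRecord] = set()
    ortholog_records: set[OrthologPhenotypeRecord] = set()
    known_all: list[str] = []
    for disease in diseases:
        chosen = [str(g) for g in rng.choice(genes, size=n_known_per_disease, replace=False)]
        entry: dict = {"known_genes": {}, "mouse": [], "zebrafish": []}
        for gene in chosen:
            n_sources = int(rng.integers(1, 5))
            sources = sorted(
                str(s) for s in rng.choice(DISEASE_SOURCES, size=n_sources, replace=False)
            )
            for source in sources:
                disease_gene_records.add(DiseaseGeneRecord(disease, gene, source))
            entry["known_genes"][gene] = sources
        known_all.extend(chosen)
        for organism in ("mouse", "zebrafish"):
            size = int(rng.integers(2, 4))
            picked = sorted(str(g) for g in rng.choice(genes, size=size, replace=False))
            for gene in picked:
                ortholog_records.add(OrthologPhenotypeRecord(disease, gene, organism))
            entry[organism] = picked
        manifest["diseases"][disease] = entry
    store.disease_genes = frozenset(disease_gene_records)
    store.orthologs = frozenset(ortholog_records)

    # paralogues: random symmetric pairs, plus one partner per known gene
    paralogues: dict[str, set[str]] = {}

    def link(a: str, b: str) -> None:
        if a == b:
            return
        paralogues.setdefault(a, set()).add(b)
        paralogues.setdefault(b, set()).add(a)

    for _ in range(max(1, n_genes // 4)):
        a, b = rng.choice(genes, size=2, replace=False)
        link(str(a), str(b))
    for gene in known_all:
        partner = str(rng.choice(genes))
        if partner != gene:
            link(gene, partner)
    store.paralogues = {g: frozenset(p) for g, p in paralogues.items()}

    # interaction network: random edges, every known gene connected
    edges: set[tuple[str, str]] = set()
    n_edges = int(n_genes * mean_degree / 2)
    for _ in range(n_edges):
        a, b = (str(x) for x in rng.choice(genes, size=2, replace=False))
        edges.add((min(a, b), max(a, b)))
    for gene in known_all:
        if not any(gene in edge for edge in edges):
            partner = str(rng.choice([g for g in genes if g != gene]))
            edges.add((min(gene, partner), max(gene, partner)))
    store.interactions = frozenset(edges)

    expression = {}
    for gene in genes:
        for tissue in tissues:
            if rng.random() < expression_prob:
                expression[(gene, tissue)] = round(float(rng.gamma(2.0, 5.0)), 2)
    store.expression = expression

    # constraint: planted known genes are made LOF-intolerant so null-variant
    # profiles can always be planted in them
    constraint = {}
    for gene in genes:
        constraint[gene] = GeneConstraint(
            gene, round(float(rng.uniform()), 3), bool(rng.random() < 0.15) or None
        )
    for i, gene in enumerate(sorted(set(known_all))):
        constraint[gene] = GeneConstraint(gene, 0.99, True if i % 2 == 0 else None)
    store.constraint = constraint
    manifest["lof_intolerant_genes"] = sorted(
        g for g, gc in constraint.items()
        if (gc.pli is not None and gc.pli >= 0.9) or gc.haploinsufficient
    )

    # known variants + domains for every planted known gene
    known_variants: set[KnownVariantRecord] = set()
    domains: dict[str, list[DomainRecord]] = {}
    manifest["known_variants"] = {}
    for gene in sorted(set(known_all)):
        chrom, base = gene_locus(gene)
        aa_ref, aa_pos, aa_alt = _KNOWN_PATH_AA
        pathogenic = KnownVariantRecord(
            gene=gene, aa_ref=aa_ref, aa_pos=aa_pos, aa_alt=aa_alt,
            chrom=chrom, pos=base + _KNOWN_PATH_OFFSET, ref="C", alt="T",
            significance="pathogenic", star_quality=2,
        )
        benign = KnownVariantRecord(
            gene=gene, aa_ref=None, aa_pos=None, aa_alt=None,
            chrom=chrom, pos=base + _KNOWN_BENIGN_OFFSET, ref="G", alt="A",
            significance="benign", star_quality=2,
        )
        known_variants.update((pathogenic, benign))
        domains[gene] = [
            DomainRecord(gene, *_HOTSPOT_INTERVAL, hotspot=True, repeat=False),
            DomainRecord(gene, *_REPEAT_INTERVAL, hotspot=False, repeat=True),
        ]
        manifest["known_variants"][gene] = {
            "pathogenic": {"aa": [aa_ref, aa_pos, aa_alt],
                           "key": [chrom, base + _KNOWN_PATH_OFFSET, "C", "T"]},
            "benign": {"key": [chrom, base + _KNOWN_BENIGN_OFFSET, "G", "A"]},
        }
    store.known_variants = frozenset(known_variants)
    store.domains = {g: tuple(d) for g, d in domains.items()}

    store.validate()
    return store, manifest


# ---------------------------------------------------------------------------
# trio fixtures

_AUTO = "auto"

SUPPORTED_PROFILE_CRITERIA = frozenset(
    {"PVS1", "PS1", "PS2", "PM1", "PM2", "PM4", "PM5", "PP5", "BA1", "BS1",
     "BP6", "BP7"}
)

_CONFLICTS = [
    ("PM2", "BA1"), ("PM2", "BS1"), ("BA1", "BS1"),
    ("PS1", "PM5"), ("PP5", "BP6"),
    ("PVS1", "PM4"), ("PVS1", "BP7"), ("PM4", "BP7"),
    ("PM1", "PS1"), ("PM1", "PM5"),
    ("BP7", "PS1"), ("BP7", "PM5"), ("BP7", "PM1"),
]


@dataclass
class PlantedVariant:
    """Request for one synthetic variant triggering an exact criteria set."""

    gene: str
    criteria: frozenset = frozenset()
    de_novo: bool | None = None  # None: inferred from PS2 membership
    pop_af: float | None | str = _AUTO

    def __post_init__(self):
        self.criteria = frozenset(self.criteria)


def _resolve_pop_af(pv: PlantedVariant, config: RunConfig) -> float | None:
    crit = pv.criteria
    if pv.pop_af is not _AUTO:
        af = pv.pop_af
        if "PM2" in crit and af is not None and af >= config.pm2_maf_cutoff:
            raise GenerationError(
                f"PM2 requested but pop_af {af} >= cutoff {config.pm2_maf_cutoff}"
            )
        if "BA1" in crit and (af is None or af < config.ba1_maf_cutoff):
            raise GenerationError(f"BA1 requested but pop_af {af} below cutoff")
        if "BS1" in crit and (
            af is None or af < config.bs1_maf_cutoff or af >= config.ba1_maf_cutoff
        ):
            raise GenerationError(f"BS1 requested but pop_af {af} outside band")
        if not crit & {"PM2", "BA1", "BS1"}:
            if af is None or af < config.pm2_maf_cutoff or af >= config.bs1_maf_cutoff:
                raise GenerationError(
                    f"pop_af {af} would trigger an unrequested frequency criterion"
                )
        return af
    if "PM2" in crit:
        return None
    if "BA1" in crit:
        return 0.06
    if "BS1" in crit:
        return 0.02
    return 5e-4  # the non-rare default: fails PM2 without reaching BS1


def _build_planted(
    pv: PlantedVariant, store: EvidenceStore, config: RunConfig, idx: int,
    samples: tuple[str, str, str],
) -> VariantRecord:
    crit = pv.criteria
    unsupported = crit - SUPPORTED_PROFILE_CRITERIA
    if unsupported:
        raise GenerationError(f"unsupported criteria in profile: {sorted(unsupported)}")
    for a, b in _CONFLICTS:
        if a in crit and b in crit:
            raise GenerationError(f"contradictory profile: {a} with {b}")
    if pv.gene not in store.constraint:
        raise GenerationError(f"gene {pv.gene} not present in store")

    de_novo = pv.de_novo
    if de_novo is None:
        de_novo = "PS2" in crit
    elif de_novo != ("PS2" in crit):
        raise GenerationError("PS2 membership must match the de_novo flag")

    gc = store.constraint[pv.gene]
    if "PVS1" in crit:
        intolerant = (gc.pli is not None and gc.pli >= config.pli_cutoff) or \
            gc.haploinsufficient is True
        if not intolerant:
            raise GenerationError(
                f"PVS1 requested but {pv.gene} is not LOF-intolerant in the store"
            )

    if "PVS1" in crit:
        exonic_func, ref, alt = FRAMESHIFT, "TA", "T"
    elif "PM4" in crit:
        exonic_func, ref, alt = STOPLOSS, "T", "C"
    elif "BP7" in crit:
        exonic_func, ref, alt = SYNONYMOUS, "G", "A"
    else:
        exonic_func, ref, alt = NONSYNONYMOUS, "C", "G"

    pathogenic_recs = [
        kv for kv in store.known_variants_by_gene(pv.gene)
        if kv.significance == "pathogenic" and kv.protein_key is not None
    ]
    benign_recs = [
        kv for kv in store.known_variants_by_gene(pv.gene)
        if kv.significance in ("benign", "likely_benign") and kv.genomic_key is not None
    ]

    aa: tuple[str, int, str] | None = _DEFAULT_AA
    if "BP7" in crit:
        aa = None
    if "PS1" in crit or "PM5" in crit:
        if not pathogenic_recs:
            raise GenerationError(
                f"{pv.gene} has no pathogenic known variant with a protein key"
            )
        rec = sorted(pathogenic_recs, key=lambda r: r.protein_key)[0]
        if "PS1" in crit:
            aa = rec.protein_key
        else:
            other = "L" if rec.aa_alt != "L" else "W"
            aa = (rec.aa_ref, rec.aa_pos, other)
    elif "PM1" in crit:
        hotspots = [d for d in store.domains.get(pv.gene, ()) if d.hotspot]
        if not hotspots:
            raise GenerationError(f"PM1 requested but {pv.gene} has no hotspot domain")
        dom = hotspots[0]
        aa = ("A", (dom.aa_start + dom.aa_end) // 2, "V")
    elif aa is not None:
        # keep the default position clear of any hotspot/repeat domain
        pos = aa[1]
        doms = store.domains.get(pv.gene, ())
        while any(d.contains(pos) for d in doms):
            pos = max(d.aa_end for d in doms) + 50
        aa = (aa[0], pos, aa[2])

    chrom, base = gene_locus(pv.gene)
    pos = base + _PLANT_OFFSET + idx
    if "PP5" in crit:
        keyed = [kv for kv in pathogenic_recs if kv.genomic_key is not None]
        keyed += [
            kv for kv in store.known_variants_by_gene(pv.gene)
            if kv.significance in ("pathogenic", "likely_pathogenic")
            and kv.genomic_key is not None and kv not in keyed
        ]
        if not keyed:
            raise GenerationError(
                f"PP5 requested but {pv.gene} has no pathogenic genomic-key record"
            )
        chrom, pos, ref, alt = keyed[0].genomic_key
    elif "BP6" in crit:
        if not benign_recs:
            raise GenerationError(
                f"BP6 requested but {pv.gene} has no benign genomic-key record"
            )
        chrom, pos, ref, alt = benign_recs[0].genomic_key

    child, father, mother = samples
    genotypes = (
        {child: HET, father: HOM_REF, mother: HOM_REF}
        if de_novo
        else {child: HET, father: HET, mother: HOM_REF}
    )
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=pv.gene,
        func_class="exonic",
        exonic_func=exonic_func,
        aa_change=AAChange(pv.gene, "NM_000001", aa[0], aa[1], aa[2]) if aa else None,
        pop_af=_resolve_pop_af(pv, config),
        genotypes=genotypes,
    )


def _chrom_sort_key(record: VariantRecord) -> tuple:
    m = re.match(r"chr(\d+)$", record.chrom)
    return (0, int(m.group(1))) if m else (1, record.chrom), record.pos


def generate_trio_vcf(
    seed: int,
    store: EvidenceStore,
    planted: list[PlantedVariant],
    out_dir,
    n_background: int = 500,
    prefix: str = "trio",
    family_id: str = "FAM1",
    samples: tuple[str, str, str] = ("PROBAND", "FATHER", "MOTHER"),
    config: RunConfig | None = None,
) -> tuple[Path, Path, dict]:
    """Write a trio VCF + PED + truth manifest with planted criteria profiles.

    Background variants are common, benign-profiled SNVs that can never reach
    a pathogenic or likely-pathogenic call under the default configuration.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    child, father, mother = samples

    records: list[tuple[VariantRecord, dict | None]] = []
    for idx, pv in enumerate(planted):
        rec = _build_planted(pv, store, config, idx, samples)
        records.append(
            (
                rec,
                {
                    "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
                    "alt": rec.alt, "gene": pv.gene,
                    "criteria": sorted(pv.criteria),
                    "de_novo": pv.de_novo if pv.de_novo is not None
                    else "PS2" in pv.criteria,
                },
            )
        )

    genes = sorted(store.constraint) or ["GENE0000"]
    gt_choices = np.array([HOM_REF, HET, HOM_ALT], dtype=object)
    for i in range(n_background):
        gene = str(rng.choice(genes))
        chrom, base = gene_locus(gene)
        synonymous = bool(rng.random() < 0.5)
        ref, alt = ("G", "A") if synonymous else ("C", "G")
        genotypes = {
            s: str(rng.choice(gt_choices, p=[0.5, 0.35, 0.15]))
            for s in (child, father, mother)
        }
        records.append(
            (
                VariantRecord(
                    chrom=chrom,
                    pos=base + _BACKGROUND_OFFSET + i,
                    ref=ref,
                    alt=alt,
                    gene=gene,
                    func_class="exonic",
                    exonic_func=SYNONYMOUS if synonymous else NONSYNONYMOUS,
                    aa_change=None,
                    pop_af=round(float(rng.uniform(0.001, 0.5)), 6),
                    genotypes=genotypes,
                ),
                None,
            )
        )

    records.sort(key=lambda pair: _chrom_sort_key(pair[0]))
    vcf_path = write_vcf(
        [r for r, _ in records], out_dir / f"{prefix}.vcf", samples=list(samples),
        key_map=config.info_key_map,
    )
    ped_path = write_ped(
        [
            PedigreeRecord(family_id, child, father, mother, "unknown", "affected"),
            PedigreeRecord(family_id, father, None, None, "male", "unaffected"),
            PedigreeRecord(family_id, mother, None, None, "female", "unaffected"),
        ],
        out_dir / f"{prefix}.ped",
    )
    manifest = {
        "seed": int(seed),
        "family_id": family_id,
        "samples": {"child": child, "father": father, "mother": mother},
        "n_background": int(n_background),
        "planted": [truth for _, truth in records if truth is not None],
    }
    with open(out_dir / f"{prefix}.manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return vcf_path, ped_path, manifest
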