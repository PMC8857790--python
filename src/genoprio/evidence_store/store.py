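"""The evidence store: flat TSV tables validated at load time.

Each table is optional — a missing file yields an empty table, so an empty
directory loads to an empty store whose queries all return empty sets.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from ..errors import StoreValidationError
from .types import (
    DISEASE_SOURCES,
    ORGANISMS,
    SIGNIFICANCE_LABELS,
    DiseaseGeneRecord,
    DomainRecord,
    ExpressionRecord,
    GeneConstraint,
    KnownVariantRecord,
    OntologyTerm,
    OrthologPhenotypeRecord,
)

TABLE_FILES = {
    "ontology": "ontology.tsv",
    "term_genes": "term_genes.tsv",
    "disease_genes": "disease_genes.tsv",
    "orthologs": "orthologs.tsv",
    "paralogues": "paralogues.tsv",
    "interactions": "interactions.tsv",
    "expression": "expression.tsv",
    "constraint": "constraint.tsv",
    "known_variants": "known_variants.tsv",
    "domains": "domains.tsv",
}


@dataclass
class EvidenceStore:
    terms: dict[str, OntologyTerm] = field(default_factory=dict)
    term_genes: dict[str, frozenset[str]] = field(default_factory=dict)
    disease_genes: frozenset[DiseaseGeneRecord] = frozenset()
    orthologs: frozenset[OrthologPhenotypeRecord] = frozenset()
    paralogues: dict[str, frozenset[str]] = field(default_factory=dict)
    interactions: frozenset[tuple[str, str]] = frozenset()
    expression: dict[tuple[str, str], float] = field(default_factory=dict)
    constraint: dict[str, GeneConstraint] = field(default_factory=dict)
    known_variants: frozenset[KnownVariantRecord] = frozenset()
    domains: dict[str, tuple[DomainRecord, ...]] = field(default_factory=dict)

    # derived indexes, built on demand -------------------------------------
    def interaction_graph(self) -> nx.Graph:
        graph = nx.Graph()
        graph.add_edges_from(self.interactions)
        return graph

    def known_variants_by_gene(self, gene: str) -> list[KnownVariantRecord]:
        return [kv for kv in self.known_variants if kv.gene == gene]

    def known_variants_by_key(
        self, key: tuple[str, int, str, str]
    ) -> list[KnownVariantRecord]:
        return [kv for kv in self.known_variants if kv.genomic_key == key]

    def tissues(self) -> set[str]:
        return {tissue for (_, tissue) in self.expression}

    def validate(self) -> None:
        """Enforce every table invariant; raise on the first violation."""
        # ontology: parents resolve, relation is a DAG
        graph = nx.DiGraph()
        for term in self.terms.values():
            graph.add_node(term.term_id)
            for parent in term.parent_ids:
                if parent not in self.terms:
                    raise StoreValidationError(
                        f"ontology: term {term.term_id} has dangling parent {parent}"
                    )
                graph.add_edge(term.term_id, parent)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            names = " -> ".join(edge[0] for edge in cycle)
            raise StoreValidationError(f"ontology: cycle through {names}")
        for term_id, genes in self.term_genes.items():
            if not genes:
                raise StoreValidationError(
                    f"term_genes: term {term_id} has an empty gene set"
                )
        for rec in self.disease_genes:
            if rec.source not in DISEASE_SOURCES:
                raise StoreValidationError(
                    f"disease_genes: bad source {rec.source!r} for {rec.gene}"
                )
        for rec in self.orthologs:
            if rec.organism not in ORGANISMS:
                raise StoreValidationError(
                    f"orthologs: bad organism {rec.organism!r} for {rec.human_gene}"
                )
        for gene, partners in self.paralogues.items():
            if gene in partners:
                raise StoreValidationError(
                    f"paralogues: gene {gene} lists itself as a paralogue"
                )
            for partner in partners:
                if gene not in self.paralogues.get(partner, frozenset()):
                    raise StoreValidationError(
                        f"paralogues: {gene} -> {partner} is not symmetric"
                    )
        for a, b in self.interactions:
            if a == b:
                raise StoreValidationError(f"interactions: self-loop on {a}")
            if a > b:
                raise StoreValidationError(
                    f"interactions: edge ({a},{b}) not stored canonically"
                )
        for (gene, tissue), level in self.expression.items():
            if level < 0:
                raise StoreValidationError(
                    f"expression: negative level for {gene}/{tissue}"
                )
        for gene, gc in self.constraint.items():
            if gc.pli is not None and not (0.0 <= gc.pli <= 1.0):
                raise StoreValidationError(f"constraint: pli out of [0,1] for {gene}")
        for kv in self.known_variants:
            if kv.protein_key is None and kv.genomic_key is None:
                raise StoreValidationError(
                    f"known_variants: record for {kv.gene} has neither protein "
                    "nor genomic key"
                )
            if kv.significance not in SIGNIFICANCE_LABELS:
                raise StoreValidationError(
                    f"known_variants: bad significance {kv.significance!r}"
                )
            if kv.star_quality < 0:
                raise StoreValidationError(
                    f"known_variants: negative star_quality for {kv.gene}"
                )
        for gene, recs in self.domains.items():
            for dom in recs:
                if dom.aa_start < 1 or dom.aa_end < dom.aa_start:
                    raise StoreValidationError(
                        f"domains: bad interval [{dom.aa_start},{dom.aa_end}] for {gene}"
                    )


# ---------------------------------------------------------------------------
# TSV (de)serialization

_NULL = "."


def _opt(value: str):
    return None if value in (_NULL, "") else value


def _opt_float(value: str):
    v = _opt(value)
    return None if v is None else float(v)


def _opt_int(value: str):
    v = _opt(value)
    return None if v is None else int(v)


def _opt_bool(value: str):
    v = _opt(value)
    if v is None:
        return None
    return v.lower() in ("true", "1", "yes")


def _read_table(directory: Path, name: str) -> list[dict[str, str]]:
    path = directory / TABLE_FILES[name]
    if not path.exists():
        return []
    with open(path, "rt", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        rows = []
        for i, row in enumerate(reader, 2):  # row 1 is the header
            if None in row or None in row.values():
                raise StoreValidationError(
                    f"{TABLE_FILES[name]}: row {i} has the wrong column count"
                )
            rows.append(row)
        return rows


def load_store(directory) -> EvidenceStore:
    """Load and validate all evidence tables found under ``directory``."""
    directory = Path(directory)
    store = EvidenceStore()

    terms: dict[str, OntologyTerm] = {}
    for row in _read_table(directory, "ontology"):
        parents = frozenset(p for p in row["parent_ids"].split("|") if p)
        terms[row["term_id"]] = OntologyTerm(row["term_id"], row["name"], parents)
    store.terms = terms

    term_genes: dict[str, frozenset[str]] = {}
    for row in _read_table(directory, "term_genes"):
        term_genes[row["term_id"]] = frozenset(
            g for g in row["genes"].split("|") if g
        )
    store.term_genes = term_genes

    store.disease_genes = frozenset(
        DiseaseGeneRecord(row["disease_id"], row["gene"], row["source"])
        for row in _read_table(directory, "disease_genes")
    )
    store.orthologs = frozenset(
        OrthologPhenotypeRecord(row["disease_id"], row["human_gene"], row["organism"])
        for row in _read_table(directory, "orthologs")
    )
    store.paralogues = {
        row["gene"]: frozenset(g for g in row["paralogues"].split("|") if g)
        for row in _read_table(directory, "paralogues")
    }
    store.interactions = frozenset(
        (min(row["gene_a"], row["gene_b"]), max(row["gene_a"], row["gene_b"]))
        for row in _read_table(directory, "interactions")
    )
    # self-loops must be rejected, not silently canonicalized away
    for row in _read_table(directory, "interactions"):
        if row["gene_a"] == row["gene_b"]:
            raise StoreValidationError(f"interactions: self-loop on {row['gene_a']}")
    store.expression = {
        (row["gene"], row["tissue"]): float(row["level"])
        for row in _read_table(directory, "expression")
    }
    store.constraint = {
        row["gene"]: GeneConstraint(
            row["gene"], _opt_float(row["pli"]), _opt_bool(row["haploinsufficient"])
        )
        for row in _read_table(directory, "constraint")
    }
    store.known_variants = frozenset(
        KnownVariantRecord(
            gene=row["gene"],
            aa_ref=_opt(row["aa_ref"]),
            aa_pos=_opt_int(row["aa_pos"]),
            aa_alt=_opt(row["aa_alt"]),
            chrom=_opt(row["chrom"]),
            pos=_opt_int(row["pos"]),
            ref=_opt(row["ref"]),
            alt=_opt(row["alt"]),
            significance=row["significance"],
            star_quality=int(row["star_quality"]),
        )
        for row in _read_table(directory, "known_variants")
    )
    domains: dict[str, list[DomainRecord]] = {}
    for row in _read_table(directory, "domains"):
        domains.setdefault(row["gene"], []).append(
            DomainRecord(
                gene=row["gene"],
                aa_start=int(row["aa_start"]),
                aa_end=int(row["aa_end"]),
                hotspot=_opt_bool(row["hotspot"]) or False,
                repeat=_opt_bool(row["repeat"]) or False,
            )
        )
    store.domains = {g: tuple(sorted(d, key=lambda r: (r.aa_start, r.aa_end)))
                     for g, d in domains.items()}

    store.validate()
    return store


def _fmt(value) -> str:
    if value is None:
        return _NULL
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return f"{value:g}"
    return str(value)


def save_store(store: EvidenceStore, directory) -> Path:
    """Write all tables as TSV under ``directory`` (created if needed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def write(name: str, header: list[str], rows: list[list]) -> None:
        with open(directory / TABLE_FILES[name], "wt", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(header)
            for row in rows:
                writer.writerow([_fmt(v) for v in row])

    write(
        "ontology",
        ["term_id", "name", "parent_ids"],
        [
            [t.term_id, t.name, "|".join(sorted(t.parent_ids))]
            for t in sorted(store.terms.values(), key=lambda t: t.term_id)
        ],
    )
    write(
        "term_genes",
        ["term_id", "genes"],
        [[tid, "|".join(sorted(genes))] for tid, genes in sorted(store.term_genes.items())],
    )
    write(
        "disease_genes",
        ["disease_id", "gene", "source"],
        sorted([r.disease_id, r.gene, r.source] for r in store.disease_genes),
    )
    write(
        "orthologs",
        ["disease_id", "human_gene", "organism"],
        sorted([r.disease_id, r.human_gene, r.organism] for r in store.orthologs),
    )
    write(
        "paralogues",
        ["gene", "paralogues"],
        [[g, "|".join(sorted(p))] for g, p in sorted(store.paralogues.items())],
    )
    write("interactions", ["gene_a", "gene_b"], sorted(list(e) for e in store.interactions))
    write(
        "expression",
        ["gene", "tissue", "level"],
        [[g, t, lvl] for (g, t), lvl in sorted(store.expression.items())],
    )
    write(
        "constraint",
        ["gene", "pli", "haploinsufficient"],
        [[gc.gene, gc.pli, gc.haploinsufficient] for _, gc in sorted(store.constraint.items())],
    )
    write(
        "known_variants",
        ["gene", "aa_ref", "aa_pos", "aa_alt", "chrom", "pos", "ref", "alt",
         "significance", "star_quality"],
        sorted(
            (
                [kv.gene, kv.aa_ref, kv.aa_pos, kv.aa_alt, kv.chrom, kv.pos,
                 kv.ref, kv.alt, kv.significance, kv.star_quality]
                for kv in store.known_variants
            ),
            key=lambda row: [str(v) for v in row],
        ),
    )
    write(
        "domains",
        ["gene", "aa_start", "aa_end", "hotspot", "repeat"],
        [
            [d.gene, d.aa_start, d.aa_end, d.hotspot, d.repeat]
            for g in sorted(store.domains)
            for d in store.domains[g]
        ],
    )
    return directory


# ---------------------------------------------------------------------------
# OBO: accepted as an alternative ontology input

def load_ontology_obo(path) -> dict[str, OntologyTerm]:
    """Minimal OBO reader: [Term] stanzas with id / name / is_a tags."""
    terms: dict[str, OntologyTerm] = {}
    current: dict | None = None

    def flush():
        if current and "id" in current:
            terms[current["id"]] = OntologyTerm(
                current["id"],
                current.get("name", current["id"]),
                frozenset(current.get("is_a", [])),
            )

    with open(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if line == "[Term]":
                flush()
                current = {}
            elif line.startswith("[") and line.endswith("]"):
                flush()
                current = None
            elif current is not None and ":" in line:
                tag, value = line.split(":", 1)
                tag = tag.strip()
                value = value.strip()
                if tag == "id":
                    current["id"] = value
                elif tag == "name":
                    current["name"] = value
                elif tag == "is_a":
                    current.setdefault("is_a", []).append(
                        value.split("!")[0].strip()
                    )
    flush()
    return terms
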