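import pytest
from hypothesis import settings

# keep the repo clean: no example database on disk
settings.register_profile("no_db", database=None, deadline=None)
settings.load_profile("no_db")

from genoprio.evidence_store import (
    DiseaseGeneRecord,
    DomainRecord,
    EvidenceStore,
    GeneConstraint,
    KnownVariantRecord,
    OntologyTerm,
    OrthologPhenotypeRecord,
)
from genoprio.io_formats import AAChange, RunConfig, VariantRecord
from genoprio.io_formats.records import HET, HOM_REF


def make_variant(**kwargs) -> VariantRecord:
    defaults = dict(
        chrom="chr1",
        pos=100,
        ref="C",
        alt="G",
        gene="KG1",
        func_class="exonic",
        exonic_func="nonsynonymous",
        aa_change=None,
        pop_af=None,
        genotypes={},
    )
    defaults.update(kwargs)
    return VariantRecord(**defaults)


def make_aa(gene="KG1", aa_ref="A", aa_pos=150, aa_alt="V") -> AAChange:
    return AAChange(gene, "NM_000001", aa_ref, aa_pos, aa_alt)


@pytest.fixture()
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture()
def hand_store() -> EvidenceStore:
    """A small, fully hand-specified store so oracles are hand-computable."""
    store = EvidenceStore()
    # ontology: root <- mid <- {leaf, leaf2}
    store.terms = {
        "HP:0000001": OntologyTerm("HP:0000001", "root", frozenset()),
        "HP:0000002": OntologyTerm("HP:0000002", "mid", frozenset({"HP:0000001"})),
        "HP:0000003": OntologyTerm("HP:0000003", "leaf", frozenset({"HP:0000002"})),
        "HP:0000004": OntologyTerm("HP:0000004", "leaf2", frozenset({"HP:0000002"})),
    }
    store.term_genes = {
        "HP:0000001": frozenset({"G_ROOT"}),
        "HP:0000002": frozenset({"G_MID"}),
        "HP:0000003": frozenset({"G_LEAF", "G_SHARED"}),
        "HP:0000004": frozenset({"G_SHARED"}),
    }
    store.disease_genes = frozenset(
        [
            DiseaseGeneRecord("MONDO:0000001", "KG1", "omim"),
            DiseaseGeneRecord("MONDO:0000001", "KG1", "orphanet"),
            DiseaseGeneRecord("MONDO:0000001", "KG1", "medgen"),
            DiseaseGeneRecord("MONDO:0000001", "KG1", "clinvar"),
            DiseaseGeneRecord("MONDO:0000001", "KG2", "omim"),
            DiseaseGeneRecord("MONDO:0000001", "KG2", "clinvar"),
            DiseaseGeneRecord("MONDO:0000002", "KG3", "orphanet"),
        ]
    )
    store.orthologs = frozenset(
        [
            OrthologPhenotypeRecord("MONDO:0000001", "G_MOUSE", "mouse"),
            OrthologPhenotypeRecord("MONDO:0000002", "G_MOUSE", "mouse"),
            OrthologPhenotypeRecord("MONDO:0000001", "G_FISH", "zebrafish"),
        ]
    )
    store.paralogues = {
        "KG1": frozenset({"P1"}),
        "KG2": frozenset({"P1", "P2"}),
        "P1": frozenset({"KG1", "KG2"}),
        "P2": frozenset({"KG2"}),
    }
    store.interactions = frozenset(
        [("I1", "KG1"), ("I1", "I2"), ("I2", "I3")]
    )
    store.expression = {
        ("G_E1", "heart"): 10.0,
        ("G_E2", "heart"): 0.5,
        ("G_E1", "brain"): 2.0,
    }
    store.constraint = {
        "KG1": GeneConstraint("KG1", 0.99, None),
        "LOWPLI": GeneConstraint("LOWPLI", 0.1, None),
        "HIGENE": GeneConstraint("HIGENE", None, True),
    }
    store.known_variants = frozenset(
        [
            KnownVariantRecord("KG1", "R", 100, "Q", "chr1", 5000, "C", "T",
                               "pathogenic", 2),
            KnownVariantRecord("KG1", None, None, None, "chr1", 6000, "G", "A",
                               "benign", 2),
            KnownVariantRecord("KG1", None, None, None, "chr1", 7000, "A", "G",
                               "pathogenic", 2),
            KnownVariantRecord("KG1", None, None, None, "chr1", 7000, "A", "G",
                               "likely_benign", 2),
            KnownVariantRecord("KG1", None, None, None, "chr1", 8000, "T", "C",
                               "pathogenic", 0),
        ]
    )
    store.domains = {
        "KG1": (
            DomainRecord("KG1", 40, 60, hotspot=True),
            DomainRecord("KG1", 200, 260, hotspot=False, repeat=True),
            DomainRecord("KG1", 300, 320, hotspot=False),
        ),
    }
    store.validate()
    return store


@pytest.fixture(scope="session")
def gen_store():
    from genoprio.evidence_store import generate_store

    return generate_store(7)


@pytest.fixture()
def trio_genotypes():
    return {"PROBAND": HET, "FATHER": HOM_REF, "MOTHER": HOM_REF}
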