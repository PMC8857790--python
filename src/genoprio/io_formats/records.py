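"""Domain records for variants and pedigrees.

Coordinates are 1-based as in VCF. Multi-allelic rows are split upstream so a
:class:`VariantRecord` always carries exactly one ALT allele; genotype calls
are expressed relative to that allele.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

# genotype call vocabulary
HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"
GENOTYPE_CALLS = (HOM_REF, HET, HOM_ALT, MISSING)

#: serialization of genotype calls back to a GT string
GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}

# canonical consequence-class vocabulary; ANNOVAR spellings map onto these
FRAMESHIFT = "frameshift"
STOPGAIN = "stopgain"
STOPLOSS = "stoploss"
NONFRAMESHIFT = "nonframeshift"
NONSYNONYMOUS = "nonsynonymous"
SYNONYMOUS = "synonymous"

_EXONIC_ALIASES = {
    "frameshift_deletion": FRAMESHIFT,
    "frameshift_insertion": FRAMESHIFT,
    "frameshift_substitution": FRAMESHIFT,
    "frameshift_block_substitution": FRAMESHIFT,
    "frameshift": FRAMESHIFT,
    "stopgain": STOPGAIN,
    "stopgain_snv": STOPGAIN,
    "stoploss": STOPLOSS,
    "stoploss_snv": STOPLOSS,
    "nonframeshift_deletion": NONFRAMESHIFT,
    "nonframeshift_insertion": NONFRAMESHIFT,
    "nonframeshift_substitution": NONFRAMESHIFT,
    "nonframeshift_block_substitution": NONFRAMESHIFT,
    "nonframeshift": NONFRAMESHIFT,
    "nonsynonymous_snv": NONSYNONYMOUS,
    "nonsynonymous": NONSYNONYMOUS,
    "synonymous_snv": SYNONYMOUS,
    "synonymous": SYNONYMOUS,
    "unknown": None,
}


def normalize_exonic_func(value: str | None) -> str | None:
    """Map an ANNOVAR consequence token onto the canonical vocabulary."""
    if value is None:
        return None
    token = str(value).strip().replace(" ", "_").replace("x3b", ";").lower()
    if token in ("", "."):
        return None
    return _EXONIC_ALIASES.get(token, token)


def normalize_func_class(value: str | None) -> str | None:
    if value is None:
        return None
    token = str(value).strip().lower()
    if token in ("", "."):
        return None
    # ANNOVAR may report "exonic;splicing" — splicing takes precedence for
    # null-variant logic, so keep the first splicing token if present
    parts = re.split(r"[;,]", token)
    if "splicing" in parts:
        return "splicing"
    return parts[0]


_AA_RE = re.compile(r"p\.([A-Za-z\*])(\d+)([A-Za-z\*0-9_]+)")


@dataclass(frozen=True)
class AAChange:
    """Protein change descriptor parsed from an ANNOVAR AAChange entry."""

    gene: str
    transcript: str
    aa_ref: str
    aa_pos: int
    aa_alt: str

    def __post_init__(self):
        if self.aa_pos < 1:
            raise ValueError(f"aa_pos must be positive, got {self.aa_pos}")


def parse_aa_change(value: str | None) -> AAChange | None:
    """Parse the first usable entry of an ANNOVAR ``AAChange`` INFO value.

    Entries look like ``GENE:NM_000001:exon2:c.89delC:p.P30Rfs*3``; multiple
    transcripts are comma-separated. Returns ``None`` when no entry carries a
    parseable ``p.`` descriptor.
    """
    if value is None or value in (".", ""):
        return None
    for entry in str(value).split(","):
        fields = entry.split(":")
        if len(fields) < 2:
            continue
        m = None
        for f in fields:
            m = _AA_RE.match(f)
            if m:
                break
        if not m:
            continue
        return AAChange(
            gene=fields[0],
            transcript=fields[1],
            aa_ref=m.group(1),
            aa_pos=int(m.group(2)),
            aa_alt=m.group(3),
        )
    return None


def format_aa_change(aa: AAChange) -> str:
    return f"{aa.gene}:{aa.transcript}:p.{aa.aa_ref}{aa.aa_pos}{aa.aa_alt}"


@dataclass
class VariantRecord:
    """One VCF row after multi-allelic splitting.

    ``raw`` retains the original column strings so untouched fields survive a
    read → write round trip byte-identically; it is excluded from equality.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    func_class: str | None = None
    exonic_func: str | None = None
    aa_change: AAChange | None = None
    pop_af: float | None = None
    genotypes: dict[str, str] = field(default_factory=dict)
    raw: dict | None = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.pop_af is not None and not (0.0 <= self.pop_af <= 1.0):
            raise ValueError(f"pop_af out of [0,1]: {self.pop_af}")
        for sample, call in self.genotypes.items():
            if call not in GENOTYPE_CALLS:
                raise ValueError(f"bad genotype call {call!r} for sample {sample}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Genomic identity used for matching and deterministic ordering."""
        return (self.chrom, self.pos, self.ref, self.alt)


# pedigree -------------------------------------------------------------------

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"
AFFECTED = "affected"
UNAFFECTED = "unaffected"


@dataclass(frozen=True)
class PedigreeRecord:
    family_id: str
    sample_id: str
    father_id: str | None
    mother_id: str | None
    sex: str
    affected: str
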