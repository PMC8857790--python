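"""VCF reading/writing for the ANNOVAR-annotated dialect.

Reading is backed by cyvcf2/htslib; a cheap structural pre-scan first checks
row shape so parse errors can name the offending line. Multi-allelic rows are
split into one :class:`VariantRecord` per ALT allele, with genotype calls and
Number=A INFO values resolved per allele.
"""
from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from cyvcf2 import VCF

from ..errors import VcfParseError
from .records import (
    GT_STRINGS,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    AAChange,
    VariantRecord,
    format_aa_change,
    normalize_exonic_func,
    normalize_func_class,
    parse_aa_change,
)

#: logical field → INFO key, following ANNOVAR refGene conventions
DEFAULT_KEY_MAP = {
    "gene": "Gene.refGene",
    "func_class": "Func.refGene",
    "exonic_func": "ExonicFunc.refGene",
    "aa_change": "AAChange.refGene",
    "pop_af": "gnomAD_genome_ALL",
}

_DEFAULT_INFO_DEFS = {
    "Gene.refGene": ("1", "String", "Gene symbol"),
    "Func.refGene": ("1", "String", "Genomic region class"),
    "ExonicFunc.refGene": ("1", "String", "Exonic consequence class"),
    "AAChange.refGene": ("1", "String", "Amino acid change"),
    "gnomAD_genome_ALL": ("1", "Float", "Population allele frequency"),
}


def _prescan(path) -> None:
    """Structural sanity pass so errors can cite a 1-based line number."""
    n_cols = None
    saw_header = False
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                n_cols = len(line.rstrip("\n").split("\t"))
                if n_cols < 8:
                    raise VcfParseError(
                        f"line {lineno}: #CHROM header has {n_cols} columns, expected >= 8"
                    )
                continue
            if not line.strip():
                continue
            if not saw_header:
                raise VcfParseError(f"line {lineno}: data row before #CHROM header")
            cols = line.rstrip("\n").split("\t")
            if len(cols) != n_cols:
                raise VcfParseError(
                    f"line {lineno}: expected {n_cols} columns, found {len(cols)}"
                )
            if not cols[1].isdigit():
                raise VcfParseError(f"line {lineno}: POS {cols[1]!r} is not an integer")
    if not saw_header:
        raise VcfParseError("missing #CHROM header line")


def _info_value(variant, key: str, alt_index: int, n_alt: int):
    try:
        value = variant.INFO.get(key)
    except KeyError:
        return None
    if value is None:
        return None
    if isinstance(value, tuple):
        value = value[alt_index] if len(value) == n_alt else value[0]
    if isinstance(value, bytes):
        value = value.decode()
    if isinstance(value, str) and value.strip() in (".", ""):
        return None
    return value


def _genotype_call(alleles: Sequence[int], alt_number: int) -> str:
    if any(a < 0 for a in alleles):
        return MISSING
    copies = sum(1 for a in alleles if a == alt_number)
    if copies == 0:
        return HOM_REF
    if copies == 1:
        return HET
    return HOM_ALT


def read_vcf(path, key_map: Mapping[str, str] | None = None) -> list[VariantRecord]:
    """Read an annotated VCF into VariantRecords, splitting multi-allelic rows.

    ``key_map`` overrides entries of :data:`DEFAULT_KEY_MAP`. Missing INFO
    keys yield null fields; a key named in the map but absent from the header
    triggers a warning, not an error.
    """
    path = str(path)
    keys = dict(DEFAULT_KEY_MAP)
    if key_map:
        keys.update(key_map)
    _prescan(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib failures carry no line info
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    header_ids = set(re.findall(r"##INFO=<ID=([^,>]+)", vcf.raw_header))
    for logical, key in keys.items():
        if key not in header_ids:
            warnings.warn(
                f"INFO key {key!r} (mapped from {logical!r}) not declared in header of {path}",
                stacklevel=2,
            )
    header_lines = [
        ln for ln in vcf.raw_header.splitlines() if ln.startswith("##")
    ]
    samples = list(vcf.samples)

    records: list[VariantRecord] = []
    try:
        for variant in vcf:
            raw_cols = str(variant).rstrip("\n").split("\t")
            alts = list(variant.ALT)
            n_alt = len(alts)
            genotype_rows = variant.genotypes if samples else []
            for i, alt in enumerate(alts):
                gene = _info_value(variant, keys["gene"], i, n_alt)
                func_class = normalize_func_class(
                    _info_value(variant, keys["func_class"], i, n_alt)
                )
                exonic_func = normalize_exonic_func(
                    _info_value(variant, keys["exonic_func"], i, n_alt)
                )
                aa_change = parse_aa_change(
                    _info_value(variant, keys["aa_change"], i, n_alt)
                )
                af_raw = _info_value(variant, keys["pop_af"], i, n_alt)
                pop_af = None
                if af_raw is not None:
                    try:
                        pop_af = float(af_raw)
                    except (TypeError, ValueError):
                        warnings.warn(
                            f"unparseable allele frequency {af_raw!r} at "
                            f"{variant.CHROM}:{variant.POS}; treated as missing"
                        )
                genotypes = {}
                for sample, row in zip(samples, genotype_rows):
                    genotypes[sample] = _genotype_call(list(row[:-1]), i + 1)
                records.append(
                    VariantRecord(
                        chrom=variant.CHROM,
                        pos=variant.POS,
                        ref=variant.REF,
                        alt=str(alt),
                        gene=str(gene) if gene is not None else None,
                        func_class=func_class,
                        exonic_func=exonic_func,
                        aa_change=aa_change,
                        pop_af=pop_af,
                        genotypes=genotypes,
                        raw={
                            "id": raw_cols[2],
                            "qual": raw_cols[5],
                            "filter": raw_cols[6],
                            "info": raw_cols[7],
                            "format": raw_cols[8] if len(raw_cols) > 8 else None,
                            "samples": raw_cols[9:],
                            "header": header_lines,
                            "n_alt": n_alt,
                        },
                    )
                )
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"malformed VCF row in {path}: {exc}") from exc
    finally:
        vcf.close()
    return records


def sanitize_info_value(value) -> str:
    """Make a value safe for an INFO field (no spaces/semicolons/equals)."""
    text = str(value)
    return (
        text.replace("%", "%25")
        .replace(";", "%3B")
        .replace("=", "%3D")
        .replace(" ", "_")
        .replace("\t", "_")
        .replace("\n", "|")
    )


def _build_info(record: VariantRecord, keys: Mapping[str, str]) -> str:
    parts = []
    if record.gene is not None:
        parts.append(f"{keys['gene']}={sanitize_info_value(record.gene)}")
    if record.func_class is not None:
        parts.append(f"{keys['func_class']}={sanitize_info_value(record.func_class)}")
    if record.exonic_func is not None:
        parts.append(f"{keys['exonic_func']}={sanitize_info_value(record.exonic_func)}")
    if record.aa_change is not None:
        parts.append(f"{keys['aa_change']}={format_aa_change(record.aa_change)}")
    if record.pop_af is not None:
        parts.append(f"{keys['pop_af']}={record.pop_af:g}")
    return ";".join(parts) if parts else "."


def write_vcf(
    records: Sequence[VariantRecord],
    path,
    annotations: Sequence[Mapping[str, object]] | Mapping[int, Mapping[str, object]] | None = None,
    info_defs: Mapping[str, tuple[str, str, str]] | None = None,
    samples: Sequence[str] | None = None,
    key_map: Mapping[str, str] | None = None,
) -> Path:
    """Write records to a plain-text VCF, preserving untouched raw fields.

    ``annotations`` supplies extra INFO keys per record (aligned sequence or
    index-keyed mapping); every new key is declared in the header, either via
    ``info_defs`` (key → (Number, Type, Description)) or a generic String
    definition.
    """
    path = Path(path)
    keys = dict(DEFAULT_KEY_MAP)
    if key_map:
        keys.update(key_map)

    def record_annotations(i: int) -> Mapping[str, object]:
        if annotations is None:
            return {}
        if isinstance(annotations, Mapping):
            return annotations.get(i, {})
        return annotations[i]

    if samples is None:
        samples = []
        for rec in records:
            for s in rec.genotypes:
                if s not in samples:
                    samples.append(s)
    samples = list(samples)

    # header: reuse the source header when available so original INFO/contig
    # definitions survive the round trip
    base_header: list[str] | None = None
    for rec in records:
        if rec.raw and rec.raw.get("header"):
            base_header = list(rec.raw["header"])
            break
    header: list[str] = ["##fileformat=VCFv4.2"]
    declared: set[str] = set()
    if base_header is not None:
        for line in base_header:
            if line.startswith("##fileformat"):
                continue
            header.append(line)
        declared |= set(re.findall(r"##INFO=<ID=([^,>]+)", "\n".join(base_header)))
    else:
        for key, (num, typ, desc) in _DEFAULT_INFO_DEFS.items():
            mapped = keys.get(
                {v: k for k, v in DEFAULT_KEY_MAP.items()}.get(key, ""), key
            )
            header.append(
                f'##INFO=<ID={mapped},Number={num},Type={typ},Description="{desc}">'
            )
            declared.add(mapped)
        if samples:
            header.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')

    declared_contigs = {
        m for line in header for m in re.findall(r"##contig=<ID=([^,>]+)", line)
    }
    seen_contigs: list[str] = []
    for rec in records:
        if rec.chrom not in declared_contigs and rec.chrom not in seen_contigs:
            seen_contigs.append(rec.chrom)
    for chrom in seen_contigs:
        header.append(f"##contig=<ID={chrom}>")

    new_keys: list[str] = []
    for i in range(len(records)):
        for k in record_annotations(i):
            if k not in declared and k not in new_keys:
                new_keys.append(k)
    for k in new_keys:
        num, typ, desc = (info_defs or {}).get(k, (".", "String", k))
        header.append(f'##INFO=<ID={k},Number={num},Type={typ},Description="{desc}">')

    columns = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        columns += ["FORMAT"] + samples
    header.append("\t".join(columns))

    lines = []
    for i, rec in enumerate(records):
        extra = record_annotations(i)
        raw = rec.raw or {}
        info = raw.get("info") if raw else None
        if info is None:
            info = _build_info(rec, keys)
        if extra:
            added = ";".join(
                k if v is True or v == "" else f"{k}={sanitize_info_value(v)}"
                for k, v in extra.items()
            )
            info = added if info == "." else f"{info};{added}"
        row = [
            rec.chrom,
            str(rec.pos),
            raw.get("id", "."),
            rec.ref,
            rec.alt,
            raw.get("qual", "."),
            raw.get("filter", "."),
            info,
        ]
        if samples:
            if raw.get("format") and raw.get("samples") and raw.get("n_alt") == 1:
                row.append(raw["format"])
                row.extend(raw["samples"])
            else:
                row.append("GT")
                row.extend(GT_STRINGS[rec.genotypes.get(s, MISSING)] for s in samples)
        lines.append("\t".join(row))

    with open(path, "wt") as fh:
        fh.write("\n".join(header + lines))
        fh.write("\n")
    return path
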