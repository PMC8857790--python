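"""Six-column PED file reading."""
from __future__ import annotations

from pathlib import Path
from typing import Iterable

from ..errors import PedParseError
from .records import AFFECTED, FEMALE, MALE, UNAFFECTED, UNKNOWN, PedigreeRecord

_SEX = {"1": MALE, "2": FEMALE}
_AFFECTED = {"1": UNAFFECTED, "2": AFFECTED}


def read_ped(path) -> list[PedigreeRecord]:
    """Parse a whitespace-delimited 6-column PED file.

    ``0`` in a parent column parses to ``None``; sex/affection codes outside
    the standard 1/2 encoding map to ``unknown``. Duplicate sample ids and
    rows with the wrong column count raise :class:`PedParseError` naming the
    line.
    """
    records: list[PedigreeRecord] = []
    seen: set[str] = set()
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 6:
                raise PedParseError(
                    f"line {lineno}: expected 6 columns, found {len(cols)}"
                )
            family_id, sample_id, father, mother, sex, aff = cols
            if sample_id in seen:
                raise PedParseError(f"line {lineno}: duplicate sample_id {sample_id!r}")
            seen.add(sample_id)
            records.append(
                PedigreeRecord(
                    family_id=family_id,
                    sample_id=sample_id,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=_SEX.get(sex, UNKNOWN),
                    affected=_AFFECTED.get(aff, UNKNOWN),
                )
            )
    return records


def write_ped(records: Iterable[PedigreeRecord], path) -> Path:
    path = Path(path)
    sex_code = {MALE: "1", FEMALE: "2", UNKNOWN: "0"}
    aff_code = {UNAFFECTED: "1", AFFECTED: "2", UNKNOWN: "0"}
    with open(path, "wt") as fh:
        for rec in records:
            fh.write(
                "\t".join(
                    [
                        rec.family_id,
                        rec.sample_id,
                        rec.father_id or "0",
                        rec.mother_id or "0",
                        sex_code[rec.sex],
                        aff_code[rec.affected],
                    ]
                )
                + "\n"
            )
    return path
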