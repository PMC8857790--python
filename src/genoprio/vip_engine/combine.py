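"""Combine evidence-criterion flags into the five-tier pathogenicity call."""
from __future__ import annotations

from typing import Mapping

PATHOGENIC = "pathogenic"
LIKELY_PATHOGENIC = "likely_pathogenic"
UNCERTAIN = "uncertain"
LIKELY_BENIGN = "likely_benign"
BENIGN = "benign"

CALLS = (BENIGN, LIKELY_BENIGN, UNCERTAIN, LIKELY_PATHOGENIC, PATHOGENIC)

#: ordinal used by the causality scatter (benign=1 ... pathogenic=5)
CALL_ORDINAL = {call: i + 1 for i, call in enumerate(CALLS)}

PS_CRITERIA = ("PS1", "PS2", "PS3", "PS4")
PM_CRITERIA = ("PM1", "PM2", "PM3", "PM4", "PM5", "PM6")
PP_CRITERIA = ("PP1", "PP2", "PP3", "PP4", "PP5")
BS_CRITERIA = ("BS1", "BS2", "BS3", "BS4")
BP_CRITERIA = ("BP1", "BP2", "BP3", "BP4", "BP5", "BP6", "BP7")

#: the full 28-criterion vocabulary accepted by the combiner
ALL_CRITERIA = (
    ("PVS1",) + PS_CRITERIA + PM_CRITERIA + PP_CRITERIA
    + ("BA1",) + BS_CRITERIA + BP_CRITERIA
)

#: criteria with built-in evaluators; the rest may be supplied externally
IMPLEMENTED_CRITERIA = (
    "PVS1", "PS1", "PS2", "PM1", "PM2", "PM4", "PM5", "PP5",
    "BA1", "BS1", "BP3", "BP6", "BP7",
)


def combine_criteria(flags: Mapping[str, bool]) -> str:
    """Map a boolean criteria profile to one of the five calls.

    Follows the standard combining rules; when a pathogenic-side and a
    benign-side rule both fire, the conflict resolves to ``uncertain``.
    Criteria absent from the mapping count as False.
    """
    f = {c: bool(flags.get(c, False)) for c in ALL_CRITERIA}
    pvs = f["PVS1"]
    n_ps = sum(f[c] for c in PS_CRITERIA)
    n_pm = sum(f[c] for c in PM_CRITERIA)
    n_pp = sum(f[c] for c in PP_CRITERIA)
    ba1 = f["BA1"]
    n_bs = sum(f[c] for c in BS_CRITERIA)
    n_bp = sum(f[c] for c in BP_CRITERIA)

    pathogenic = (
        (pvs and (n_ps >= 1 or n_pm >= 2 or (n_pm == 1 and n_pp == 1) or n_pp >= 2))
        or n_ps >= 2
        or (
            n_ps == 1
            and (
                n_pm >= 3
                or (n_pm == 2 and n_pp >= 2)
                or (n_pm == 1 and n_pp >= 4)
            )
        )
    )
    likely_pathogenic = (
        (pvs and n_pm == 1)
        or (n_ps == 1 and 1 <= n_pm <= 2)
        or (n_ps == 1 and n_pp >= 2)
        or n_pm >= 3
        or (n_pm == 2 and n_pp >= 2)
        or (n_pm == 1 and n_pp >= 4)
    )
    benign = ba1 or n_bs >= 2
    likely_benign = (n_bs == 1 and n_bp >= 1) or n_bp >= 2

    pathogenic_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if pathogenic_side and benign_side:
        return UNCERTAIN
    if pathogenic:
        return PATHOGENIC
    if likely_pathogenic:
        return LIKELY_PATHOGENIC
    if benign:
        return BENIGN
    if likely_benign:
        return LIKELY_BENIGN
    return UNCERTAIN
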