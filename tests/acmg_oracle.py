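"""Independent re-implementation of the criteria-combining rules, coded as
explicit rule tables over prefix counts. Kept deliberately different in
structure from the production combiner so it can serve as its oracle."""

_PATHOGENIC_RULES = (
    {"PVS": 1, "PS": 1},
    {"PVS": 1, "PM": 2},
    {"PVS": 1, "PM": 1, "PP": 1},
    {"PVS": 1, "PP": 2},
    {"PS": 2},
    {"PS": 1, "PM": 3},
    {"PS": 1, "PM": 2, "PP": 2},
    {"PS": 1, "PM": 1, "PP": 4},
)

_LIKELY_PATHOGENIC_RULES = (
    {"PVS": 1, "PM": 1},
    {"PS": 1, "PM": 1},
    {"PS": 1, "PP": 2},
    {"PM": 3},
    {"PM": 2, "PP": 2},
    {"PM": 1, "PP": 4},
)

_BENIGN_RULES = ({"BA": 1}, {"BS": 2})

_LIKELY_BENIGN_RULES = ({"BS": 1, "BP": 1}, {"BP": 2})


def _counts(flags):
    counts = {"PVS": 0, "PS": 0, "PM": 0, "PP": 0, "BA": 0, "BS": 0, "BP": 0}
    for criterion, value in flags.items():
        if not value:
            continue
        if criterion == "PVS1":
            counts["PVS"] += 1
        elif criterion == "BA1":
            counts["BA"] += 1
        else:
            prefix = criterion[:2]
            if prefix in counts:
                counts[prefix] += 1
    return counts


def _fires(counts, rules):
    return any(
        all(counts[category] >= needed for category, needed in rule.items())
        for rule in rules
    )


def oracle_call(flags) -> str:
    counts = _counts(flags)
    pathogenic = _fires(counts, _PATHOGENIC_RULES)
    likely_pathogenic = _fires(counts, _LIKELY_PATHOGENIC_RULES)
    benign = _fires(counts, _BENIGN_RULES)
    likely_benign = _fires(counts, _LIKELY_BENIGN_RULES)
    if (pathogenic or likely_pathogenic) and (benign or likely_benign):
        return "uncertain"
    if pathogenic:
        return "pathogenic"
    if likely_pathogenic:
        return "likely_pathogenic"
    if benign:
        return "benign"
    if likely_benign:
        return "likely_benign"
    return "uncertain"
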