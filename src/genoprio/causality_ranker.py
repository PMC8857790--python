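"""Causality binning, ranking, scatter export, and polygon (lasso) filtering.

The four review bins combine the pathogenicity call with the gene status:
P/LP in a known gene (bin 1), in a candidate gene (bin 2), in a novel gene
(bin 3), and VUS in a known gene (bin 4). Every other combination is left
unbinned; within bins variants are ranked by descending validity score with a
genomic-coordinate tie-break for determinism.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import GenoprioError
from .io_formats.records import VariantRecord
from .validity_engine import CANDIDATE, KNOWN, NOVEL, ValidityResult
from .vip_engine.combine import (
    CALL_ORDINAL,
    LIKELY_PATHOGENIC,
    PATHOGENIC,
    UNCERTAIN,
)
from .vip_engine.criteria import ACMGAssessment

#: scatter color per tier, dark green (benign) through red (pathogenic)
TIER_COLORS = {
    "benign": "darkgreen",
    "likely_benign": "lightgreen",
    "uncertain": "gold",
    "likely_pathogenic": "orange",
    "pathogenic": "red",
}


@dataclass
class RankedVariant:
    variant: VariantRecord
    call: str
    validity_score: float
    gene_status: str
    bin: int | None = None
    rank: int | None = None
    sample: str | None = None


@dataclass(frozen=True)
class ScatterPoint:
    x: float  # validity score
    y: int  # pathogenicity ordinal, benign=1 ... pathogenic=5
    key: tuple[str, int, str, str]
    color: str


@dataclass
class LassoPolygon:
    vertices: list[tuple[float, float]]

    def __post_init__(self):
        if len(self.vertices) < 3:
            raise GenoprioError("polygon needs at least 3 vertices")
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]

    def area(self) -> float:
        total = 0.0
        n = len(self.vertices)
        for i in range(n):
            x1, y1 = self.vertices[i]
            x2, y2 = self.vertices[(i + 1) % n]
            total += x1 * y2 - x2 * y1
        return abs(total) / 2.0


def _bin_for(call: str, status: str) -> int | None:
    plp = call in (PATHOGENIC, LIKELY_PATHOGENIC)
    if plp and status == KNOWN:
        return 1
    if plp and status == CANDIDATE:
        return 2
    if plp and status == NOVEL:
        return 3
    if call == UNCERTAIN and status == KNOWN:
        return 4
    return None


def assign_bins(
    records: Sequence[VariantRecord],
    assessments: Sequence[ACMGAssessment],
    validity: dict[str, ValidityResult],
    sample: str | None = None,
) -> list[RankedVariant]:
    """Pair each variant's call with its gene's validity and assign a bin.

    Genes without a validity result (including null genes) score 0 / novel.
    """
    if len(records) != len(assessments):
        raise GenoprioError("records and assessments differ in length")
    ranked = []
    for rec, assessment in zip(records, assessments):
        res = validity.get(rec.gene) if rec.gene else None
        score = res.score if res else 0.0
        status = res.status if res else NOVEL
        ranked.append(
            RankedVariant(
                variant=rec,
                call=assessment.call,
                validity_score=score,
                gene_status=status,
                bin=_bin_for(assessment.call, status),
                sample=sample,
            )
        )
    return ranked


def rank_variants(binned: Iterable[RankedVariant]) -> list[RankedVariant]:
    """Total order: bin ascending, validity descending, coordinate tie-break.

    Binned variants get 1-based ranks; unbinned ones are appended unranked.
    """
    items = list(binned)
    with_bin = [rv for rv in items if rv.bin is not None]
    without = [rv for rv in items if rv.bin is None]
    with_bin.sort(key=lambda rv: (rv.bin, -rv.validity_score, rv.variant.key))
    without.sort(key=lambda rv: rv.variant.key)
    for i, rv in enumerate(with_bin, 1):
        rv.rank = i
    for rv in without:
        rv.rank = None
    return with_bin + without


def scatter_points(ranked: Iterable[RankedVariant]) -> list[ScatterPoint]:
    return [
        ScatterPoint(
            x=rv.validity_score,
            y=CALL_ORDINAL[rv.call],
            key=rv.variant.key,
            color=TIER_COLORS[rv.call],
        )
        for rv in ranked
    ]


def scatter_export(
    ranked: Sequence[RankedVariant],
    tsv_path=None,
    plot_path=None,
) -> list[ScatterPoint]:
    """One point per variant in validity-vs-pathogenicity space; optionally
    writes a TSV of points and a static plot."""
    points = scatter_points(ranked)
    if tsv_path is not None:
        with open(tsv_path, "wt") as fh:
            fh.write("chrom\tpos\tref\talt\tvalidity\ttier_ordinal\tcolor\n")
            for p in points:
                chrom, pos, ref, alt = p.key
                fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{p.x:g}\t{p.y}\t{p.color}\n")
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        ax.scatter(
            [p.x for p in points],
            [p.y for p in points],
            c=[p.color for p in points],
            alpha=0.7,
            edgecolors="none",
        )
        ax.set_xlabel("gene validity score")
        ax.set_ylabel("pathogenicity tier")
        ax.set_yticks(range(1, 6))
        ax.set_yticklabels(
            ["benign", "likely benign", "uncertain", "likely pathogenic", "pathogenic"]
        )
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return points


def point_in_polygon(
    x: float, y: float, vertices: Sequence[tuple[float, float]], eps: float = 1e-9
) -> bool:
    """Even-odd rule with an inclusive boundary."""
    n = len(vertices)
    # boundary first: a point on any edge counts as selected
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) <= eps:
            if min(x1, x2) - eps <= x <= max(x1, x2) + eps and \
               min(y1, y2) - eps <= y <= max(y1, y2) + eps:
                return True
    inside = False
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


def lasso_filter(
    points: Sequence[ScatterPoint], polygon: LassoPolygon
) -> list[tuple[str, int, str, str]]:
    """Variant keys whose scatter point lies inside or on the polygon."""
    if polygon.area() == 0.0:
        warnings.warn("degenerate (zero-area) polygon: only boundary points selected")
    return [
        p.key for p in points if point_in_polygon(p.x, p.y, polygon.vertices)
    ]


def write_ranked_tsv(ranked: Sequence[RankedVariant], path) -> Path:
    path = Path(path)
    with open(path, "wt") as fh:
        fh.write(
            "rank\tbin\tchrom\tpos\tref\talt\tgene\tcall\tvalidity_score\t"
            "gene_status\tsample\n"
        )
        for rv in ranked:
            v = rv.variant
            fh.write(
                f"{rv.rank if rv.rank is not None else '.'}\t"
                f"{rv.bin if rv.bin is not None else '.'}\t"
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.gene or '.'}\t"
                f"{rv.call}\t{rv.validity_score:g}\t{rv.gene_status}\t"
                f"{rv.sample or '.'}\n"
            )
    return path
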