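"""Classification of circRNAs against a gene annotation.

Each high-confidence circRNA is assigned one of four types by a decision
cascade (first match wins):

1. exonic     — both junction ends fall on exons of one same-strand gene;
2. intronic   — the circle lies entirely inside one intron of a
                same-strand gene;
3. antisense  — the circle overlaps a gene only on the opposite strand;
4. intergenic — no gene overlap at all.

Exonic circRNAs additionally get an exon count and the flanking introns
immediately up/downstream of the circularized exon block.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass

from intervaltree import IntervalTree

from .circ_consensus import CircRNA
from .genome_io import GeneModel

CIRC_TYPES = ("exonic", "intronic", "intergenic", "antisense")


@dataclass(frozen=True)
class ClassifiedCirc:
    circ: CircRNA
    circ_type: str
    parental_gene: str | None
    n_exons: int | None
    flanking_intron_left: tuple[int, int] | None
    flanking_intron_right: tuple[int, int] | None

    @property
    def key(self) -> str:
        return self.circ.key


class GeneIndex:
    """Interval index over gene spans for overlap queries."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = {g.gene_id: g for g in genes}
        self.trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for g in genes:
            s, e = g.span
            self.trees[g.chrom].addi(s, e, g.gene_id)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        if chrom not in self.trees:
            return []
        hits = self.trees[chrom].overlap(start, end)
        return [self.genes[h.data] for h in sorted(hits, key=lambda h: h.data)]


def _end_on_exon(pos_start: int, pos_end: int, gene: GeneModel, tol: int) -> bool:
    """True when both circle ends sit within (or at boundaries of) exons."""

    def within(pos: int, as_end: bool) -> bool:
        for s, e in gene.exons:
            if as_end:
                # an end coordinate is exon-compatible if pos in (s, e]
                if s - tol < pos <= e + tol:
                    return True
            else:
                if s - tol <= pos < e + tol:
                    return True
        return False

    return within(pos_start, as_end=False) and within(pos_end, as_end=True)


def _inside_one_intron(start: int, end: int, gene: GeneModel) -> bool:
    return any(s <= start and end <= e for s, e in gene.introns)


def count_exons(circ: CircRNA, gene: GeneModel) -> int:
    """Number of gene exons intersecting the circle's genomic span."""
    n = sum(1 for s, e in gene.exons if s < circ.end and e > circ.start)
    if n == 0:
        raise ValueError(f"{circ.key} is not exonic in gene {gene.gene_id}")
    return n


def _flanking_introns(
    circ: CircRNA, gene: GeneModel
) -> tuple[tuple[int, int] | None, tuple[int, int] | None]:
    left = right = None
    for s, e in gene.introns:
        if e <= circ.start and (left is None or e > left[1]):
            left = (s, e)
        if s >= circ.end and (right is None or s < right[0]):
            right = (s, e)
    return left, right


def _pick_parental(circ: CircRNA, candidates: list[GeneModel]) -> GeneModel:
    """Gene covering the largest fraction of the circle; ties by gene_id."""

    def coverage(g: GeneModel) -> int:
        s, e = g.span
        return max(0, min(e, circ.end) - max(s, circ.start))

    return sorted(candidates, key=lambda g: (-coverage(g), g.gene_id))[0]


def assign_type(
    circ: CircRNA, index: GeneIndex, boundary_tolerance: int = 0
) -> ClassifiedCirc:
    """Apply the type cascade to one circRNA."""
    if circ.chrom not in index.trees:
        warnings.warn(
            f"{circ.key}: chromosome absent from annotation; "
            "classified intergenic",
            stacklevel=2,
        )
        return ClassifiedCirc(circ, "intergenic", None, None, None, None)

    overlapping = index.overlapping(circ.chrom, circ.start, circ.end)
    same = [g for g in overlapping if g.strand == circ.strand]

    exonic = [
        g for g in same
        if _end_on_exon(circ.start, circ.end, g, boundary_tolerance)
    ]
    if exonic:
        gene = _pick_parental(circ, exonic)
        left, right = _flanking_introns(circ, gene)
        return ClassifiedCirc(
            circ, "exonic", gene.gene_id, count_exons(circ, gene), left, right
        )

    intronic = [g for g in same if _inside_one_intron(circ.start, circ.end, g)]
    if intronic:
        gene = _pick_parental(circ, intronic)
        intron = next(
            (s, e) for s, e in gene.introns if s <= circ.start and circ.end <= e
        )
        return ClassifiedCirc(circ, "intronic", gene.gene_id, None, intron, intron)

    # any same-strand overlap that is neither exonic nor intronic still has a
    # parental gene (junctions inside exon/intron mixtures); treat as exonic
    # candidates failing the boundary rule -> fall through to antisense only
    # when no same-strand gene overlaps at all.
    if same:
        gene = _pick_parental(circ, same)
        left, right = _flanking_introns(circ, gene)
        return ClassifiedCirc(circ, "exonic", gene.gene_id,
                              count_exons(circ, gene), left, right)

    if overlapping:  # opposite strand only
        gene = _pick_parental(circ, overlapping)
        return ClassifiedCirc(circ, "antisense", gene.gene_id, None, None, None)

    return ClassifiedCirc(circ, "intergenic", None, None, None, None)


def classify_all(
    circs: list[CircRNA], genes: list[GeneModel], boundary_tolerance: int = 0
) -> list[ClassifiedCirc]:
    index = GeneIndex(genes)
    return [assign_type(c, index, boundary_tolerance) for c in circs]


def parental_gene_table(classified: list[ClassifiedCirc]) -> dict[str, list[str]]:
    """Inverse index parental gene -> circRNA keys (exonic and intronic)."""
    table: dict[str, list[str]] = defaultdict(list)
    for c in classified:
        if c.parental_gene is not None and c.circ_type in ("exonic", "intronic"):
            table[c.parental_gene].append(c.key)
    return dict(table)


def write_classified(classified: list[ClassifiedCirc], path) -> None:
    def fmt(iv: tuple[int, int] | None) -> str:
        return f"{iv[0]}-{iv[1]}" if iv else "."

    with open(path, "w") as fh:
        fh.write("key\ttype\tparental_gene\tn_exons\tflank_left\tflank_right\n")
        for c in classified:
            fh.write("\t".join([
                c.key, c.circ_type, c.parental_gene or ".",
                str(c.n_exons) if c.n_exons is not None else ".",
                fmt(c.flanking_intron_left), fmt(c.flanking_intron_right),
            ]) + "\n")


def type_summary(classified: list[ClassifiedCirc]) -> dict:
    """Counts and percentages of the four circRNA types."""
    counts = {t: 0 for t in CIRC_TYPES}
    for c in classified:
        counts[c.circ_type] += 1
    total = len(classified)
    pct = {
        t: (100.0 * n / total) if total else 0.0 for t, n in counts.items()
    }
    return {"counts": counts, "percent": pct, "total": total}
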