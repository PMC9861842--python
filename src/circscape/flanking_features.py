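"""Features of circRNA flanking introns versus sampled linear-gene background.

Circularization in plants correlates with long, repeat-rich, hypermethylated
flanking introns. This module measures those properties (repeat coverage,
weighted methylation, lengths) for a set of intervals and compares circRNA
flanking introns against an equally sized random sample of genes without
detectable circRNAs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome_io import GeneModel, MethylationTrack, RepeatInterval


@dataclass
class FeatureComparison:
    feature: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    t_statistic: float
    p_value: float
    mannwhitney_p: float
    log10_transformed: bool


def sample_background(
    genes_without_circ: list[GeneModel], n: int, seed: int
) -> list[GeneModel]:
    """Uniform sample of n background genes, without replacement."""
    if n > len(genes_without_circ):
        raise ValueError(
            f"background pool ({len(genes_without_circ)}) smaller than n={n}"
        )
    rng = np.random.default_rng(seed)
    order = sorted(genes_without_circ, key=lambda g: g.gene_id)
    idx = rng.choice(len(order), size=n, replace=False)
    return [order[i] for i in sorted(idx)]


def _merged_overlaps(
    start: int, end: int, repeats: list[RepeatInterval], chrom: str
) -> list[tuple[int, int]]:
    clipped = sorted(
        (max(r.start, start), min(r.end, end))
        for r in repeats
        if r.chrom == chrom and r.start < end and r.end > start
    )
    merged: list[tuple[int, int]] = []
    for s, e in clipped:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def repeat_fraction(
    chrom: str, start: int, end: int, repeats: list[RepeatInterval]
) -> float:
    """Fraction of the interval covered by the union of repeat intervals."""
    if end <= start:
        raise ValueError(f"zero-length interval [{start},{end})")
    covered = sum(e - s for s, e in _merged_overlaps(start, end, repeats, chrom))
    return covered / (end - start)


def repeat_class_breakdown(
    intervals: list[tuple[str, int, int]], repeats: list[RepeatInterval]
) -> dict:
    """bp of each repeat class inside the interval set, as fractions.

    Classes are measured independently (per-class union within each
    interval), then normalized by the total repeat bp, so the fractions sum
    to 1 whenever any repeat bp exists.
    """
    classes = sorted({r.repeat_class for r in repeats}) or []
    bp = {c: 0 for c in classes}
    for chrom, start, end in intervals:
        for c in classes:
            sub = [r for r in repeats if r.repeat_class == c]
            bp[c] += sum(
                e - s for s, e in _merged_overlaps(start, end, sub, chrom)
            )
    total = sum(bp.values())
    if total == 0:
        return {"fractions": {c: 0.0 for c in classes}, "total_bp": 0,
                "empty": True}
    return {
        "fractions": {c: v / total for c, v in bp.items()},
        "total_bp": total,
        "empty": False,
    }


def weighted_methylation(
    chrom: str, start: int, end: int, track: MethylationTrack,
    context: str | None = None,
) -> float:
    """Sum(methylated reads) / sum(total reads) over cytosines in the interval.

    Returns NaN when the interval contains no covered cytosine.
    """
    recs = track.in_interval(chrom, start, end, context)
    total = sum(r.total for r in recs)
    if total == 0:
        return float("nan")
    return sum(r.methylated for r in recs) / total


def metagene_methylation_profile(
    intervals: list[tuple[str, int, int]],
    track: MethylationTrack,
    n_bins: int = 20,
    flank_bp: int = 2000,
    n_flank_bins: int = 10,
    context: str | None = None,
) -> dict:
    """Coverage-weighted methylation around a set of intervals.

    Each interval body is rescaled to ``n_bins`` bins; ``flank_bp`` of
    fixed-width sequence either side is split into ``n_flank_bins`` bins.
    Per bin, methylated and total read counts are pooled across intervals
    (coverage weighting), then divided.
    """
    if not intervals:
        raise ValueError("no intervals")
    total_bins = n_flank_bins + n_bins + n_flank_bins
    meth = np.zeros(total_bins)
    cov = np.zeros(total_bins)
    flank_w = flank_bp / n_flank_bins
    for chrom, start, end in intervals:
        body_w = (end - start) / n_bins
        for r in track.in_interval(chrom, start - flank_bp, end + flank_bp,
                                   context):
            if r.position < start:
                b = int((r.position - (start - flank_bp)) / flank_w)
                b = min(b, n_flank_bins - 1)
            elif r.position >= end:
                b = n_flank_bins + n_bins + min(
                    int((r.position - end) / flank_w), n_flank_bins - 1
                )
            else:
                b = n_flank_bins + min(
                    int((r.position - start) / body_w), n_bins - 1
                )
            meth[b] += r.methylated
            cov[b] += r.total
    with np.errstate(invalid="ignore"):
        profile = np.where(cov > 0, meth / np.maximum(cov, 1), np.nan)
    return {
        "profile": profile,
        "coverage": cov,
        "bin_labels": (
            [f"up_{i}" for i in range(n_flank_bins)]
            + [f"body_{i}" for i in range(n_bins)]
            + [f"down_{i}" for i in range(n_flank_bins)]
        ),
    }


def compare_groups(
    values_a, values_b, feature: str = "", log10_transform: bool = True,
    welch: bool = True,
) -> FeatureComparison:
    """Two-sided t-test between two groups, Welch by default.

    Length-like features are compared on the log10 scale; non-positive
    values are shifted by +1 before the transform (with a warning). A
    Mann-Whitney U p-value is reported alongside as a robustness column.
    """
    a = np.asarray([v for v in values_a if not np.isnan(v)], dtype=float)
    b = np.asarray([v for v in values_b if not np.isnan(v)], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    raw_a, raw_b = a.copy(), b.copy()
    if log10_transform:
        if (a <= 0).any() or (b <= 0).any():
            warnings.warn(
                "non-positive values under log10 transform; shifted by +1",
                stacklevel=2,
            )
            a, b = a + 1, b + 1
        a, b = np.log10(a), np.log10(b)
    t_stat, p = stats.ttest_ind(a, b, equal_var=not welch)
    if np.isnan(p):  # zero variance in both groups
        t_stat, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    try:
        mw_p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    except ValueError:  # all values identical
        mw_p = 1.0
    return FeatureComparison(
        feature=feature,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(raw_a.mean()),
        mean_b=float(raw_b.mean()),
        median_a=float(np.median(raw_a)),
        median_b=float(np.median(raw_b)),
        t_statistic=float(t_stat),
        p_value=float(p),
        mannwhitney_p=mw_p,
        log10_transformed=log10_transform,
    )
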