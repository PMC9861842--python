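"""Expression quantification and differential expression of junction counts.

circRNA abundance is expressed as RPB (junction reads per billion clean
reads) and linear genes as FPKM. Differential expression between two
conditions uses an exact negative-binomial test on library-size-equalized
counts with a common, method-of-moments dispersion — the small-sample
count-data approach standard for 3-replicate RNA-seq designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MIN_DISPERSION = 1e-4


@dataclass
class DEResult:
    feature_id: str
    log2_fc: float
    p_value: float
    p_adjusted: float
    mean_a: float
    mean_b: float
    direction: str  # up | down | ns


def rpb(junction_reads: float, clean_reads: float) -> float:
    """Junction reads per billion clean reads."""
    if clean_reads <= 0:
        raise ValueError("clean_reads must be positive")
    if junction_reads < 0:
        raise ValueError("junction_reads must be non-negative")
    return junction_reads / (clean_reads / 1e9)


def bin_expression(rpb_value: float) -> str:
    """Discretize RPB into low (<100), medium (100-500), high (>500)."""
    if rpb_value < 0:
        raise ValueError("RPB must be non-negative")
    if rpb_value < 100:
        return "low"
    if rpb_value <= 500:
        return "medium"
    return "high"


def fpkm(fragment_count: float, exonic_length_bp: float, total_mapped: float) -> float:
    """Fragments per kilobase of exon model per million mapped fragments."""
    if exonic_length_bp <= 0:
        raise ValueError("exonic length must be positive")
    if total_mapped <= 0:
        raise ValueError("total mapped fragments must be positive")
    return fragment_count / ((exonic_length_bp / 1000.0) * (total_mapped / 1e6))


# ---------------------------------------------------------------------------
# differential expression


def estimate_common_dispersion(counts: np.ndarray, groups: list[np.ndarray]) -> float:
    """Method-of-moments common NB dispersion on normalized counts.

    For each feature, the within-group sample variance v and group mean m
    give a moment estimate (v - m) / m^2; estimates are averaged across
    features and groups (weighted by degrees of freedom) and floored at
    ``MIN_DISPERSION``.
    """
    num = 0.0
    den = 0.0
    for idx in groups:
        sub = counts[:, idx]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        phi = (v[ok] - m[ok]) / m[ok] ** 2
        df = sub.shape[1] - 1
        num += phi.sum() * df
        den += ok.sum() * df
    if den == 0:
        return MIN_DISPERSION
    return max(num / den, MIN_DISPERSION)


def _exact_nb_test(s_a: int, s_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact test on group sums of NB counts at equal library sizes.

    Conditional on the total t = s_a + s_b, the null distribution of the
    group-A sum follows from S_a ~ NB(n_a*mu, phi/n_a) and
    S_b ~ NB(n_b*mu, phi/n_b) with mu = t/(n_a+n_b). The two-sided p-value
    sums the probabilities of all outcomes no more likely than the
    observed one.
    """
    t = s_a + s_b
    if t == 0:
        return 1.0
    mu = t / (n_a + n_b)
    size_a, size_b = n_a / phi, n_b / phi
    p_a = size_a / (size_a + n_a * mu)
    p_b = size_b / (size_b + n_b * mu)
    s = np.arange(t + 1)
    logp = stats.nbinom.logpmf(s, size_a, p_a) + stats.nbinom.logpmf(
        t - s, size_b, p_b
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[s_a]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-10)].sum()))


def de_test(
    matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    library_sizes: dict[str, float] | None = None,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    use_adjusted: bool = False,
) -> list[DEResult]:
    """Differential expression between two sample groups.

    ``matrix`` is features x samples of raw counts. Counts are scaled to a
    common (geometric-mean) library size and rounded to pseudo-counts, a
    common dispersion is estimated by the method of moments, and each
    feature gets a two-sided exact NB p-value on group sums, BH-adjusted
    across features. log2 fold change uses a 0.5 pseudocount on normalized
    group means. A feature is called up/down when |log2FC| exceeds
    ``lfc_threshold`` and its (adjusted, if ``use_adjusted``) p-value is at
    most ``alpha``.
    """
    for s in list(group_a) + list(group_b):
        if s not in matrix.columns:
            raise KeyError(f"sample {s!r} absent from matrix")
    cols = list(group_a) + list(group_b)
    counts = matrix[cols].to_numpy(dtype=float)
    if library_sizes is None:
        lib = counts.sum(axis=0)
        lib[lib == 0] = 1.0
    else:
        lib = np.array([library_sizes[s] for s in cols], dtype=float)
    ref = float(np.exp(np.log(lib).mean()))
    norm = counts * (ref / lib)

    n_a, n_b = len(group_a), len(group_b)
    if min(n_a, n_b) < 2:
        warnings.warn(
            "fewer than 2 replicates in a group; dispersion cannot be "
            "estimated, falling back to Poisson (phi -> minimum)",
            stacklevel=2,
        )
        phi = MIN_DISPERSION
    else:
        idx_a = np.arange(n_a)
        idx_b = np.arange(n_a, n_a + n_b)
        phi = estimate_common_dispersion(norm, [idx_a, idx_b])

    pseudo = np.rint(norm).astype(int)
    s_a = pseudo[:, :n_a].sum(axis=1)
    s_b = pseudo[:, n_a:].sum(axis=1)
    pvals = np.array(
        [_exact_nb_test(int(a), int(b), n_a, n_b, phi) for a, b in zip(s_a, s_b)]
    )
    padj = multipletests(pvals, method="fdr_bh")[1]

    mean_a = norm[:, :n_a].mean(axis=1)
    mean_b = norm[:, n_a:].mean(axis=1)
    lfc = np.log2((mean_a + 0.5) / (mean_b + 0.5))

    results = []
    for i, fid in enumerate(matrix.index):
        crit_p = padj[i] if use_adjusted else pvals[i]
        if crit_p <= alpha and lfc[i] > lfc_threshold:
            direction = "up"
        elif crit_p <= alpha and lfc[i] < -lfc_threshold:
            direction = "down"
        else:
            direction = "ns"
        results.append(
            DEResult(
                feature_id=str(fid),
                log2_fc=float(lfc[i]),
                p_value=float(pvals[i]),
                p_adjusted=float(padj[i]),
                mean_a=float(mean_a[i]),
                mean_b=float(mean_b[i]),
                direction=direction,
            )
        )
    return results


def de_union_vs_control(
    matrix: pd.DataFrame,
    sample_groups: dict[str, list[str]],
    control: str,
    library_sizes: dict[str, float] | None = None,
    **kwargs,
) -> dict:
    """Union of per-timepoint DE calls against the control condition.

    Each non-control condition is tested against ``control``; a feature is
    differentially expressed if it is called in any comparison. Direction
    is taken from the comparison with the smallest p-value.
    """
    if control not in sample_groups:
        raise KeyError(f"control group {control!r} not in sample_groups")
    per_comparison = {}
    best: dict[str, DEResult] = {}
    for cond, samples in sample_groups.items():
        if cond == control:
            continue
        res = de_test(matrix, samples, sample_groups[control],
                      library_sizes=library_sizes, **kwargs)
        per_comparison[cond] = res
        for r in res:
            if r.direction == "ns":
                continue
            if r.feature_id not in best or r.p_value < best[r.feature_id].p_value:
                best[r.feature_id] = r
    up = sorted(f for f, r in best.items() if r.direction == "up")
    down = sorted(f for f, r in best.items() if r.direction == "down")
    return {
        "per_comparison": per_comparison,
        "de_ids": sorted(best),
        "up": up,
        "down": down,
        "results": best,
    }


# ---------------------------------------------------------------------------
# enrichment


def hypergeom_enrich(
    study_ids: set[str],
    population_ids: set[str],
    term_map: dict[str, set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric (upper tail) term enrichment with BH control.

    ``term_map`` maps term -> set of population ids annotated to it.
    Columns follow the k/K/n/N convention: k study hits in the term, K term
    size in the population, n study size, N population size.
    """
    study = set(study_ids)
    population = set(population_ids)
    if not study <= population:
        raise ValueError("study ids must be a subset of the population")
    N, n = len(population), len(study)
    rows = []
    for term, members in sorted(term_map.items()):
        K = len(members & population)
        k = len(members & study)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["padj"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["padj"] <= alpha
    return df
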