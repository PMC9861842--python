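"""Cross-species conservation scoring of circRNAs.

Two complementary routes:

* junction-anchored alignment — the back-splice junction sequence (up to
  100 bp either side of the circular joint) is locally aligned against a
  subject database; a hit counts as conservation evidence only when the
  aligned region covers the junction itself;
* alignment-free k-mer profiles — length-normalized, background-
  standardized k-mer abundance vectors compared by Pearson correlation,
  suited to noncoding RNAs whose similarity is compositional rather than
  positional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np

from .circ_consensus import CircRNA
from .genome_io import Genome, reverse_complement

# Karlin-Altschul parameters for the +1/-2 match/mismatch scheme, stated
# explicitly so E-values are reproducible bit-for-bit.
KA_LAMBDA = 1.37
KA_K = 0.711

MATCH = 1
MISMATCH = -2
GAP_OPEN = -5   # charged once when a gap is opened, on top of the extension
GAP_EXTEND = -2  # charged per gapped residue (first residue costs -7 total)


@dataclass(frozen=True)
class JunctionSequence:
    """The circular back-splice joint, linearized.

    The last min(100, L) bases of the circle followed by its first
    min(100, L) bases, so that position ``junction_offset`` is the first
    base after the joint.
    """

    key: str
    sequence: str
    junction_offset: int


@dataclass
class KmerProfile:
    key: str
    k: int
    vector: np.ndarray  # standardized, length 4^k
    zero_variance: bool = False


@dataclass(frozen=True)
class ConservationHit:
    query: str
    subject: str
    species: str
    method: str  # junction_alignment | linear_blast_like | kmer
    score: float  # identity fraction for alignments, Pearson r for kmer
    evalue: float | None
    junction_covered: bool | None
    conserved: bool


def build_junction_sequence(circ: CircRNA, genome: Genome) -> JunctionSequence:
    """Extract the junction-spanning sequence of a circRNA.

    For a + strand circle [start, end) the sequence is
    genome[end-m:end] + genome[start:start+m] with m = min(100, L). For a
    - strand circle the circle is reverse-complemented first, then the
    same rule applies.
    """
    L = circ.genomic_length
    m = min(100, L)
    circle = genome.fetch(circ.chrom, circ.start, circ.end)
    if circ.strand == "-":
        circle = reverse_complement(circle)
    seq = circle[L - m:] + circle[:m]
    return JunctionSequence(circ.key, seq, junction_offset=m)


# ---------------------------------------------------------------------------
# seeded gapped local alignment


def _local_align(query: str, subject: str) -> tuple[int, int, int, float]:
    """Affine-gap Smith-Waterman.

    Returns (best score, query_start, query_end, identity) for the best
    local alignment, with the query span in 0-based half-open coordinates.
    Gap of length k costs GAP_OPEN + k * GAP_EXTEND.
    """
    n, m = len(query), len(subject)
    NEG = -10 ** 9
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in subject (query consumed)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query
    ptr: dict[tuple[int, int], tuple[int, int, bool]] = {}
    best, best_pos = 0, (0, 0)
    for i in range(1, n + 1):
        qi = query[i - 1]
        for j in range(1, m + 1):
            E[i][j] = max(E[i - 1][j] + GAP_EXTEND,
                          H[i - 1][j] + GAP_OPEN + GAP_EXTEND)
            F[i][j] = max(F[i][j - 1] + GAP_EXTEND,
                          H[i][j - 1] + GAP_OPEN + GAP_EXTEND)
            sub = MATCH if qi == subject[j - 1] else MISMATCH
            diag = H[i - 1][j - 1] + sub
            h = max(0, diag, E[i][j], F[i][j])
            H[i][j] = h
            if h > 0:
                if h == diag:
                    ptr[(i, j)] = (i - 1, j - 1, qi == subject[j - 1])
                elif h == E[i][j]:
                    ptr[(i, j)] = (i - 1, j, False)
                else:
                    ptr[(i, j)] = (i, j - 1, False)
            if h > best:
                best, best_pos = h, (i, j)
    if best == 0:
        return 0, 0, 0, 0.0
    # traceback for query span and identity
    i, j = best_pos
    q_end = i
    matches = cols = 0
    while H[i][j] > 0 and (i, j) in ptr:
        pi, pj, is_match = ptr[(i, j)]
        cols += 1
        if is_match:
            matches += 1
        i, j = pi, pj
    q_start = i
    return best, q_start, q_end, matches / cols if cols else 0.0


def _seed_words(seq: str, word: int) -> set[str]:
    return {seq[i:i + word] for i in range(len(seq) - word + 1)}


def evalue(score: int, query_len: int, subject_len: int) -> float:
    """Karlin-Altschul E-value for an ungapped-statistics approximation."""
    return KA_K * query_len * subject_len * math.exp(-KA_LAMBDA * score)


def junction_conserved(
    query: JunctionSequence,
    subject_db: dict[str, tuple[str, str]],
    evalue_cutoff: float = 1e-5,
    word_size: int = 11,
) -> list[ConservationHit]:
    """Align a junction sequence against subjects; keep junction-covering hits.

    ``subject_db`` maps subject id -> (species, sequence). Subjects sharing
    no exact ``word_size``-mer with the query are skipped (word seeding);
    the rest get a full affine-gap local alignment. A hit is reported iff
    its E-value is at most ``evalue_cutoff``; it counts as conserved only
    when the aligned query span also covers the two bases around the
    back-splice joint.
    """
    if len(query.sequence) < word_size:
        raise ValueError(
            f"query {query.key} shorter than seed word ({word_size})"
        )
    qwords = _seed_words(query.sequence, word_size)
    hits = []
    jo = query.junction_offset
    for subject_id, (species, seq) in subject_db.items():
        if len(seq) >= word_size and not (qwords & _seed_words(seq, word_size)):
            continue
        score, q_start, q_end, identity = _local_align(query.sequence, seq)
        if score <= 0:
            continue
        ev = evalue(score, len(query.sequence), len(seq))
        if ev > evalue_cutoff:
            continue
        covered = q_start <= jo - 1 and q_end >= jo + 1
        hits.append(
            ConservationHit(
                query=query.key,
                subject=subject_id,
                species=species,
                method="junction_alignment",
                score=identity,
                evalue=ev,
                junction_covered=covered,
                conserved=covered,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# k-mer profiles


def _all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in product("ACGT", repeat=k)]


def raw_kmer_counts(sequence: str, k: int = 6) -> np.ndarray:
    """Per-kb counts of every k-mer (sliding window, overlapping)."""
    index = {km: i for i, km in enumerate(_all_kmers(k))}
    counts = np.zeros(4 ** k)
    for i in range(len(sequence) - k + 1):
        idx = index.get(sequence[i:i + k])
        if idx is not None:  # skip windows containing N
            counts[idx] += 1
    return counts / (len(sequence) / 1000.0)


def build_kmer_profiles(
    sequences: dict[str, str], k: int = 6,
    background: dict[str, str] | None = None,
) -> dict[str, KmerProfile]:
    """Standardized k-mer profiles for a set of sequences.

    Each raw per-kb count vector is z-scored component-wise against the
    background set (default: the input set itself), so that systematic
    composition biases shared by all sequences cancel out.
    """
    if background is None:
        background = sequences
    bg = np.vstack([raw_kmer_counts(s, k) for s in background.values()])
    mean = bg.mean(axis=0)
    std = bg.std(axis=0)
    safe_std = np.where(std > 0, std, 1.0)
    profiles = {}
    for key, seq in sequences.items():
        raw = raw_kmer_counts(seq, k)
        z = (raw - mean) / safe_std
        z[std == 0] = 0.0
        profiles[key] = KmerProfile(key, k, z, zero_variance=bool(z.std() == 0))
    return profiles


def kmer_pearson(a: KmerProfile, b: KmerProfile) -> float:
    """Pearson correlation of two standardized profiles (NaN if degenerate)."""
    if a.k != b.k:
        raise ValueError("profiles built with different k")
    if a.vector.std() == 0 or b.vector.std() == 0:
        return float("nan")
    return float(np.corrcoef(a.vector, b.vector)[0, 1])


def kmer_conserved(r: float, threshold: float = 0.2) -> bool:
    """Strictly-greater rule: r == threshold is NOT conserved."""
    return bool(not math.isnan(r) and r > threshold)


def conservation_summary(hits: list[ConservationHit], n_query: int,
                         exclude_species: set[str] | None = None) -> dict:
    """Fraction of queries with at least one conserved hit."""
    if n_query <= 0:
        raise ValueError("n_query must be positive")
    exclude_species = exclude_species or set()
    per_species: dict[str, set[str]] = {}
    conserved_all, conserved_other = set(), set()
    for h in hits:
        if not h.conserved:
            continue
        per_species.setdefault(h.species, set()).add(h.query)
        conserved_all.add(h.query)
        if h.species not in exclude_species:
            conserved_other.add(h.query)
    return {
        "n_query": n_query,
        "n_conserved": len(conserved_all),
        "fraction": len(conserved_all) / n_query,
        "fraction_excluding": len(conserved_other) / n_query,
        "per_species": {
            sp: len(qs) / n_query for sp, qs in sorted(per_species.items())
        },
    }
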