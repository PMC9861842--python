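import itertools
import math
import statistics

import numpy as np
import pytest
from Bio import Align

from circscape.circ_consensus import CircRNA
from circscape.conservation import (
    _local_align,
    build_junction_sequence,
    build_kmer_profiles,
    conservation_summary,
    junction_conserved,
    kmer_conserved,
    kmer_pearson,
    raw_kmer_counts,
    ConservationHit,
)
from circscape.genome_io import Genome


def circ(chrom, start, end, strand="+"):
    return CircRNA(chrom, start, end, strand, (5,), frozenset({"A", "B"}))


def random_genome(seed, length=3000):
    rng = np.random.default_rng(seed)
    return Genome({"chr1": "".join(
        np.array(list("ACGT"))[rng.integers(0, 4, size=length)])})


class TestJunctionSequence:
    def test_plus_strand_indexing(self):
        genome = random_genome(1)
        j = build_junction_sequence(circ("chr1", 1000, 1400), genome)
        g = genome.sequences["chr1"]
        assert j.sequence == g[1300:1400] + g[1000:1100]
        assert j.junction_offset == 100

    def test_short_circle_uses_whole_circle_twice(self):
        genome = random_genome(2)
        j = build_junction_sequence(circ("chr1", 100, 150), genome)
        g = genome.sequences["chr1"]
        assert len(j.sequence) == 100
        assert j.sequence == g[100:150] + g[100:150]
        assert j.junction_offset == 50

    def test_minus_strand_six_mer_by_hand(self):
        #         0123456789
        genome = Genome({"chr1": "AACGTTGGCA"})
        # circle [2,8) on -: forward CGTTGG, circle = RC = CCAACG
        # m = 6: junction seq = circle[0:] + circle[:6] = CCAACGCCAACG
        j = build_junction_sequence(circ("chr1", 2, 8, "-"), genome)
        assert j.sequence == "CCAACGCCAACG"
        assert j.junction_offset == 6

    def test_missing_chromosome_errors(self):
        genome = random_genome(3)
        with pytest.raises(KeyError):
            build_junction_sequence(circ("chrX", 0, 100), genome)


def sw_oracle_score(query, subject):
    """Independent affine-gap local alignment score (Biopython)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -7   # first gapped residue: open -5 + extend -2
    aligner.extend_gap_score = -2
    return aligner.score(query, subject)


class TestJunctionConserved:
    def test_alignment_scores_match_smith_waterman_oracle(self):
        rng = np.random.default_rng(7)
        seqs = []
        base = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=200)])
        seqs.append(base)
        # related sequences: point mutations, indel, and fragments
        mutated = list(base)
        for pos in rng.integers(0, 200, size=12):
            mutated[pos] = "ACGT"[rng.integers(0, 4)]
        seqs.append("".join(mutated))
        seqs.append(base[:90] + base[110:])        # internal deletion
        seqs.append(base[50:170])                  # fragment
        seqs.append("".join(np.array(list("ACGT"))[
            rng.integers(0, 4, size=180)]))        # unrelated
        for q, s in itertools.permutations(seqs, 2):
            score, *_ = _local_align(q, s)
            assert score == sw_oracle_score(q, s)

    def test_exact_copy_is_conserved_hit(self):
        genome = random_genome(11)
        j = build_junction_sequence(circ("chr1", 500, 900), genome)
        hits = junction_conserved(j, {"copy": ("speciesX", j.sequence)})
        assert len(hits) == 1
        assert hits[0].score == 1.0
        assert hits[0].junction_covered

    def test_randomized_junction_region_not_covered(self):
        rng = np.random.default_rng(13)
        genome = random_genome(13)
        j = build_junction_sequence(circ("chr1", 500, 900), genome)
        seq = list(j.sequence)
        # destroy 100 bases centred on the junction
        lo, hi = j.junction_offset - 50, j.junction_offset + 50
        seq[lo:hi] = np.array(list("ACGT"))[rng.integers(0, 4, size=hi - lo)]
        hits = junction_conserved(j, {"broken": ("speciesX", "".join(seq))})
        assert all(not h.junction_covered for h in hits)

    def test_flank_only_alignment_excluded_from_conserved(self):
        genome = random_genome(17)
        j = build_junction_sequence(circ("chr1", 500, 900), genome)
        subject = j.sequence[:80]  # aligns only to query span [0, 80)
        hits = junction_conserved(j, {"flank": ("speciesX", subject)})
        assert len(hits) == 1
        assert not hits[0].junction_covered
        assert not hits[0].conserved

    def test_query_shorter_than_seed_word_errors(self):
        from circscape.conservation import JunctionSequence
        j = JunctionSequence("k", "ACGTACGT", 4)
        with pytest.raises(ValueError):
            junction_conserved(j, {})


def brute_force_standardized_profiles(seqs, k):
    """Independent recomputation: dict counting + statistics stdlib."""
    kmers = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
    raw = {}
    for name, s in seqs.items():
        counts = {km: 0 for km in kmers}
        for i in range(len(s) - k + 1):
            if s[i:i + k] in counts:
                counts[s[i:i + k]] += 1
        raw[name] = [c / (len(s) / 1000) for c in counts.values()]
    names = list(seqs)
    out = {}
    for name in names:
        vec = []
        for i, km in enumerate(kmers):
            col = [raw[n][i] for n in names]
            mu = statistics.mean(col)
            sd = statistics.pstdev(col)
            vec.append((raw[name][i] - mu) / sd if sd > 0 else 0.0)
        out[name] = vec
    return out


class TestKmerProfiles:
    def test_profile_vs_itself_r_one(self):
        rng = np.random.default_rng(19)
        s = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=300)])
        profiles = build_kmer_profiles({"a": s, "b": s[::-1]}, k=4)
        assert kmer_pearson(profiles["a"], profiles["a"]) == pytest.approx(1.0)

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(23)
        seqs = {
            f"s{i}": "".join(np.array(list("ACGT"))[
                rng.integers(0, 4, size=250)])
            for i in range(4)
        }
        k = 3
        mine = build_kmer_profiles(seqs, k=k)
        brute = brute_force_standardized_profiles(seqs, k)
        for name in seqs:
            assert np.allclose(mine[name].vector, brute[name])
        # pearson agrees with a textbook recomputation on the brute vectors
        r_mine = kmer_pearson(mine["s0"], mine["s1"])
        x, y = np.array(brute["s0"]), np.array(brute["s1"])
        r_brute = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / math.sqrt(((x - x.mean()) ** 2).sum()
                        * ((y - y.mean()) ** 2).sum())
        )
        assert r_mine == pytest.approx(r_brute, abs=1e-12)

    def test_threshold_is_strictly_greater(self):
        assert not kmer_conserved(0.2)
        assert kmer_conserved(0.2000001)
        assert not kmer_conserved(float("nan"))

    def test_symmetry(self):
        rng = np.random.default_rng(29)
        seqs = {
            "a": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)]),
            "b": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)]),
        }
        p = build_kmer_profiles(seqs, k=4)
        assert kmer_pearson(p["a"], p["b"]) == \
            pytest.approx(kmer_pearson(p["b"], p["a"]))

    def test_self_concatenation_stable_per_kb(self):
        """Doubling a sequence leaves per-kb counts unchanged up to edge
        k-mers (tolerance 2k/L)."""
        rng = np.random.default_rng(31)
        s = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=400)])
        k = 5
        a = raw_kmer_counts(s, k)
        b = raw_kmer_counts(s + s, k)
        assert np.abs(a - b).max() <= 2 * k / (len(s) / 1000)

    def test_zero_variance_profile_gives_nan(self):
        # identical homopolymers: every standardized component is 0,
        # so the correlation is undefined and reported as NaN
        p = build_kmer_profiles({"a": "A" * 50, "b": "A" * 50}, k=3)
        assert p["a"].zero_variance
        assert math.isnan(kmer_pearson(p["a"], p["b"]))


class TestConservationSummary:
    def _hit(self, q, species, conserved=True):
        return ConservationHit(q, "s", species, "junction_alignment",
                               1.0, 1e-9, conserved, conserved)

    def test_study_scale_fraction(self):
        """655 conserved queries of 2702 is the 24.2% headline fraction."""
        hits = [self._hit(f"q{i}", "other") for i in range(655)]
        summary = conservation_summary(hits, 2702)
        assert 100 * summary["fraction"] == pytest.approx(24.2, abs=0.05)

    def test_no_hits_zero_fraction(self):
        assert conservation_summary([], 10)["fraction"] == 0.0

    def test_all_queries_conserved(self):
        hits = [self._hit(f"q{i}", "sp") for i in range(10)]
        assert conservation_summary(hits, 10)["fraction"] == 1.0

    def test_duplicate_hits_counted_once(self):
        hits = [self._hit("q0", "sp1"), self._hit("q0", "sp2")]
        assert conservation_summary(hits, 4)["n_conserved"] == 1

    def test_same_species_excluded_fraction(self):
        hits = [self._hit("q0", "self"), self._hit("q1", "other")]
        s = conservation_summary(hits, 4, exclude_species={"self"})
        assert s["fraction"] == 0.5
        assert s["fraction_excluding"] == 0.25

    def test_zero_queries_rejected(self):
        with pytest.raises(ValueError):
            conservation_summary([], 0)
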