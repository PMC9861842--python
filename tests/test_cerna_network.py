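import numpy as np
import pytest

from circscape.cerna_network import (
    BindingSite,
    MiRNA,
    build_network,
    circ_sites_on_junction,
    export_network,
    predict_sites,
    read_network,
)
from circscape.genome_io import ValidationError, reverse_complement

MIR = MiRNA("miR-test", "TGGAGAAGCAGGGCACGTTGA")  # 21 nt, position 20 = G


def embed(site, pad_seed=71, total=200, at=90):
    rng = np.random.default_rng(pad_seed)
    bases = np.array(list("ACGT"))
    seq = "".join(bases[rng.integers(0, 4, size=total)])
    return seq[:at] + site + seq[at + len(site):]


class TestPredictSites:
    def test_perfect_complement_expectation_zero(self):
        target = embed(reverse_complement(MIR.sequence))
        sites = predict_sites(MIR, "t", target)
        assert len(sites) == 1
        assert sites[0].expectation == 0.0
        assert sites[0].target_start == 90
        assert set(sites[0].states) == {"match"}

    def test_mismatch_in_seed_region_costs_double(self):
        """One mismatch at miRNA position 10 scores 2.0 (seed-doubled)."""
        rc = list(reverse_complement(MIR.sequence))
        L = len(MIR)
        j = L - 10  # rc index pairing miRNA position 10
        # replace with the rc base's own complement: neither match nor wobble
        wobble_safe = {"A": "C", "C": "A", "G": "T", "T": "G"}
        rc[j] = wobble_safe[rc[j]]
        sites = predict_sites(MIR, "t", embed("".join(rc)))
        assert len(sites) == 1
        assert sites[0].expectation == 2.0
        assert sites[0].states[9] == "mismatch"

    def test_wobble_outside_seed_costs_half(self):
        """A G:U pair at miRNA position 20 scores 0.5."""
        rc = list(reverse_complement(MIR.sequence))
        L = len(MIR)
        j = L - 20
        assert rc[j] == "C"  # miRNA position 20 is G; C->T gives G:U
        rc[j] = "T"
        sites = predict_sites(MIR, "t", embed("".join(rc)))
        assert len(sites) == 1
        assert sites[0].expectation == 0.5
        assert sites[0].states[19] == "G:U"

    def test_single_bulge_detected_with_gap_penalty(self):
        rc = reverse_complement(MIR.sequence)
        # extra target base at rc index 3 (miRNA position 18, outside seed)
        bulged = rc[:3] + "A" + rc[3:]
        sites = predict_sites(MIR, "t", embed(bulged))
        assert sites
        best = min(sites, key=lambda s: s.expectation)
        assert best.expectation <= 2.0

    def test_expectation_monotone_under_edits(self):
        """Every additional edit away from perfect complementarity can only
        raise the best expectation."""
        rng = np.random.default_rng(73)
        rc = list(reverse_complement(MIR.sequence))
        prev = 0.0
        for n_edits in range(1, 5):
            pos = int(rng.integers(0, len(rc)))
            wobble_safe = {"A": "C", "C": "A", "G": "T", "T": "G"}
            rc[pos] = wobble_safe[rc[pos]]
            sites = predict_sites(MIR, "t", embed("".join(rc)),
                                  max_expectation=50.0)
            best = min((s.expectation for s in sites), default=np.inf)
            assert best >= prev
            prev = best

    def test_stringent_cutoff_on_random_sequence_finds_nothing(self):
        rng = np.random.default_rng(79)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        assert predict_sites(MIR, "t", seq, max_expectation=0.0) == []

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValidationError):
            predict_sites(MIR, "t", "ACGTQQQT" * 10)

    def test_target_shorter_than_mirna_no_sites(self):
        assert predict_sites(MIR, "t", "ACGT") == []

    def test_mirna_length_validated(self):
        with pytest.raises(ValidationError):
            MiRNA("short", "ACGTACGT")


class TestJunctionSites:
    def test_junction_spanning_site_superset_of_linear_flanks(self, bundle):
        """Sites on the circular junction sequence include every site found
        on either linear flank, plus junction spanners."""
        from circscape.conservation import build_junction_sequence
        from circscape.circ_consensus import consensus_filter
        from circscape import genome_io

        mirnas = [
            MiRNA(n, s)
            for n, s in sorted(
                genome_io.read_fasta(bundle.paths["mirnas"]).items())
        ]
        calls_a = genome_io.read_circ_calls(bundle.paths["caller_a"], "A")
        calls_b = genome_io.read_circ_calls(bundle.paths["caller_b"], "B")
        circs = {c.key: c for c in consensus_filter(calls_a, calls_b)}
        sponge_keys = [s[0] for s in bundle.truth.sponges]
        for key in sponge_keys:
            circ = circs[key]
            j = build_junction_sequence(circ, bundle.genome)
            junction_sites = circ_sites_on_junction(
                circ, mirnas, bundle.genome)
            flank_sites = []
            for m in mirnas:
                left = j.sequence[:j.junction_offset]
                right = j.sequence[j.junction_offset:]
                flank_sites += predict_sites(m, key, left)
                flank_sites += predict_sites(m, key, right)
            junction_pairs = {(s.mirna_id, s.expectation)
                              for s in junction_sites}
            for s in flank_sites:
                assert any(m == s.mirna_id and e <= s.expectation
                           for m, e in junction_pairs)

    def test_planted_junction_spanning_sites_detected(self, bundle):
        from circscape.circ_consensus import consensus_filter
        from circscape import genome_io

        mirnas = {n: MiRNA(n, s) for n, s in
                  genome_io.read_fasta(bundle.paths["mirnas"]).items()}
        calls_a = genome_io.read_circ_calls(bundle.paths["caller_a"], "A")
        calls_b = genome_io.read_circ_calls(bundle.paths["caller_b"], "B")
        circs = {c.key: c for c in consensus_filter(calls_a, calls_b)}
        assert bundle.truth.sponges
        for circ_key, mir_id, _gene in bundle.truth.sponges:
            sites = circ_sites_on_junction(
                circs[circ_key], [mirnas[mir_id]], bundle.genome)
            perfect = [s for s in sites if s.expectation == 0.0]
            assert len(perfect) == 1
            # the planted site spans the back-splice joint
            from circscape.conservation import build_junction_sequence
            jo = build_junction_sequence(
                circs[circ_key], bundle.genome).junction_offset
            assert perfect[0].target_start < jo < perfect[0].target_end


def site(target, mirna, expectation=1.0):
    return BindingSite(target, mirna, 0, 21, expectation,
                       ("match",) * 21)


class TestBuildNetwork:
    def test_tripartite_with_pruning(self):
        circ_sites = [site("circ1", "miR1"), site("circ2", "miR2"),
                      site("circX", "miR1")]
        mrna_sites = [site("gene1", "miR1"), site("gene2", "miR3")]
        net = build_network({"circ1", "circ2"}, {"gene1", "gene2"},
                            circ_sites, mrna_sites)
        # miR2 has no mRNA edge, miR3 no circ edge -> both pruned;
        # circX not DE -> dropped
        nodes = dict(net.graph.nodes(data="node_type"))
        assert nodes == {"circ1": "circ", "miR1": "miRNA", "gene1": "mRNA"}
        assert net.counts() == {"n_circ": 1, "n_mirna": 1, "n_mrna": 1,
                                "n_edges": 2}

    def test_no_de_circ_gives_empty_network(self):
        net = build_network(set(), {"gene1"},
                            [site("circ1", "miR1")],
                            [site("gene1", "miR1")])
        assert net.graph.number_of_nodes() == 0

    def test_no_circ_mrna_edges_ever(self):
        circ_sites = [site("circ1", "miR1")]
        mrna_sites = [site("gene1", "miR1")]
        net = build_network({"circ1"}, {"gene1"}, circ_sites, mrna_sites)
        for u, v in net.graph.edges():
            types = {net.graph.nodes[u]["node_type"],
                     net.graph.nodes[v]["node_type"]}
            assert "miRNA" in types

    def test_planted_sponge_triples_recovered_exactly(self, bundle):
        from circscape.circ_consensus import consensus_filter
        from circscape.synthetic_data import transcript_sequence
        from circscape import genome_io

        mirnas = [MiRNA(n, s) for n, s in sorted(
            genome_io.read_fasta(bundle.paths["mirnas"]).items())]
        calls_a = genome_io.read_circ_calls(bundle.paths["caller_a"], "A")
        calls_b = genome_io.read_circ_calls(bundle.paths["caller_b"], "B")
        circs = {c.key: c for c in consensus_filter(calls_a, calls_b)}
        truth = bundle.truth
        de_circs = {c.key for c in truth.circs if c.de_status != "none"
                    and c.key in circs}
        de_genes = set(truth.de_genes_up) | set(truth.de_genes_down)
        gene_by_id = {g.gene_id: g for g in bundle.genes}
        circ_sites = []
        for key in sorted(de_circs):
            circ_sites += circ_sites_on_junction(circs[key], mirnas,
                                                 bundle.genome)
        mrna_sites = []
        for gid in sorted(de_genes):
            seq = transcript_sequence(gene_by_id[gid], bundle.genome)
            for m in mirnas:
                mrna_sites += predict_sites(m, gid, seq)
        net = build_network(de_circs, de_genes, circ_sites, mrna_sites)
        expected_edges = set()
        for circ_key, mir, gene in truth.sponges:
            expected_edges.add(frozenset((circ_key, mir)))
            expected_edges.add(frozenset((mir, gene)))
        got_edges = {frozenset(e) for e in net.graph.edges()}
        assert got_edges == expected_edges


class TestExport:
    def test_round_trip_counts(self, tmp_path):
        net = build_network({"c1", "c2"}, {"g1", "g2", "g3"},
                            [site("c1", "m1"), site("c2", "m1")],
                            [site("g1", "m1"), site("g2", "m1"),
                             site("g3", "m1")])
        path = tmp_path / "net.tsv"
        export_network(net, path)
        back = read_network(path)
        assert back.counts() == net.counts() == {
            "n_circ": 2, "n_mirna": 1, "n_mrna": 3, "n_edges": 5}

    def test_empty_network_header_only(self, tmp_path):
        net = build_network(set(), set(), [], [])
        path = tmp_path / "net.tsv"
        export_network(net, path)
        assert path.read_text() == "source\ttarget\tedge_type\texpectation\n"
        assert (tmp_path / "net.tsv.nodes").read_text() == "node\tnode_type\n"
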