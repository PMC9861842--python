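"""miRNA target prediction and sponge (ceRNA) network assembly.

Binding sites are scored with a plant-miRNA expectation scheme: the
reverse complement of the mature miRNA is slid along the target allowing
at most one bulge, penalizing G:U wobbles 0.5, mismatches 1.0 and gaps 2.0,
with penalties doubled in the seed-critical region (miRNA positions 2-13).
A site is accepted when the summed expectation stays at or below a cutoff
(default 5.0). The sponge network keeps circRNA-miRNA and miRNA-mRNA edges
whose circRNA / mRNA endpoints are differentially expressed, forming a
tripartite graph with no direct circRNA-mRNA edges.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .circ_consensus import CircRNA
from .conservation import JunctionSequence, build_junction_sequence
from .genome_io import Genome, ValidationError, reverse_complement

SEED_START, SEED_END = 2, 13  # miRNA positions (1-based, from the 5' end)
VALID_MIRNA_BASES = set("ACGTU")

# penalties per aligned miRNA position
P_MATCH = 0.0
P_WOBBLE = 0.5
P_MISMATCH = 1.0
P_GAP = 2.0

# rc-vs-target pairs that correspond to a G:U wobble in the RNA duplex
_WOBBLE_PAIRS = {("C", "T"), ("A", "G")}


@dataclass(frozen=True)
class MiRNA:
    mirna_id: str
    sequence: str  # stored as DNA, 5'->3'

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if set(seq) - VALID_MIRNA_BASES:
            raise ValidationError(f"{self.mirna_id}: invalid bases")
        if not 18 <= len(seq) <= 24:
            raise ValidationError(
                f"{self.mirna_id}: mature miRNA length {len(seq)} outside 18-24"
            )
        object.__setattr__(self, "sequence", seq.replace("U", "T"))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BindingSite:
    target_id: str
    mirna_id: str
    target_start: int
    target_end: int
    expectation: float
    states: tuple[str, ...]  # per miRNA position: match | G:U | mismatch | gap


@dataclass
class SpongeNetwork:
    graph: nx.Graph = field(default_factory=nx.Graph)

    def counts(self) -> dict:
        by_type: dict[str, int] = {"circ": 0, "miRNA": 0, "mRNA": 0}
        for _, d in self.graph.nodes(data=True):
            by_type[d["node_type"]] += 1
        return {
            "n_circ": by_type["circ"],
            "n_mirna": by_type["miRNA"],
            "n_mrna": by_type["mRNA"],
            "n_edges": self.graph.number_of_edges(),
        }


def _position_penalty(base_penalty: float, mirna_pos: int) -> float:
    if SEED_START <= mirna_pos <= SEED_END:
        return base_penalty * 2.0
    return base_penalty


def _score_variant(
    rc: str, window: str, gap_kind: str | None, gap_at: int, L: int
) -> tuple[float, list[str]] | None:
    """Score one alignment variant; None when hard constraints fail.

    ``rc`` is the reverse complement of the miRNA, so rc index j pairs
    miRNA position L - j (1-based from the miRNA 5' end). ``gap_at`` is an
    rc index for a miRNA bulge, or a window index for a target bulge.
    """
    expectation = 0.0
    states = ["?"] * L  # indexed by miRNA position - 1
    mismatches = 0
    seed_run = 0

    def pair_state(rc_base: str, t_base: str) -> str:
        if rc_base == t_base:
            return "match"
        if (rc_base, t_base) in _WOBBLE_PAIRS:
            return "G:U"
        return "mismatch"

    for j in range(L):
        mirna_pos = L - j
        if gap_kind == "mirna_bulge" and j == gap_at:
            states[mirna_pos - 1] = "gap"
            expectation += _position_penalty(P_GAP, mirna_pos)
            continue
        if gap_kind == "mirna_bulge":
            t_idx = j if j < gap_at else j - 1
        elif gap_kind == "target_bulge":
            t_idx = j if j < gap_at else j + 1
        else:
            t_idx = j
        state = pair_state(rc[j], window[t_idx])
        states[mirna_pos - 1] = state
        if state == "G:U":
            expectation += _position_penalty(P_WOBBLE, mirna_pos)
        elif state == "mismatch":
            expectation += _position_penalty(P_MISMATCH, mirna_pos)
            mismatches += 1
    if gap_kind == "target_bulge":
        # the unpaired target base is charged at the adjacent miRNA position
        mirna_pos = max(1, L - gap_at)
        expectation += _position_penalty(P_GAP, mirna_pos)

    if mismatches > 4:
        return None
    for pos in range(SEED_START, SEED_END + 1):
        if pos <= L and states[pos - 1] == "mismatch":
            seed_run += 1
            if seed_run > 2:
                return None
        else:
            seed_run = 0
    return expectation, states


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_BIG = 1e9


def _candidate_offsets(rc: str, target: str, max_expectation: float) -> list[int]:
    """Vectorized screen: offsets whose best variant could pass the cutoff.

    Computes the exact expectation of the ungapped and every single-bulge
    alignment at every offset (ignoring the mismatch-count constraints,
    which only reject), and returns offsets whose minimum is within the
    cutoff. The exact scorer is then run only at those offsets.
    """
    L, n = len(rc), len(target)
    # penalty lookup: rows = rc base, cols = target base (N never pairs)
    lut = np.full((5, 5), P_MISMATCH)
    for b in range(4):
        lut[b, b] = P_MATCH
    lut[_BASE_CODE["C"], _BASE_CODE["T"]] = P_WOBBLE
    lut[_BASE_CODE["A"], _BASE_CODE["G"]] = P_WOBBLE
    lut[:, 4] = P_MISMATCH
    lut[4, :] = P_MISMATCH

    tpad = np.full(n + 3, 4, dtype=np.intp)  # one sentinel left, two right
    tpad[1:n + 1] = [_BASE_CODE[c] for c in target]
    rcode = np.array([_BASE_CODE[c] for c in rc], dtype=np.intp)

    cols = n - L + 3  # column i corresponds to true offset o = i - 1
    M = np.empty((L, cols))
    for j in range(L):
        M[j] = lut[rcode[j], tpad[j:j + cols]]
        mirna_pos = L - j
        if SEED_START <= mirna_pos <= SEED_END:
            M[j] *= 2.0
    C = np.vstack([np.zeros(cols), np.cumsum(M, axis=0)])  # C[g] = sum j<g
    total = C[L]
    offsets = np.arange(0, n - L + 1)
    best = total[offsets + 1].copy()  # ungapped
    for g in range(1, L):
        gp_m = _position_penalty(P_GAP, L - g)
        # miRNA bulge at rc index g (window one base shorter)
        cand = C[g, offsets + 1] + (total - C[g + 1])[offsets] + gp_m
        best = np.minimum(best, cand)
        # target bulge before rc index g (window one base longer)
        gp_t = _position_penalty(P_GAP, max(1, L - g))
        cand = C[g, offsets + 1] + (total - C[g])[offsets + 2] + gp_t
        ok = offsets <= n - L - 1
        best[ok] = np.minimum(best[ok], cand[ok])
    return [int(o) for o in offsets[best <= max_expectation]]


def predict_sites(
    mirna: MiRNA, target_id: str, target_sequence: str,
    max_expectation: float = 5.0,
) -> list[BindingSite]:
    """Slide the miRNA's reverse complement along a target sequence.

    At each offset the ungapped alignment and every single-bulge variant
    (one unpaired base on either strand) are scored; the best variant is
    reported when its expectation is at most ``max_expectation``. Overlapping
    sites of the same miRNA are collapsed to the best-scoring one.
    """
    target = target_sequence.upper().replace("U", "T")
    if set(target) - set("ACGTN"):
        raise ValidationError(f"{target_id}: invalid bases in target")
    L = len(mirna)
    if len(target) < L:
        return []
    rc = reverse_complement(mirna.sequence)

    candidates = []
    for i in _candidate_offsets(rc, target, max_expectation):
        variants: list[tuple[float, list[str], int]] = []
        got = _score_variant(rc, target[i:i + L], None, -1, L)
        if got:
            variants.append((got[0], got[1], L))
        for g in range(1, L):  # miRNA bulge: site is one base shorter
            if i + L - 1 <= len(target):
                got = _score_variant(rc, target[i:i + L - 1], "mirna_bulge", g, L)
                if got:
                    variants.append((got[0], got[1], L - 1))
        for g in range(1, L):  # target bulge: site is one base longer
            if i + L + 1 <= len(target):
                got = _score_variant(rc, target[i:i + L + 1], "target_bulge", g, L)
                if got:
                    variants.append((got[0], got[1], L + 1))
        if not variants:
            continue
        expectation, states, span = min(variants, key=lambda v: (v[0], -v[2]))
        if expectation <= max_expectation:
            candidates.append(
                BindingSite(
                    target_id, mirna.mirna_id, i, i + span,
                    expectation, tuple(states),
                )
            )
    # collapse overlapping candidate sites, best expectation first
    kept: list[BindingSite] = []
    for site in sorted(candidates, key=lambda s: (s.expectation, s.target_start)):
        if all(
            site.target_end <= k.target_start or site.target_start >= k.target_end
            for k in kept
        ):
            kept.append(site)
    return sorted(kept, key=lambda s: s.target_start)


def circ_sites_on_junction(
    circ: CircRNA, mirnas: list[MiRNA], genome: Genome,
    max_expectation: float = 5.0,
    junction: JunctionSequence | None = None,
) -> list[BindingSite]:
    """Predict miRNA sites on a circRNA's junction sequence.

    Searching the junction sequence (circle end joined to circle start)
    makes junction-spanning sites detectable, which a linear scan of the
    genomic span would miss.
    """
    if junction is None:
        junction = build_junction_sequence(circ, genome)
    sites = []
    for mirna in mirnas:
        sites.extend(
            predict_sites(mirna, circ.key, junction.sequence, max_expectation)
        )
    return sites


def build_network(
    de_circs: set[str],
    de_genes: set[str],
    circ_sites: list[BindingSite],
    mrna_sites: list[BindingSite],
) -> SpongeNetwork:
    """Assemble the DE-constrained tripartite sponge network.

    circRNA-miRNA edges survive only for differentially expressed circRNAs,
    miRNA-mRNA edges only for differentially expressed genes; miRNAs
    lacking either edge type are pruned (a sponge claim needs both).
    """
    g = nx.Graph()
    circ_edges = [s for s in circ_sites if s.target_id in de_circs]
    mrna_edges = [s for s in mrna_sites if s.target_id in de_genes]
    mirnas_with_circ = {s.mirna_id for s in circ_edges}
    mirnas_with_mrna = {s.mirna_id for s in mrna_edges}
    keep = mirnas_with_circ & mirnas_with_mrna
    for s in circ_edges:
        if s.mirna_id not in keep:
            continue
        g.add_node(s.target_id, node_type="circ")
        g.add_node(s.mirna_id, node_type="miRNA")
        prev = g.get_edge_data(s.target_id, s.mirna_id)
        if prev is None or s.expectation < prev["expectation"]:
            g.add_edge(s.target_id, s.mirna_id, edge_type="circ-miRNA",
                       expectation=s.expectation)
    for s in mrna_edges:
        if s.mirna_id not in keep:
            continue
        g.add_node(s.target_id, node_type="mRNA")
        g.add_node(s.mirna_id, node_type="miRNA")
        prev = g.get_edge_data(s.target_id, s.mirna_id)
        if prev is None or s.expectation < prev["expectation"]:
            g.add_edge(s.target_id, s.mirna_id, edge_type="miRNA-mRNA",
                       expectation=s.expectation)
    return SpongeNetwork(g)


def export_network(network: SpongeNetwork, path: str | os.PathLike) -> None:
    """Write TSV edge list plus a node-attribute table (path + '.nodes')."""
    path = str(path)
    with open(path, "w") as fh:
        fh.write("source\ttarget\tedge_type\texpectation\n")
        for u, v, d in sorted(network.graph.edges(data=True)):
            if d["edge_type"] == "miRNA-mRNA":
                # orient miRNA -> mRNA
                if network.graph.nodes[u]["node_type"] != "miRNA":
                    u, v = v, u
            else:  # circ -> miRNA
                if network.graph.nodes[u]["node_type"] != "circ":
                    u, v = v, u
            fh.write(f"{u}\t{v}\t{d['edge_type']}\t{d['expectation']:.3f}\n")
    with open(path + ".nodes", "w") as fh:
        fh.write("node\tnode_type\n")
        for n, d in sorted(network.graph.nodes(data=True)):
            fh.write(f"{n}\t{d['node_type']}\n")


def read_network(path: str | os.PathLike) -> SpongeNetwork:
    """Round-trip reader for :func:`export_network` output."""
    path = str(path)
    g = nx.Graph()
    with open(path + ".nodes") as fh:
        next(fh)
        for line in fh:
            node, node_type = line.rstrip("\n").split("\t")
            g.add_node(node, node_type=node_type)
    with open(path) as fh:
        next(fh)
        for line in fh:
            u, v, edge_type, expectation = line.rstrip("\n").split("\t")
            g.add_edge(u, v, edge_type=edge_type, expectation=float(expectation))
    return SpongeNetwork(g)
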