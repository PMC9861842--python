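"""Seeded synthetic fixture bundle with planted ground truth.

Emulates a chilling-stress circRNA study design at desk scale: a small
multi-gene genome, planted circRNAs of all four types, two back-splice
callers with controlled key overlap, repeat-enriched and hypermethylated
flanking introns around circularized exons, junction-read count matrices
over five timepoints (control plus four chilling durations) with three
replicates, planted fold changes, and miRNA binding sites embedded on
sponge-edge circRNAs and mRNAs. Every planted fact is written to a truth
table so downstream stages can be scored for exact recovery.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import genome_io
from .genome_io import (
    CircCall,
    GeneModel,
    Genome,
    MethylationRecord,
    MethylationTrack,
    RepeatInterval,
    circ_key,
    reverse_complement,
)

CONDITIONS = ("CK", "C6", "C12", "C24", "C7d")


class ConfigError(ValueError):
    """Simulation configuration violates a constraint."""


@dataclass
class SimulationConfig:
    """All knobs of the generator. ``seed`` is mandatory.

    Defaults mirror the emulated study design: 5 timepoints x 3 replicates,
    overdispersed junction counts (NB dispersion 0.1), LTR repeats enriched
    ~3x in circRNA flanking introns, and elevated weighted methylation
    there.
    """

    seed: int
    n_chromosomes: int = 2
    chrom_length: int = 200_000
    n_genes: int = 60
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (90, 300)
    intron_length: tuple[int, int] = (150, 800)
    intergenic_gap: tuple[int, int] = (800, 2000)
    n_circ_exonic: int = 24
    n_circ_intronic: int = 8
    n_circ_intergenic: int = 4
    n_circ_antisense: int = 2
    n_long_decoys: int = 2       # shared calls with genomic span > 10 kb
    n_lowread_decoys: int = 2    # shared calls failing the read-support filter
    caller_overlap_fraction: float = 0.8
    junction_read_mean: float = 8.0
    de_read_mean: float = 100.0
    nb_dispersion: float = 0.1
    n_timepoints: int = 5
    n_replicates: int = 3
    n_de_up: int = 4
    n_de_down: int = 2
    de_fold: float = 4.0
    clean_reads_mean: float = 2e8
    repeat_fraction_circ: float = 0.45
    repeat_fraction_background: float = 0.15
    methylation_circ: float = 0.6
    methylation_background: float = 0.25
    methylation_beta_concentration: float = 20.0
    cytosine_sampling: float = 0.2
    coverage_mean: float = 20.0
    n_mirnas: int = 12
    mirna_length: int = 21
    n_sponge_triples: int = 3
    n_de_genes_up: int = 6
    n_de_genes_down: int = 3
    gene_count_mean: float = 200.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory (no silent nondeterminism)")
        if not 0.0 <= self.caller_overlap_fraction <= 1.0:
            raise ConfigError("caller_overlap_fraction must be in [0, 1]")
        for name in ("n_chromosomes", "chrom_length", "n_genes",
                     "n_timepoints", "n_replicates", "n_mirnas"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.de_fold <= 0:
            raise ConfigError("fold changes must be > 0")
        if self.exons_per_gene[0] < 3:
            raise ConfigError(
                "exonic circRNAs need host genes with >= 3 exons"
            )
        if self.n_sponge_triples > min(self.n_de_up, self.n_mirnas,
                                       self.n_de_genes_up):
            raise ConfigError("not enough DE circs/miRNAs/DE genes for the "
                              "requested sponge triples")

    @property
    def n_circ(self) -> int:
        return (self.n_circ_exonic + self.n_circ_intronic
                + self.n_circ_intergenic + self.n_circ_antisense)

    @property
    def conditions(self) -> tuple[str, ...]:
        return CONDITIONS[: self.n_timepoints]

    @property
    def sample_names(self) -> list[str]:
        return [f"{c}_r{r + 1}" for c in self.conditions
                for r in range(self.n_replicates)]


@dataclass
class TruthCirc:
    key: str
    circ_type: str
    parental_gene: str | None
    n_exons: int | None
    flanking_intron_left: tuple[int, int] | None
    flanking_intron_right: tuple[int, int] | None
    shared: bool
    pass_filter: bool
    de_status: str  # up | down | none
    fold: float


@dataclass
class TruthTable:
    circs: list[TruthCirc]
    sponges: list[tuple[str, str, str]]  # (circ key, miRNA id, gene id)
    de_genes_up: list[str]
    de_genes_down: list[str]

    def by_key(self) -> dict[str, TruthCirc]:
        return {c.key: c for c in self.circs}

    def consensus_keys(self) -> set[str]:
        return {c.key for c in self.circs if c.shared and c.pass_filter}


@dataclass
class Bundle:
    config: SimulationConfig
    outdir: Path
    paths: dict[str, Path]
    genome: Genome
    genes: list[GeneModel]
    truth: TruthTable


def sample_nb_counts(rng: np.random.Generator, mean: float, dispersion: float,
                     size) -> np.ndarray:
    """Negative binomial with mean/dispersion parameterization.

    var = mean + dispersion * mean^2 (size parameter r = 1/dispersion).
    """
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _beta_level(rng: np.random.Generator, mean: float, conc: float) -> float:
    mean = min(max(mean, 1e-3), 1 - 1e-3)
    return float(rng.beta(mean * conc, (1 - mean) * conc))


# ---------------------------------------------------------------------------
# layout


def _place_genes(cfg: SimulationConfig, rng: np.random.Generator
                 ) -> tuple[list[GeneModel], list[tuple[str, int, int]]]:
    """Tile genes along chromosomes; returns gene models and intergenic gaps."""
    genes: list[GeneModel] = []
    gaps: list[tuple[str, int, int]] = []
    gid = 0
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        pos = int(rng.integers(*cfg.intergenic_gap))
        while gid < cfg.n_genes:
            n_ex = int(rng.integers(cfg.exons_per_gene[0],
                                    cfg.exons_per_gene[1] + 1))
            exon_lens = rng.integers(*cfg.exon_length, size=n_ex)
            intron_lens = rng.integers(*cfg.intron_length, size=n_ex - 1)
            span = int(exon_lens.sum() + intron_lens.sum())
            if pos + span + cfg.intergenic_gap[1] > cfg.chrom_length:
                break
            exons = []
            cursor = pos
            for i in range(n_ex):
                exons.append((cursor, cursor + int(exon_lens[i])))
                cursor += int(exon_lens[i])
                if i < n_ex - 1:
                    cursor += int(intron_lens[i])
            strand = "+" if rng.random() < 0.65 else "-"
            gid += 1
            genes.append(GeneModel(f"gene{gid:04d}", chrom, strand, exons))
            gap = int(rng.integers(*cfg.intergenic_gap))
            gaps.append((chrom, cursor, cursor + gap))
            pos = cursor + gap
        if gid >= cfg.n_genes:
            break
    if gid < cfg.n_genes:
        raise ConfigError(
            f"only {gid} of {cfg.n_genes} genes fit; increase chrom_length"
        )
    return genes, gaps


def _plant_circs(cfg: SimulationConfig, rng: np.random.Generator,
                 genes: list[GeneModel], gaps: list[tuple[str, int, int]]
                 ) -> list[TruthCirc]:
    """Choose coordinates for every planted circRNA, one per host gene."""
    circs: list[TruthCirc] = []
    eligible = [g for g in genes if len(g.exons) >= 3]
    if len(eligible) < cfg.n_circ_exonic + cfg.n_circ_intronic + cfg.n_circ_antisense:
        raise ConfigError("not enough genes to host the requested circRNAs")
    order = rng.permutation(len(eligible))
    hosts = [eligible[i] for i in order]
    cursor = 0

    # exonic: contiguous internal exon block so both flanking introns exist.
    # Sponge/DE circs must sit on + strand hosts (site embedding is done in
    # forward-genome coordinates); reorder so + strand hosts come first.
    exonic_hosts = hosts[cursor:cursor + cfg.n_circ_exonic]
    exonic_hosts.sort(key=lambda g: (g.strand != "+", g.gene_id))
    cursor += cfg.n_circ_exonic
    for g in exonic_hosts:
        n_ex = len(g.exons)
        i = int(rng.integers(1, n_ex - 1))
        j = int(rng.integers(i, n_ex - 1))
        start, end = g.exons[i][0], g.exons[j][1]
        if end - start > g.span[1] - g.span[0]:
            raise ConfigError("requested circRNA longer than host gene")
        circs.append(TruthCirc(
            key=circ_key(g.chrom, start, end, g.strand),
            circ_type="exonic", parental_gene=g.gene_id, n_exons=j - i + 1,
            flanking_intron_left=g.introns[i - 1],
            flanking_intron_right=g.introns[j],
            shared=True, pass_filter=True, de_status="none", fold=1.0,
        ))

    for g in hosts[cursor:cursor + cfg.n_circ_intronic]:
        introns = g.introns
        s, e = introns[int(rng.integers(0, len(introns)))]
        margin = max(5, (e - s) // 10)
        start = s + margin
        end = e - margin
        circs.append(TruthCirc(
            key=circ_key(g.chrom, start, end, g.strand),
            circ_type="intronic", parental_gene=g.gene_id, n_exons=None,
            flanking_intron_left=(s, e), flanking_intron_right=(s, e),
            shared=True, pass_filter=True, de_status="none", fold=1.0,
        ))
    cursor += cfg.n_circ_intronic

    for g in hosts[cursor:cursor + cfg.n_circ_antisense]:
        s0, e0 = g.span
        start = s0 + int(rng.integers(0, (e0 - s0) // 3))
        end = start + int(rng.integers(100, max(101, (e0 - s0) // 2)))
        anti = "-" if g.strand == "+" else "+"
        circs.append(TruthCirc(
            key=circ_key(g.chrom, start, min(end, e0), anti),
            circ_type="antisense", parental_gene=g.gene_id, n_exons=None,
            flanking_intron_left=None, flanking_intron_right=None,
            shared=True, pass_filter=True, de_status="none", fold=1.0,
        ))
    cursor += cfg.n_circ_antisense

    wide_gaps = [g for g in gaps if g[2] - g[1] >= 400]
    if len(wide_gaps) < cfg.n_circ_intergenic:
        raise ConfigError("not enough intergenic room for requested circRNAs")
    pick = rng.choice(len(wide_gaps), size=cfg.n_circ_intergenic, replace=False)
    for idx in sorted(int(i) for i in pick):
        chrom, s, e = wide_gaps[idx]
        start = s + 50
        end = e - 50
        strand = "+" if rng.random() < 0.5 else "-"
        circs.append(TruthCirc(
            key=circ_key(chrom, start, end, strand),
            circ_type="intergenic", parental_gene=None, n_exons=None,
            flanking_intron_left=None, flanking_intron_right=None,
            shared=True, pass_filter=True, de_status="none", fold=1.0,
        ))
    return circs


def _plant_decoys(cfg: SimulationConfig, rng: np.random.Generator
                  ) -> list[TruthCirc]:
    """Shared calls constructed to fail the length or read-support filter."""
    decoys = []
    for i in range(cfg.n_long_decoys):
        start = int(rng.integers(0, cfg.chrom_length - 13_000))
        decoys.append(TruthCirc(
            key=circ_key("chr1", start, start + 12_000 + i, "+"),
            circ_type="decoy_long", parental_gene=None, n_exons=None,
            flanking_intron_left=None, flanking_intron_right=None,
            shared=True, pass_filter=False, de_status="none", fold=1.0,
        ))
    for i in range(cfg.n_lowread_decoys):
        start = int(rng.integers(0, cfg.chrom_length - 1000))
        decoys.append(TruthCirc(
            key=circ_key("chr1", start, start + 500 + i, "-"),
            circ_type="decoy_lowread", parental_gene=None, n_exons=None,
            flanking_intron_left=None, flanking_intron_right=None,
            shared=True, pass_filter=False, de_status="none", fold=1.0,
        ))
    return decoys


# ---------------------------------------------------------------------------
# main generator


def generate(config: SimulationConfig, outdir: str | os.PathLike) -> Bundle:
    """Write the full fixture bundle; deterministic given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sequences = {
        f"chr{i + 1}": list(_random_seq(rng, cfg.chrom_length))
        for i in range(cfg.n_chromosomes)
    }
    genes, gaps = _place_genes(cfg, rng)
    circs = _plant_circs(cfg, rng, genes, gaps)
    decoys = _plant_decoys(cfg, rng)

    # DE status: planted on exonic circs (which are first in the list and
    # sorted + strand first, so sponge embedding stays in forward coords)
    exonic = [c for c in circs if c.circ_type == "exonic"]
    if cfg.n_de_up + cfg.n_de_down > len(exonic):
        raise ConfigError("more DE circs requested than exonic circs planted")
    for c in exonic[: cfg.n_de_up]:
        c.de_status, c.fold = "up", cfg.de_fold
    for c in exonic[cfg.n_de_up: cfg.n_de_up + cfg.n_de_down]:
        c.de_status, c.fold = "down", 1.0 / cfg.de_fold

    # DE genes: disjoint from circ host genes to keep truths independent
    host_ids = {c.parental_gene for c in circs if c.parental_gene}
    free = [g for g in genes if g.gene_id not in host_ids]
    plus_free = [g for g in free if g.strand == "+"]
    if len(plus_free) < cfg.n_de_genes_up or \
            len(free) < cfg.n_de_genes_up + cfg.n_de_genes_down:
        raise ConfigError("not enough non-host genes for planted DE genes")
    de_genes_up = [g.gene_id for g in plus_free[: cfg.n_de_genes_up]]
    rest = [g for g in free if g.gene_id not in set(de_genes_up)]
    de_genes_down = [g.gene_id for g in rest[: cfg.n_de_genes_down]]

    # miRNAs and sponge triples
    mirnas = {
        f"miR{i + 1:03d}": _random_seq(rng, cfg.mirna_length)
        for i in range(cfg.n_mirnas)
    }
    gene_by_id = {g.gene_id: g for g in genes}
    sponge_circs = [c for c in exonic
                    if c.de_status == "up"
                    and c.key.endswith("+")][: cfg.n_sponge_triples]
    if len(sponge_circs) < cfg.n_sponge_triples:
        raise ConfigError("not enough + strand DE exonic circs for sponges")
    sponges = []
    mirna_ids = sorted(mirnas)
    for i, circ in enumerate(sponge_circs):
        mir_id = mirna_ids[i]
        gene_id = de_genes_up[i]
        rc = reverse_complement(mirnas[mir_id])
        L = cfg.mirna_length
        split = L // 2
        chrom, start, end, _ = genome_io.parse_circ_key(circ.key)
        seq = sequences[chrom]
        # junction-spanning: tail of the circle then head of the circle
        seq[end - split:end] = list(rc[:split])
        seq[start:start + (L - split)] = list(rc[split:])
        # mRNA site: middle of an internal exon of the DE gene
        g = gene_by_id[gene_id]
        ex_s, ex_e = max(g.exons, key=lambda x: x[1] - x[0])
        mid = (ex_s + ex_e - L) // 2
        sequences[g.chrom][mid:mid + L] = list(rc)
        sponges.append((circ.key, mir_id, gene_id))

    genome = Genome({k: "".join(v) for k, v in sorted(sequences.items())})

    # ---- repeats -----------------------------------------------------------
    circ_flanks: set[tuple[str, int, int]] = set()
    for c in circs:
        if c.circ_type != "exonic":
            continue
        chrom = c.key.split(":")[0]
        for iv in (c.flanking_intron_left, c.flanking_intron_right):
            if iv:
                circ_flanks.add((chrom, iv[0], iv[1]))
    repeats: list[RepeatInterval] = []
    for g in genes:
        for s, e in g.introns:
            iv = (g.chrom, s, e)
            target = (cfg.repeat_fraction_circ if iv in circ_flanks
                      else cfg.repeat_fraction_background)
            frac = _beta_level(rng, target, 30.0)
            span = int(round(frac * (e - s)))
            if span < 5:
                continue
            off = int(rng.integers(0, e - s - span + 1))
            repeats.append(RepeatInterval(g.chrom, s + off, s + off + span, "LTR"))
    repeats.sort(key=lambda r: (r.chrom, r.start, r.end))

    # ---- methylation -------------------------------------------------------
    flank_lookup: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in circ_flanks:
        flank_lookup.setdefault(chrom, []).append((s, e))
    records = []
    for chrom in sorted(genome.sequences):
        seq = genome.sequences[chrom]
        positions = np.flatnonzero(np.frombuffer(seq.encode(), dtype=np.uint8)
                                   == ord("C"))
        keep = rng.random(len(positions)) < cfg.cytosine_sampling
        for pos in positions[keep]:
            pos = int(pos)
            nxt = seq[pos + 1: pos + 3]
            if nxt[:1] == "G":
                context = "CpG"
            elif len(nxt) == 2 and nxt[1] == "G":
                context = "CHG"
            else:
                context = "CHH"
            elevated = any(s <= pos < e for s, e in flank_lookup.get(chrom, []))
            mean = (cfg.methylation_circ if elevated
                    else cfg.methylation_background)
            level = _beta_level(rng, mean, cfg.methylation_beta_concentration)
            total = int(rng.poisson(cfg.coverage_mean))
            if total == 0:
                continue
            records.append(MethylationRecord(
                chrom, pos, context, int(rng.binomial(total, level)), total
            ))
    track = MethylationTrack(records)

    # ---- junction counts and caller tables ---------------------------------
    n_samples = cfg.n_timepoints * cfg.n_replicates
    counts: dict[str, np.ndarray] = {}
    for c in circs:
        base = (cfg.de_read_mean if c.de_status != "none"
                else float(rng.lognormal(np.log(cfg.junction_read_mean), 0.5)))
        row = np.empty(n_samples, dtype=int)
        for t in range(cfg.n_timepoints):
            mean = base if t == 0 else base * c.fold
            row[t * cfg.n_replicates:(t + 1) * cfg.n_replicates] = \
                sample_nb_counts(rng, mean, cfg.nb_dispersion,
                                 cfg.n_replicates)
        counts[c.key] = row
    for d in decoys:
        if d.circ_type == "decoy_long":
            counts[d.key] = sample_nb_counts(
                rng, cfg.junction_read_mean, cfg.nb_dispersion, n_samples)
        else:
            row = np.zeros(n_samples, dtype=int)
            row[int(rng.integers(0, n_samples))] = 1
            counts[d.key] = row

    everything = circs + decoys
    n_shared = round(cfg.caller_overlap_fraction * len(everything))
    # sharing priority: filter decoys and DE circs must reach the consensus;
    # the rest are interleaved across types so caller-unique calls are not
    # concentrated in one circRNA type
    group0, group1, buckets = [], [], {}
    for i, t in enumerate(everything):
        if t.circ_type.startswith("decoy"):
            group0.append(i)
        elif t.de_status != "none":
            group1.append(i)
        else:
            buckets.setdefault(t.circ_type, []).append(i)
    group2 = []
    max_rounds = max((len(b) for b in buckets.values()), default=0)
    for round_i in range(max_rounds):
        for ctype in sorted(buckets):
            if round_i < len(buckets[ctype]):
                group2.append(buckets[ctype][round_i])
    priority = group0 + group1 + group2
    shared_idx = set(priority[:n_shared])
    calls_a, calls_b = [], []
    for rank, i in enumerate(priority):
        t = everything[i]
        t.shared = i in shared_idx
        chrom, start, end, strand = genome_io.parse_circ_key(t.key)
        reads = counts[t.key]
        call_a = CircCall(chrom, start, end, strand, "caller_a",
                          tuple(int(x) for x in reads))
        reads_b = rng.binomial(reads, 0.85)
        call_b = CircCall(chrom, start, end, strand, "caller_b",
                          tuple(int(x) for x in reads_b))
        if t.shared:
            calls_a.append(call_a)
            calls_b.append(call_b)
        elif (rank - n_shared) % 2 == 0:
            calls_a.append(call_a)
        else:
            calls_b.append(call_b)

    # caller B thinning may drop a planted consensus circ below the read
    # filter only if caller A also fails; pass_filter reflects the merged max
    for t in everything:
        if t.shared and t.pass_filter:
            t.pass_filter = int(counts[t.key].max()) >= 2

    # ---- gene counts -------------------------------------------------------
    gene_counts: dict[str, np.ndarray] = {}
    for g in genes:
        base = float(rng.lognormal(np.log(cfg.gene_count_mean), 0.8))
        if g.gene_id in de_genes_up:
            fold = cfg.de_fold
        elif g.gene_id in de_genes_down:
            fold = 1.0 / cfg.de_fold
        else:
            fold = 1.0
        row = np.empty(n_samples, dtype=int)
        for t in range(cfg.n_timepoints):
            mean = base if t == 0 else base * fold
            row[t * cfg.n_replicates:(t + 1) * cfg.n_replicates] = \
                sample_nb_counts(rng, mean, cfg.nb_dispersion,
                                 cfg.n_replicates)
        gene_counts[g.gene_id] = row

    lib_sizes = np.round(
        cfg.clean_reads_mean * rng.uniform(0.9, 1.1, size=n_samples)
    ).astype(int)

    # term map: one cold-response term enriched among planted DE genes
    de_all = set(de_genes_up) | set(de_genes_down)
    term_map: dict[str, list[str]] = {"GO:cold_response": [],
                                      "GO:metabolism": [],
                                      "GO:transport": []}
    for g in genes:
        if g.gene_id in de_all:
            if rng.random() < 0.8:
                term_map["GO:cold_response"].append(g.gene_id)
        elif rng.random() < 0.1:
            term_map["GO:cold_response"].append(g.gene_id)
        if rng.random() < 0.3:
            term_map["GO:metabolism"].append(g.gene_id)
        if rng.random() < 0.2:
            term_map["GO:transport"].append(g.gene_id)

    truth = TruthTable(
        circs=[c for c in everything],
        sponges=sponges,
        de_genes_up=de_genes_up,
        de_genes_down=de_genes_down,
    )

    paths = _write_bundle(cfg, outdir, genome, genes, repeats, track,
                          calls_a, calls_b, counts, gene_counts, lib_sizes,
                          mirnas, term_map, truth)
    return Bundle(cfg, outdir, paths, genome, genes, truth)


def _write_bundle(cfg, outdir: Path, genome, genes, repeats, track,
                  calls_a, calls_b, counts, gene_counts, lib_sizes,
                  mirnas, term_map, truth) -> dict[str, Path]:
    p = {name: outdir / fname for name, fname in {
        "genome": "genome.fa",
        "annotation": "annotation.gff3",
        "repeats": "repeats.bed",
        "methylation": "methylation.tsv",
        "caller_a": "caller_a.tsv",
        "caller_b": "caller_b.tsv",
        "circ_counts": "circ_counts.tsv",
        "gene_counts": "gene_counts.tsv",
        "library_sizes": "library_sizes.tsv",
        "mirnas": "mirnas.fa",
        "term_map": "term_map.tsv",
        "truth_circs": "truth_circs.tsv",
        "truth_sponges": "truth_sponges.tsv",
        "config": "config.txt",
    }.items()}
    samples = cfg.sample_names

    genome_io.write_fasta(genome.sequences, p["genome"])
    genome_io.gff3_from_gene_models(genes, p["annotation"])
    genome_io.write_bed(repeats, p["repeats"])
    genome_io.write_methylation(track, p["methylation"])
    genome_io.write_circ_calls(calls_a, p["caller_a"], samples)
    genome_io.write_circ_calls(calls_b, p["caller_b"], samples)

    with open(p["circ_counts"], "w") as fh:
        fh.write("id\t" + "\t".join(samples) + "\n")
        for c in truth.circs:
            if c.circ_type.startswith("decoy"):
                continue
            fh.write(c.key + "\t" + "\t".join(map(str, counts[c.key])) + "\n")
    with open(p["gene_counts"], "w") as fh:
        fh.write("id\t" + "\t".join(samples) + "\n")
        for g in genes:
            fh.write(g.gene_id + "\t"
                     + "\t".join(map(str, gene_counts[g.gene_id])) + "\n")
    with open(p["library_sizes"], "w") as fh:
        fh.write("sample\tclean_reads\n")
        for s, v in zip(samples, lib_sizes):
            fh.write(f"{s}\t{v}\n")
    genome_io.write_fasta(mirnas, p["mirnas"])
    with open(p["term_map"], "w") as fh:
        fh.write("gene_id\tterm\n")
        for term in sorted(term_map):
            for gid in sorted(term_map[term]):
                fh.write(f"{gid}\t{term}\n")

    with open(p["truth_circs"], "w") as fh:
        fh.write("key\ttype\tparental_gene\tn_exons\tflank_left\tflank_right"
                 "\tshared\tpass_filter\tde_status\tfold\n")
        for c in truth.circs:
            fl = f"{c.flanking_intron_left[0]}-{c.flanking_intron_left[1]}" \
                if c.flanking_intron_left else "."
            fr = f"{c.flanking_intron_right[0]}-{c.flanking_intron_right[1]}" \
                if c.flanking_intron_right else "."
            fh.write("\t".join([
                c.key, c.circ_type, c.parental_gene or ".",
                str(c.n_exons if c.n_exons is not None else "."),
                fl, fr, str(int(c.shared)), str(int(c.pass_filter)),
                c.de_status, f"{c.fold:g}",
            ]) + "\n")
    with open(p["truth_sponges"], "w") as fh:
        fh.write("circ_key\tmirna_id\tgene_id\n")
        for circ, mir, gene in truth.sponges:
            fh.write(f"{circ}\t{mir}\t{gene}\n")
    with open(p["config"], "w") as fh:
        for k, v in asdict(cfg).items():
            fh.write(f"{k}={v}\n")
    return p


def transcript_sequence(gene: GeneModel, genome: Genome) -> str:
    """Spliced mRNA sequence of a gene model (exons joined, stranded)."""
    seq = "".join(genome.fetch(gene.chrom, s, e) for s, e in gene.exons)
    return reverse_complement(seq) if gene.strand == "-" else seq
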