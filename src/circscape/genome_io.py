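"""Genome, annotation, and track I/O.

All coordinates are 0-based half-open internally. File formats that use
other conventions (GFF3: 1-based closed) are converted exactly once, on
ingest. Downstream modules never touch a file format directly; they query
the containers defined here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = set("ACGTN")
METHYLATION_CONTEXTS = ("CpG", "CHG", "CHH")
REPEAT_CLASSES = ("LTR", "LINE", "SINE", "DNA", "other")


class ValidationError(ValueError):
    """An input record violates a structural invariant."""


class ParseError(ValueError):
    """A file could not be parsed; message names the offending line."""


@dataclass
class Genome:
    """A genome as a name -> uppercase nucleotide-string map."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValidationError(
                    f"chromosome {name!r} contains invalid bases: {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return genome[start:end) on the forward strand."""
        if chrom not in self.sequences:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        if not (0 <= start <= end <= len(self.sequences[chrom])):
            raise ValidationError(
                f"interval [{start},{end}) outside {chrom} "
                f"(length {len(self.sequences[chrom])})"
            )
        return self.sequences[chrom][start:end]


@dataclass
class GeneModel:
    """One gene collapsed to a single exon chain.

    ``exons`` are non-overlapping [start, end) intervals sorted by start;
    introns are the gaps between consecutive exons.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"gene {self.gene_id}: no exons")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for s, e in self.exons:
            if e <= s:
                raise ValidationError(f"gene {self.gene_id}: empty exon [{s},{e})")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValidationError(f"gene {self.gene_id}: overlapping exons")

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
            if s2 > e1
        ]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class RepeatInterval:
    chrom: str
    start: int
    end: int
    repeat_class: str = "other"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"repeat [{self.start},{self.end}): end <= start")
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValidationError(f"unknown repeat class {self.repeat_class!r}")


@dataclass(frozen=True)
class MethylationRecord:
    chrom: str
    position: int
    context: str
    methylated: int
    total: int

    def __post_init__(self) -> None:
        if self.context not in METHYLATION_CONTEXTS:
            raise ValidationError(f"unknown context {self.context!r}")
        if not (0 <= self.methylated <= self.total):
            raise ValidationError(
                f"{self.chrom}:{self.position}: methylated {self.methylated} "
                f"> total {self.total}"
            )


@dataclass
class MethylationTrack:
    """Per-cytosine methylated/total read counts."""

    records: list[MethylationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for r in self.records:
            key = (r.chrom, r.position, r.context)
            if key in seen:
                raise ValidationError(f"duplicate cytosine record {key}")
            seen.add(key)

    def in_interval(
        self, chrom: str, start: int, end: int, context: str | None = None
    ) -> list[MethylationRecord]:
        return [
            r
            for r in self.records
            if r.chrom == chrom
            and start <= r.position < end
            and (context is None or r.context == context)
        ]


@dataclass(frozen=True)
class CircCall:
    """One caller's back-splice junction call with per-sample read support."""

    chrom: str
    start: int
    end: int
    strand: str
    caller: str
    reads: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"{self.chrom}:{self.start}|{self.end}: end <= start"
            )
        if any(r < 0 for r in self.reads):
            raise ValidationError(f"{self.key}: negative read count")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.start}|{self.end}:{self.strand}"

    @property
    def genomic_length(self) -> int:
        return self.end - self.start


def circ_key(chrom: str, start: int, end: int, strand: str) -> str:
    return f"{chrom}:{start}|{end}:{strand}"


def parse_circ_key(key: str) -> tuple[str, int, int, str]:
    chrom, coords, strand = key.rsplit(":", 2)
    start, end = coords.split("|")
    return chrom, int(start), int(end), strand


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path: str | os.PathLike) -> None:
    seqrecs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_genome(path: str | os.PathLike) -> Genome:
    return Genome(read_fasta(path))


# ---------------------------------------------------------------------------
# GFF3


def _collapse_transcripts(db: gffutils.FeatureDB, gene) -> list[tuple[int, int]]:
    """Pick the exon chain of the transcript with the greatest exonic length.

    Ties broken by exon count (more exons win), then transcript id.
    """
    best: tuple[int, int, str, list[tuple[int, int]]] | None = None
    for mrna in db.children(gene, featuretype=("mRNA", "transcript")):
        exons = [
            (f.start - 1, f.end)  # GFF3 is 1-based closed
            for f in db.children(mrna, featuretype="exon")
        ]
        if not exons:
            continue
        exonic_len = sum(e - s for s, e in exons)
        cand = (exonic_len, len(exons), mrna.id, sorted(exons))
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
    if best is None:
        # gene with exons as direct children (no mRNA level)
        exons = [
            (f.start - 1, f.end) for f in db.children(gene, featuretype="exon")
        ]
        if not exons:
            raise ValidationError(f"gene {gene.id}: no exon features")
        return sorted(exons)
    return best[3]


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from GFF3, collapsing multi-transcript genes.

    Coordinates are converted from the file's 1-based closed convention to
    0-based half-open. For a gene with several transcripts the exon chain
    of the longest (greatest total exonic length) transcript is kept.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            if not (fields[3].isdigit() and fields[4].isdigit()):
                raise ParseError(
                    f"{path}:{lineno}: non-numeric coordinates"
                )
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted exception types
        raise ParseError(f"malformed GFF3 {path}: {exc}") from exc

    models = []
    for gene in db.features_of_type("gene"):
        exons = _collapse_transcripts(db, gene)
        gene_span = (gene.start - 1, gene.end)
        for s, e in exons:
            if s < gene_span[0] or e > gene_span[1]:
                raise ValidationError(
                    f"gene {gene.id}: exon [{s},{e}) outside gene span {gene_span}"
                )
        models.append(
            GeneModel(gene_id=gene.id, chrom=gene.seqid, strand=gene.strand, exons=exons)
        )
    return models


# ---------------------------------------------------------------------------
# circRNA call tables (BED-like TSV: chrom, start, end, strand, reads...)


def read_circ_calls(path: str | os.PathLike, caller_name: str) -> list[CircCall]:
    """Read one caller's junction-call table.

    Expected columns: chrom, start, end, strand, then one junction-read
    count per sample. Duplicate keys within the table are merged by
    summing the per-sample read counts.
    """
    merged: dict[str, CircCall] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: expected >=5 columns")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                strand = fields[3]
                reads = tuple(int(x) for x in fields[4:])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            call = CircCall(chrom, start, end, strand, caller_name, reads)
            if call.key in merged:
                prev = merged[call.key]
                if len(prev.reads) != len(call.reads):
                    raise ValidationError(
                        f"{path}:{lineno}: inconsistent sample count for {call.key}"
                    )
                call = CircCall(
                    chrom,
                    start,
                    end,
                    strand,
                    caller_name,
                    tuple(a + b for a, b in zip(prev.reads, call.reads)),
                )
            merged[call.key] = call
    return list(merged.values())


def write_circ_calls(
    calls: list[CircCall], path: str | os.PathLike, sample_names: list[str]
) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tstrand\t" + "\t".join(sample_names) + "\n")
        for c in sorted(calls, key=lambda c: (c.chrom, c.start, c.end, c.strand)):
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.strand}\t"
                + "\t".join(str(r) for r in c.reads)
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED6 (repeats and generic intervals; name column carries repeat_class)


def write_bed(
    intervals: list[RepeatInterval] | list[tuple], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if isinstance(iv, RepeatInterval):
                chrom, start, end, name = iv.chrom, iv.start, iv.end, iv.repeat_class
                strand = "+"
            else:
                chrom, start, end, name, strand = (list(iv) + ["region", "+"])[:5]
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")


def read_repeats(path: str | os.PathLike) -> list[RepeatInterval]:
    repeats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >=4 BED columns")
            repeats.append(
                RepeatInterval(fields[0], int(fields[1]), int(fields[2]), fields[3])
            )
    return repeats


# ---------------------------------------------------------------------------
# methylation track (TSV: chrom, position, context, methylated, total)


def read_methylation(path: str | os.PathLike) -> MethylationTrack:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns")
            try:
                rec = MethylationRecord(
                    fields[0], int(fields[1]), fields[2], int(fields[3]), int(fields[4])
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return MethylationTrack(records)


def write_methylation(track: MethylationTrack, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tposition\tcontext\tmethylated\ttotal\n")
        for r in track.records:
            fh.write(f"{r.chrom}\t{r.position}\t{r.context}\t{r.methylated}\t{r.total}\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def gff3_from_gene_models(models: list[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as a minimal gene/mRNA/exon GFF3 (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            s0, e0 = g.span
            fh.write(
                f"{g.chrom}\t.\tgene\t{s0 + 1}\t{e0}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\t.\tmRNA\t{s0 + 1}\t{e0}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\t.\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
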