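"""Consensus filtering of back-splice junction calls from two callers.

Back-splice callers disagree substantially on real data, so only junctions
reported by both callers, with adequate read support and a plausible
genomic span, are kept as the high-confidence circRNA set.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import CircCall, ValidationError


@dataclass(frozen=True)
class CircRNA:
    """A high-confidence circRNA merged across callers."""

    chrom: str
    start: int
    end: int
    strand: str
    reads: tuple[int, ...]
    provenance: frozenset[str]

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.start}|{self.end}:{self.strand}"

    @property
    def genomic_length(self) -> int:
        return self.end - self.start

    @property
    def max_reads(self) -> int:
        return max(self.reads) if self.reads else 0


def _by_key(calls: list[CircCall]) -> dict[str, CircCall]:
    index: dict[str, CircCall] = {}
    for c in calls:
        if c.key in index:
            prev = index[c.key]
            c = CircCall(
                c.chrom, c.start, c.end, c.strand, c.caller,
                tuple(a + b for a, b in zip(prev.reads, c.reads)),
            )
        index[c.key] = c
    return index


def consensus_filter(
    calls_a: list[CircCall],
    calls_b: list[CircCall],
    min_junction_reads: int = 2,
    max_length: int = 10_000,
) -> list[CircRNA]:
    """Intersect two callers' junction calls and apply support/length filters.

    A junction is kept when (1) both callers report the exact key, (2) its
    genomic span is at most ``max_length`` bp, and (3) its best per-sample
    junction-read support after merging is at least ``min_junction_reads``
    (inclusive). Per-sample reads are merged across callers by taking the
    maximum, since both callers count the same underlying junction reads.
    Output is sorted by (chrom, start, end).
    """
    if min_junction_reads < 0 or max_length < 0:
        raise ValidationError("thresholds must be non-negative")
    index_a = _by_key(calls_a)
    index_b = _by_key(calls_b)
    out = []
    for key in set(index_a) & set(index_b):
        a, b = index_a[key], index_b[key]
        if len(a.reads) != len(b.reads):
            raise ValidationError(f"{key}: callers disagree on sample count")
        merged = tuple(max(x, y) for x, y in zip(a.reads, b.reads))
        circ = CircRNA(
            a.chrom, a.start, a.end, a.strand, merged,
            provenance=frozenset({a.caller, b.caller}),
        )
        if circ.genomic_length > max_length:
            continue
        if circ.max_reads < min_junction_reads:
            continue
        out.append(circ)
    return sorted(out, key=lambda c: (c.chrom, c.start, c.end, c.strand))


def overlap_stats(calls_a: list[CircCall], calls_b: list[CircCall]) -> dict:
    """Caller agreement bookkeeping: set sizes, intersection, and Jaccard."""
    keys_a, keys_b = set(_by_key(calls_a)), set(_by_key(calls_b))
    union = keys_a | keys_b
    inter = keys_a & keys_b
    return {
        "n_a": len(keys_a),
        "n_b": len(keys_b),
        "n_shared": len(inter),
        "n_union": len(union),
        "jaccard": (len(inter) / len(union)) if union else 0.0,
        "undefined": not union,
    }


def write_consensus(
    circs: list[CircRNA], path, sample_names: list[str]
) -> None:
    with open(path, "w") as fh:
        fh.write("key\tchrom\tstart\tend\tstrand\tprovenance\t"
                 + "\t".join(sample_names) + "\n")
        for c in circs:
            fh.write("\t".join([
                c.key, c.chrom, str(c.start), str(c.end), c.strand,
                ";".join(sorted(c.provenance)),
                *[str(r) for r in c.reads],
            ]) + "\n")


def read_consensus(path) -> list[CircRNA]:
    circs = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            f = line.rstrip("\n").split("\t")
            circs.append(CircRNA(
                f[1], int(f[2]), int(f[3]), f[4],
                tuple(int(x) for x in f[6:]),
                provenance=frozenset(f[5].split(";")),
            ))
    return circs


def circrna_as_calls(circs: list[CircRNA]) -> tuple[list[CircCall], list[CircCall]]:
    """Re-express consensus circRNAs as two identical call lists.

    Used to verify idempotence: filtering the consensus against itself with
    the same thresholds must be the identity.
    """
    def as_call(c: CircRNA, caller: str) -> CircCall:
        return CircCall(c.chrom, c.start, c.end, c.strand, caller, c.reads)

    return (
        [as_call(c, "consensus_a") for c in circs],
        [as_call(c, "consensus_b") for c in circs],
    )
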