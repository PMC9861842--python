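# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `circscape`. Coordinates are 0-based half-open
throughout the library; GFF3 input (1-based closed) is converted exactly
once on ingest.

## Consensus identification

Two back-splice callers' tables are normalized to the key scheme
`chrom:start|end:strand` and intersected exactly. Rationale for the three
rules:

- **Exact key matching.** Fuzzy ±1 junction matching trades precision for
  recall in a way that is hard to audit; the exact rule is the default and
  a tolerance flag is deliberately absent from the core operation.
- **Read support ≥ 2, inclusive.** Real junction-read distributions put
  their mode at two unique reads; an exclusive "> 2" rule would discard
  that mode. The threshold is a flag (`--min-reads`).
- **Genomic span ≤ 10 kb.** "Length" is taken as genomic span, not spliced
  length, because intronic and intergenic circles have no splice model to
  measure a spliced length on.
- **Cross-caller merge = per-sample maximum.** Both callers count the same
  underlying junction reads, so summing would double-count; the maximum is
  the least-surprising reconciliation of two measurements of one quantity.

`overlap_stats` reports Jaccard |A∩B|/|A∪B|; with both sets empty it
returns 0 with an `undefined` flag rather than raising.

## Classification

The decision cascade is exonic > intronic > antisense > intergenic, first
match wins; this ordering mirrors both common practice and the observed
dominance of exonic circles. "Junction end on an exon" admits a boundary
tolerance flag (default 0 bp — synthetic data is exact; real callers may
need ±2). A circle overlapping two same-strand genes is assigned the gene
covering the larger fraction of it, ties broken lexicographically.
Antisense is defined by *any* opposite-strand overlap (no requirement that
the ends fall on the antisense gene's exons); the stricter reading would
only shrink an already small class. A same-strand overlap that is neither
end-on-exon nor inside-one-intron matches no rule of the cascade; such
circles necessarily cover at least one exon and are assigned exonic with
the covering gene.

Multi-transcript genes collapse to the transcript with the greatest total
exonic length (ties: more exons, then id). Any single-chain convention is
defensible; this one maximizes the exon evidence available to the
end-on-exon test.

## Junction sequences and conservation

The junction sequence is the circle's last m bases followed by its first m
bases, m = min(100, L), read in circular orientation (for minus-strand
circles the circle is reverse-complemented first). This makes the
back-splice joint an internal position (`junction_offset`) that alignments
and binding sites can be required to span — the property that
distinguishes evidence of *circularity* from mere sequence similarity of
the locus.

Alignment route: exact-word seeding (word size 11) prefilters subjects,
then a full affine-gap Smith–Waterman (match +1, mismatch −2, gap open −5
plus −2 per gapped residue) scores each candidate. E-values use the
Karlin–Altschul form E = K·m·n·exp(−λS) with K = 0.711, λ = 1.37 for this
scoring scheme and n = the individual subject length; the constants are
fixed so results reproduce bit-for-bit. A hit counts as conservation
evidence only when E ≤ 1e-5 *and* the aligned query span covers the two
bases around the joint. The aligner is validated in the test suite against
an independent implementation (Biopython's `PairwiseAligner`) on all
fixture pairs.

k-mer route: per-kb counts of all 4^k k-mers (k = 6 default; 4096
components stay informative at the 200 bp junction-sequence scale),
z-scored per component against the union of all sequences in the
comparison (the background the standardization needs is not otherwise
specified, and the union is the only choice that treats query and subject
sets symmetrically). Conservation is Pearson r strictly greater than 0.2;
r at exactly the threshold is *not* conserved. Zero-variance profiles
yield NaN with a flag rather than a silent 0.

## Flanking-intron features

- `repeat_fraction` merges overlapping repeat intervals before measuring
  coverage, so nested annotations cannot push the fraction above 1.
- `weighted_methylation` is Σ methylated / Σ total reads over cytosines in
  the interval — the coverage-weighted estimator, which is additive over
  disjoint intervals by construction. Intervals with no covered cytosine
  return NaN, never 0.
- The metagene profile rescales each interval body to `n_bins` bins
  (default 20) with fixed-width flanks (default 2000 bp in 10 bins per
  side) and pools read counts per bin before dividing (coverage
  weighting). Bin counts and flank width are presentation choices exposed
  as flags, not claims.
- Group comparisons default to Welch's unequal-variance t-test on log10
  values for length-like features (length distributions are heavy-tailed
  and group variances are not plausibly equal); the classic pooled test is
  a flag, and a Mann–Whitney p-value is always reported alongside as a
  robustness column. Fractions and methylation levels are compared on
  their natural scale.
- The linear background is an equal-size uniform sample (without
  replacement, seeded) of genes with no detected circRNA; "random intron
  regions" means introns of those sampled genes, not arbitrary genomic
  windows, so the comparison is like-with-like.

## Expression and differential expression

RPB = junction reads / (clean reads / 1e9); binning is low < 100,
100 ≤ medium ≤ 500, high > 500 — the published bin edges leave (500, 501)
unassigned, and since RPB is continuous the gap is closed at 500. FPKM is
the standard fragments / (kb of exon model × millions mapped).

The DE test is an exact conditional negative-binomial test in the small-
sample RNA-seq tradition: counts are scaled to the geometric-mean library
size and rounded; a common dispersion is estimated by the method of
moments, (v − m)/m² pooled over features and groups, floored at 1e-4; for
each feature the two group sums are compared under the null that both
groups share mean t/(n_a+n_b), with the two-sided p summing all outcomes
no more likely than the observed one; BH adjustment across features.
log2FC uses a 0.5 pseudocount on normalized means. Thresholds follow the
emulated design: circRNAs |log2FC| > 1 with raw p ≤ 0.05, genes fold ≥ 2
with BH-adjusted p ≤ 0.05 — both are flags. Multi-timepoint designs test
each condition against the control and union the calls.

Calibration (asserted in the acceptance suite, 2000 features, NB mean 100,
dispersion 0.1, 3 vs 3): empirical type-I error ≈ 0.05 at α = 0.05;
planted 4-fold features recovered with sensitivity ≥ 0.9 and FDR ≤ 0.1
under BH 0.05, *given external library sizes*. Library sizes are meant to
be clean-read totals (the same quantity RPB normalizes by); the
column-sum fallback is subject to composition bias when a large fraction
of features changes in one direction, exactly as total-count normalization
is in any count-based DE analysis.

GO-style enrichment is a flat one-sided hypergeometric upper-tail test
per term with BH control; no DAG propagation (the term map is taken as
given).

## miRNA sites and the sponge network

The expectation score slides the reverse complement of the mature miRNA
along the target: match 0, G:U wobble 0.5, mismatch 1, gap 2, all doubled
at miRNA positions 2–13 (seed-critical region); at most one bulge on
either strand; hard limits of ≤ 4 mismatches and no mismatch run > 2 in
the seed; a site is reported when the summed expectation is ≤ 5. These are
the cited target-prediction tool's published defaults, exposed as flags. A
vectorized screen computes the exact expectation of every offset/variant
first and the full scorer (which also applies the hard limits and emits
per-position states) runs only on offsets that could pass — the screen
ignores only constraints that reject, so no passing site can be missed.

circRNA sites are searched on the junction sequence, so junction-spanning
sites are detectable and site detection is a strict superset of scanning
the two linear flanks. mRNA sites are searched on the full spliced
transcript (no CDS/UTR distinction). The network keeps circ–miRNA edges
for DE circRNAs and miRNA–mRNA edges for DE genes, prunes miRNAs lacking
either edge type (a sponge claim needs both sides), and never emits a
direct circ–mRNA edge. Binding anywhere on the junction sequence
qualifies; junction overlap is not additionally required for network
membership.

## Synthetic data: what it emulates, and what it does not

The generator plants, under one seed, everything the pipeline claims to
recover: a 2-chromosome (200 kb each), 60-gene genome; 24/8/4/2
exonic/intronic/intergenic/antisense circRNAs (a scaled-down mirror of the
reported ~71/21/8/1% mix), one per host gene, with exonic circles placed
on internal exon blocks so both flanking introns exist; two caller tables
sharing exactly round(overlap × n) keys (default 0.8), with two over-long
(> 10 kb) and two under-supported decoys to exercise the filters; junction
read counts NB with dispersion 0.1 over 5 timepoints × 3 replicates,
fold 4 up / 0.25 down planted at all treatment timepoints on six exonic
circles (DE baseline mean 100); LTR repeat coverage ~0.45 in circ flanking
introns vs ~0.15 elsewhere and weighted methylation ~0.6 vs ~0.25
(per-cytosine: beta-distributed level, Poisson(20) coverage, binomial
methylated reads, context read off the sequence); 12 random 21-nt miRNAs
with three sponge triples whose reverse-complement binding sites are
embedded junction-spanning in the circle and verbatim in a DE gene's
exon. Sponge circles and target genes are restricted to the + strand so
the embedding arithmetic stays in forward-genome coordinates.

Deliberately absent, hence untested by the bundle: read-level sequencing
noise and caller-specific artifacts (calls are planted, not re-detected
from reads); isoform complexity beyond one transcript per gene; realistic
repeat taxonomies (all planted repeats are LTR); inter-feature correlation
(the association of circles with *longer* host genes seen in real data is
not planted, so the gene-length comparison on synthetic data is null by
design); cross-species conservation structure (subject databases for the
conservation stage are user-supplied or built in tests). Passing the
bundle therefore demonstrates correctness of the pipeline's logic and
statistics on data satisfying its assumptions, not robustness to the
failure modes of real caller output.

Problem sizes throughout (60 genes, ≤ 42 calls, 2000-feature calibration
matrices) are chosen so the full test suite and the acceptance script
each complete in seconds while keeping every statistical assertion
well-powered.

## Degenerate inputs and tie-breaks

Empty caller intersection → empty consensus (not an error). Unknown
chromosome at classification → intergenic with a warning. Zero-variance
groups in a t-test → p = 1 when means agree, 0 otherwise. No covered
cytosine → NaN. Binding-site variants tying on expectation prefer the
ungapped (longer-window) alignment; overlapping sites of one miRNA
collapse to the best-scoring one. Missing optional inputs (methylation
track, repeat BED, miRNA FASTA, subject database) skip their section with
an explicit warning and leave the rest of the run intact.
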