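# circscape

Characterization of plant circular RNAs (circRNAs) from back-splice
junction calls: consensus identification, classification, conservation
scoring, flanking-intron feature analysis, expression and differential
expression, and circRNA–miRNA–mRNA "sponge" network construction.

## The problem

Circular RNAs arise when a downstream splice donor ligates back to an
upstream acceptor, producing a covalently closed transcript whose
back-splice junction is the detection signal. In plants under abiotic
stress (e.g. tea plant under chilling), circRNAs are identified from
rRNA-depleted, RNase-R-treated RNA-seq by junction-calling tools that
disagree substantially — so the first analysis step is a consensus of two
callers, followed by read-support and length filters. Downstream questions
are then: what kind of circRNA is each call (exonic, intronic, intergenic,
antisense)? Are the circles conserved across species? Do their flanking
introns carry more transposable-element sequence and DNA methylation than
the genome background (a proposed biogenesis mechanism)? Which circRNAs
respond to the stress, and which could act as miRNA sponges that de-repress
stress-responsive mRNAs?

`circscape` implements that pipeline as a tested library + CLI, together
with a seeded synthetic-data generator that plants known ground truth
(circRNA types, parental genes, fold changes, repeat/methylation
enrichment, miRNA binding sites) so every stage can be validated end to
end without any external download.

## Core statistics and models

- **Consensus filter** — keep junctions called by both callers with
  genomic span ≤ 10 kb and max per-sample junction reads ≥ 2; per-sample
  reads merged across callers by maximum. Caller agreement reported as
  Jaccard |A∩B|/|A∪B|.
- **Type cascade** — exonic (both junction ends on exons of one
  same-strand gene) > intronic (inside one intron) > antisense (opposite
  strand overlap only) > intergenic.
- **Junction sequence** — last min(100, L) bases of the circle joined to
  its first min(100, L) bases, so alignments and miRNA sites can span the
  back-splice joint.
- **Conservation** — (1) seeded affine-gap local alignment
  (+1/−2, gap open −5, extend −2) with Karlin–Altschul E ≤ 1e-5 and the
  requirement that the aligned region covers the junction; (2)
  alignment-free k-mer profiles: per-kb counts of all 4^k k-mers (k = 6),
  z-scored against a background set, compared by Pearson r with a strict
  r > 0.2 conservation call.
- **Flanking features** — repeat coverage of merged repeat intervals;
  weighted methylation level Σ methylated / Σ total reads over cytosines;
  metagene profiles; Welch t-tests (plus Mann–Whitney) against an
  equal-size random sample of genes without circRNAs.
- **Expression** — RPB = junction reads / (clean reads / 1e9), binned
  low (<100) / medium (100–500) / high (>500); FPKM for linear genes.
- **Differential expression** — exact two-sided negative-binomial test on
  library-size-equalized group sums with a method-of-moments common
  dispersion, BH correction; log2FC with a 0.5 pseudocount; per-timepoint
  comparisons against the control unioned.
- **Sponge network** — psRNATarget-style expectation score (G:U 0.5,
  mismatch 1, gap 2, doubled at miRNA positions 2–13, ≤ 1 bulge,
  expectation ≤ 5), sites searched on the circular junction sequence;
  tripartite network keeps circ–miRNA and miRNA–mRNA edges whose
  circRNA/mRNA is differentially expressed and prunes miRNAs lacking
  either edge type.

## Worked example

```bash
circscape simulate --seed 4 --outdir bundle
circscape run-all --bundle bundle --outdir out --seed 4
```

The first command writes a complete synthetic study (genome FASTA, GFF3,
repeats BED, methylation track, two caller tables, count matrices, miRNA
FASTA, truth tables). The second runs every stage and prints

```
report written to out/report.json
```

with `out/report.md` summarizing (numbers for seed 4):

```
## Consensus
- caller A: 38 keys; caller B: 38 keys
- shared: 34 (Jaccard 0.810)
- high-confidence after filters: 30

## Classification
- exonic: 16 (53.3%)
- intronic: 8 (26.7%)
- intergenic: 4 (13.3%)
- antisense: 2 (6.7%)
- parental genes: 24

## Flanking features (circular vs linear)
- repeat_fraction: mean 0.448 vs 0.203, p = 6.36e-12
- methylation: mean 0.608 vs 0.285, p = 2.89e-17

## Sponge network
- 3 circRNAs, 3 miRNAs, 3 mRNAs, 6 edges
```

Reading: of 42 planted junction calls, 34 are shared between the two
simulated callers; the 2 over-long and 2 under-supported decoys are
filtered, leaving 30 high-confidence circRNAs whose types match the
planted truth exactly. Flanking introns of the circularized exons show
the planted ~2–3× enrichment in repeat coverage and weighted methylation
over the sampled linear-gene background at vanishing p-values, and the
three planted sponge triples surface as exactly the six network edges.

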