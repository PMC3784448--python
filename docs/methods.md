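# Methods

This note records the models behind `xenopart`, the defaults that matter,
and what the synthetic test surface does and does not demonstrate.

## Species-of-origin partition

The unit of classification is the *fragment* (read pair): mates are sequenced
from one molecule, so species assignment per-pair is both better-powered and
the only choice consistent with emitting paired FASTQ per category. A
single-end mode (`ClassifyConfig(unit="single")`) exists for completeness.

A fragment counts as "mapped" to a genome when, among its primary alignment
records: both mates are FLAG-mapped, both are properly paired (same
reference, opposite strands, insert within the expected window — required by
default for DNA libraries, disabled for RNA-seq where splice-spanning mates
are legitimately discordant), and the *minimum* of the two mate MAPQs is at
least `min_mapq` (default 20). The MAPQ gate removes multi-hit reads, whose
placements are untrustworthy in either genome; it is applied symmetrically to
both references before partitioning. Whether this gate should be an enforced
filter or merely a reported diagnostic is genuinely open; it defaults on and
can be dropped with `min_mapq=0`.

MAPQ 255 means "quality unavailable" in the SAM specification. For
partitioning such records count as mapped — the aligner asserted a location —
but pileup depth calculations exclude them (both behaviours configurable via
`treat_mapq_unavailable_as`). Secondary and supplementary records never
participate.

Two routes produce the partition: direct set algebra over the two mapped-id
sets, and the sequential recipe (primary alignment to graft; realignment of
the graft-mapped and graft-unmapped sets to host; subtraction of the common
ids) that mirrors how the workflow runs with external aligners. They are
algebraically identical; the test suite nevertheless executes both and
compares, because the sequential path is what a user reproduces with
samtools and two aligner runs.

Membership in *common* is by mapping status only — no requirement that the
two placements be homologous loci. Duplicate marking (coordinate-keyed,
highest summed base quality kept, id tie-break) runs per-genome after
classification and only in DNA workflows; RNA-seq coverage is inherently
duplicated by expression and is left untouched.

## Quality trimming

Sliding-window trimming scans 6-base windows left to right and truncates the
read before the first window whose mean Phred quality falls below 20; reads
shorter than 50 nt afterwards are discarded, and a pair is discarded whenever
either mate is (classification is pair-based). Output is always a prefix of
the input, so trimming is idempotent. No leading-end trim and no adapter
clipping: the rule is deliberately the simplest windowed-average semantics.
Quality encoding is fixed at Phred+33 and enforced; gzip is sniffed from the
file extension.

## The micro-aligner

`microalign` exists so the whole pipeline — including the host-contamination
window check — runs on synthetic fixtures with no external aligners. It
indexes every forward-strand k-mer (k = 21), seeds reads with non-overlapping
k-mers on both strands, extends ungapped, and reports the placement with the
fewest mismatches (ties broken toward '+' strand, then lowest coordinate).
Its mapping quality is internal and documented, not an emulation of any
production aligner:

```
mapq_like = 0                                   if two equal-best placements
          = min(60, 10 · (mm₂ − mm₁))           otherwise (60 if no second hit)
```

The guarantee that matters downstream: reads from exact repeats get
mapq_like = 0 and are removed by the MAPQ ≥ 20 gate. Default mismatch budget
is 5 for 101 nt reads (~5%). Indels are not aligned — the aligner is a
fixture generator, and the classifier treats any SAM producer identically.

## The simulator

`simulate` emulates the structure of a xenograft experiment, not its full
error physics:

- **Genome pair**: a random ancestor evolves into two lineages by independent
  site substitutions; the per-lineage rate q solves
  2q(1−q) + (2/3)q² = D so that the *pairwise* divergence equals the
  parameter D. Default D = 0.12 is a human/mouse-like stand-in (a config
  knob, not a biological claim). Substitutions are uniform over the three
  alternative bases (Jukes–Cantor-like). Optional host-lineage indels
  (geometric lengths, mean 2) perturb the graft→host site correspondence,
  which stays strictly monotonic over its domain.
- **Read mixture**: fragment origin is Bernoulli(host_fraction); starts are
  uniform; insert lengths normal (default 200 ± 20 nt, truncated at the read
  length); 101 nt mates in FR orientation with the fragment strand drawn at
  random; per-base errors at `error_rate` substitute a uniform different
  base. Base qualities are constant (Q37): trimming behaviour is exercised by
  dedicated quality fixtures, not by the mixture simulator. Fragment ids are
  sequential (`FRAG000001`) and carry no origin information; truth travels as
  separate labels.
- **RNA-seq-like sampling**: graft fragments are drawn from exonic intervals
  of a generated BED12 gene model with Dirichlet-distributed per-gene
  weights, each fragment inside a single exon (no splice junctions — enough
  to test counting and RPKM, not spliced alignment). Host fragments are drawn
  genome-wide, as stromal contamination would be.
- **Spike-in variants**: a subclonal SNV is carried by each covering
  graft-origin fragment with probability `vaf`, drawn once per fragment so
  mates agree; the generator can bias the transition:transversion mix to give
  the mutation-spectrum analysis a non-uniform truth.

What passing tests therefore show: the set algebra, gating, counting and
filtering layers are correct, and the pipeline recovers fragment origin
essentially perfectly when the two genomes are uniformly ~12% diverged and
errors are rare. What they do not show: performance on real genomes, where
divergence is non-uniform (conserved exons vs unalignable deserts), indels
and repeats are pervasive, and error profiles are position- and
context-dependent. In particular the near-zero *common* fraction at D = 0.12
is a property of uniform divergence; real exome libraries show a few percent
of fragments mapping to both genomes.

## Quantification

Fragments are assigned to the single gene whose exons overlap the fragment's
aligned mate intervals by the most bases; zero overlap is unassigned, a tie
across genes is discarded as ambiguous (both tallied — assigned + unassigned
+ ambiguous equals input fragments). Strand is ignored (non-directional
libraries). Counting is fragment-level by default (`count_unit="read"`
available). The RPKM denominator is the fragments assigned within the
category being quantified, since quantification happens after species
separation; any denominator can be passed explicitly. Graft and host
expression use the identical code path. `spearman_log2` applies
log2(x + pseudocount) (default pseudocount 1.0) before ranking with average
ties; the monotone transform cannot change Spearman's ρ and is kept because
exported matrices are log2-scaled. Constant vectors yield NaN explicitly.

## Variant post-processing

Variant calling is consumed, not reimplemented: the layer starts from VCF
(multi-allelic records split on ingest, per-allele depths carried).

- **Pileup**: bases with quality ≥ 20 from primary, properly-paired,
  non-duplicate, MAPQ-available records; each exclusion is tallied.
  Extraction assumes ungapped placements; indel-containing alignments are
  skipped.
- **Hard filters**: LowDepth (depth < 5), LowQual (QUAL < 50), StrandBias
  (FS ≥ 60), SnpCluster. FS is −10·log10 of the two-sided Fisher exact p on
  the ref/alt × forward/reverse table (scipy's exact test; the test suite
  cross-checks against a hand-written hypergeometric enumeration), capped at
  10,000 so p = 0 stays finite. Filters are recomputed from scratch each
  application, hence idempotent.
- **SNP clusters**: "cluster size = 10" is ambiguous between a count and a
  window; here it is read as a 10 nt window with a 3-SNV count (the
  conventional pairing), both exposed as flags. Indels join depth/quality
  filtering but are excluded from cluster and spectrum logic.
- **Germline subtraction** and **known/novel annotation** are exact key
  matches on (chrom, pos, ref, alt); the known:novel ratio is reported.
- **Mutation spectrum**: the 12 raw substitutions collapse to 6
  strand-symmetric classes written purine-ref first (e.g. "G>A/C>T");
  complementing every record is an involution that leaves counts unchanged.
- **Rescue classification** of a variant absent from the counterpart
  sample's calls, by direct pileup there: depth < 10 →
  NOT_DETECTED_LOW_DEPTH; else allele fraction ≥ 0.2 → CALLED; else ≥ 1 alt
  read → DETECTED_BELOW_THRESHOLD (subclonal presence); else
  NOT_DETECTED_NO_ALT. The 0.2 / 10 thresholds are the post-hoc criteria the
  workflow defines, not caller parameters.
- **Host-contamination window check**: reads whose alignments overlap
  ±1,000 bp of a suspect locus are realigned against the host genome. Its
  default mismatch budget is 3 (~3% of a 101 nt read), the stringency
  short-read DNA aligners effectively apply — under uniform 12% divergence a
  genuine graft read then has ~1.2 × 10⁻³ probability of a spurious host
  placement (measured; binom cdf(3; 101, 0.12) ≈ 1.3 × 10⁻³), so windows of
  tens of reads report zero, while genuine host reads (error ~0.1%) always
  align. At the aligner's same-species budget of 5 the spurious rate is
  ~1.3%, which would defeat the check on the uniformly-diverged toy genomes.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run entirely on generated data:
200 kb genome pairs with 50,000-pair mixtures at host fractions 0.05 / 0.20 /
0.40 for recovery; 10,000-read trimming oracles; every 2×2 table with grand
total ≤ 30 for the Fisher cross-check; 1,000-record randomized call sets for
filtering; 20 replicate ~100× fixtures for rescue rates. These sizes give
binomial tolerances of a fraction of a percent while keeping a full run
around a minute. All generators are pure functions of (inputs, seed);
sub-seeds are derived arithmetically from the one CLI seed. Ties everywhere
break deterministically (lowest coordinate, lexicographic id), and
percentage reports round to one decimal.

## Known limitations

- No gapped or spliced alignment in the micro-aligner; real RNA-seq must be
  aligned externally (any SAM/BAM is accepted).
- A "neither genome but assignable" scavenging step beyond the unmapped set,
  and k-mer-based classification, are out of scope by design — the method is
  deliberately the alignment-and-read-id strategy.
- Pileup ignores indel-containing reads; allele counting is SNV-oriented.
- The simulator's uniform divergence overstates how cleanly real graft and
  host reads separate; treat the recovery numbers as validation of the
  machinery, not as expected real-data performance.
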