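# Methods

This note documents the models, rules and numerical choices behind
`retroscribe`, and what the synthetic-data generators do and do not
emulate.

## Coordinate model

All internal coordinates are 0-based half-open intervals; GTF/GFF3 and
RepeatMasker `.out` files (1-based inclusive) are converted only at the
I/O boundary, and BED is read natively. A transcript is a stranded chain
of sorted, non-abutting exons with an optional CDS span (start codon
through stop codon, both bounds exonic). Exons that overlap or abut in an
input file are merged on read; a zero-length gap is not a splice
junction, so abutting exons are rejected at model construction.

Repeat taxonomy follows the RepeatMasker class/family strings: LTR
(subgroups HERV for ERV families and MaLR for ERVL-MaLR and the
MST/MLT/THE names), LINE, SINE, SVA (Retroposon/SVA), with everything
else — simple repeats, low-complexity, satellites, DNA transposons, RNA
genes — mapped to `Other` and excluded from ERE totals. When only a locus
name is available (BED input), the class is inferred from a shipped
name-prefix table. The mapping is deterministic and overridable.

## Repeat-overlap taxonomy

Per transcript, repeats with less than `min_overlap_bp` (10 bp) of exonic
overlap are ignored. The remaining repeats decide one of four mutually
exclusive categories, with precedence stand-alone > terminal-exon >
embedded (the most specific structural claim wins):

- **stand-alone** — the union of repeats of a single ERE class covers at
  least `standalone_cov_min` (0.80) of the transcript's exonic length;
- **terminal-exon** — a repeat covers at least `terminal_exon_cov_min`
  (0.50) of the 5′-most or 3′-most exon and reaches within
  `terminus_tolerance_bp` (10 bp) of the corresponding transcript
  terminus;
- **embedded** — any other retained exonic overlap;
- **none** — no retained overlap.

The class label is the single contributing class, or `multiple` when two
or more classes each contribute at least `min_overlap_bp` — class-level
diversity, not locus count, because the categories are reported per
class. The numeric cutoffs are design choices made to keep the categories
stable on RepeatMasker-style fragmented annotations (a single element is
often split into several rows); all are configurable. Overlap is computed
strand-agnostically and strand concordance is reported as a flag, since
repeat-derived sequence is informative on either strand. Monotonicity
(raising `standalone_cov_min` never increases the stand-alone count) and
invariance of coverage under splitting a repeat into adjacent fragments
are enforced by property tests, and the whole classifier is checked for
exact agreement with a per-base brute-force oracle on 1,000 random
configurations.

## Transcript tiers and assembly intersection

"Fully annotated" means exact intron-chain equality with a same-strand
reference transcript, ends free (the complete-match semantics of
cuffcompare); monoexonic queries instead need reciprocal overlap
≥ `monoexonic_reciprocal_min` (0.80) with a monoexonic reference.
"Partial" merges all intermediate relations: at least one shared splice
junction or ≥ 1 bp of same-strand exonic overlap. Everything else —
including antisense-only overlap, read conservatively — is "novel". The
three tiers partition any query set.

Two assemblies intersect on transcripts "fully supported by both": equal
intron chains with both termini agreeing within `end_match_tolerance_bp`
(100 bp — full-length isoform reads and short-read contigs disagree on
ends at about this scale; no published tolerance exists), monoexonic
pairs requiring reciprocal overlap ≥ 0.90. Each query transcript keeps
only its best partner (smallest summed end distance, ties by identifier),
which makes the pairing symmetric up to orientation when matches are
unique.

## Contig filter chain

The de novo assembly filter is a pure predicate per contig:

1. **polyA trim** — remove the longest suffix that begins with A and has
   ≥ 90 % A content, when at least 10 nt long; mirrored for leading T
   (reverse-complemented fragments). Requiring the trimmed block to begin
   on the run base prevents eating genuine 3′ sequence and makes the trim
   provably idempotent. A contig trimmed to nothing is flagged
   degenerate.
2. **complexity** — global normalized k-mer Shannon entropy with k = 5:
   H / log(min(4^k, L−k+1)), in [0, 1]; keep requires ≥ 0.7. A windowed
   variant exists behind a config switch; the global form is simpler and
   deterministic.
3. **expression** — keep requires ≥ 0.05 TPM in at least one sample
   (boundary inclusive).
4. **alignment** — keep requires identity > 0.85 AND coverage > 0.85
   (the stricter, conjunctive-keep reading of the removal rule, matching
   a standard GMAP post-filter); a lenient mode removing only contigs
   failing both criteria is available.

Rejection reasons enumerate every failed rule, so the report is a full
audit. Tightening any threshold can only shrink the kept set.

## Counting, normalization and selection

Counting follows the unique-reads convention: multimapping placements
contribute nowhere; within the gene layer and within the repeat layer a
read incrementing exactly one feature counts, a read overlapping two or
more features of the same layer is dropped as ambiguous, and the two
layers are counted independently (a read in an exonized Alu counts once
in each). The ERE read fraction of a sample is the share of unique
placements overlapping any repeat by ≥ 1 bp (configurable minimum).

Depth normalization uses median-of-ratios size factors: per-feature
geometric means over samples form the pseudo-reference (features with any
zero excluded) and each sample's factor is the median ratio to it. Note
that scaling one sample by c rescales its factor by c only relative to
the other samples — the geometric-mean reference absorbs c^(1/m) — which
is the form verified against a brute-force oracle. TPM is the standard
length-normalized measure summing to 10^6 per sample.

Selection gates operate on log2(normalized + 1):

- **responsive** features: paired two-tailed Student t-test between pre-
  and post-treatment samples of the same patient; selected at
  |fold change| ≥ 2 and p ≤ 0.006, with the fold change computed from
  linear-scale group means with a pseudocount of 1 (the source analysis
  ran in a closed GUI package; the paired t on logs is the standard
  equivalent, and a Welch variant sits behind a flag).
- **multigroup** features: one-way ANOVA across sample groups with
  Benjamini–Hochberg adjustment, selected at q ≤ 0.05; zero-variance
  features are excluded and reported.

Calibration is tested, not assumed: under pure-null normal noise the
p ≤ 0.006 selection rate matches 0.006 within three Monte-Carlo standard
errors, and BH at q ≤ 0.05 keeps the empirical FDR within 0.05 + 3 SE on
a 10 %-non-null simulation.

Repeat families aggregate by summation under a name → group map
(prefix-based by default, e.g. LTR12C and LTR12E into LTR12), with
unmapped loci preserved in an `ungrouped` row so totals are conserved.
Signature gene sets (e.g. interferon-stimulated genes, IFN-inducible LTR
elements) are scored by the mean log2(normalized + 1) over member genes
present, missing members being reported. qRT-PCR CT tables are quantified
by ΔCT relative to a reference gene (HPRT by default),
2^−(CT_target − CT_ref), with a cumulative per-sample score (the sum over
targets) compared between outcome groups by a two-tailed t-test.

## Intron retention and consequences

Intron *i* of an index isoform counts as retained when the variant's
exonic footprint covers at least `retention_cov_min` (0.95) of it — not
exact equality, to tolerate assembly end wobble. Ordinals are numbered
5′→3′ in transcript orientation (reverse of genomic order on the minus
strand). A variant terminating inside an intron (intronic
polyadenylation) is scored on the retained portion upstream of its
terminus only.

Consequences follow the canonical 50-nt rule. The variant is translated
from the index start codon through its own exon chain; the first in-frame
stop upstream of the index stop is a premature termination codon (PTC).
A PTC more than `nmd_rule_nt` (50) nt upstream of the variant's last
exon–exon junction predicts nonsense-mediated decay; a PTC in the last
exon (including a retained last intron, which removes the downstream
junction) or within 50 nt of the last junction predicts a C-terminally
truncated protein; no new stop before the index stop (e.g. a retained
3′UTR intron) is `none`; a non-coding index is `noncoding`. Setting the
rule distance to infinity provably never yields NMD.

## Synthetic data: what it emulates, what it does not

The generators are pure functions of (parameters, seed) and regenerate
byte-identically.

- **Annotations** plant each overlap category with margin: stand-alone
  transcripts are monoexonic and fully covered by one element;
  terminal-exon plants cover the last exon through the terminus but stay
  below 80 % of the transcript; embedded plants sit ≥ 60 bp inside an
  exon. Transcripts are spaced (500 bp default) so plants never interact.
- **Retention pairs** are built on a GGC-lattice locus (stop- and
  start-free in every frame) with exon/intron lengths that are multiples
  of 3, so exonizing an intron preserves frame; the start codon, index
  stop and — per requested consequence — a single in-frame PTC inside a
  retained intron are written at controlled positions. This makes the
  planted ordinal set and consequence exact by construction on either
  strand.
- **Counts** are negative binomial (var = μ + αμ², α = 0.05 by default,
  Poisson in the α → 0 limit) over log-normal per-feature baselines,
  with multiplicative per-patient factors shared by a patient's samples
  (honouring the paired pre/post design), log-normal per-sample depth
  factors, and planted 2^log2FC effects on a chosen contrast. Defaults
  (8–10 patients per paired contrast, 5 samples per group, log2FC = 2)
  mirror the scale of the study design.
- **Read placements** draw each read's repeat status as a Bernoulli with
  the planted ERE fraction (0.16 for healthy-like samples, matching the
  observed scale) and place off-repeat reads strictly inside repeat-free
  gaps, so measurement equals the recorded draws exactly.

What the generators do **not** emulate: sequencing error, coverage bias,
fragmented or nested real RepeatMasker annotations, overlapping gene
models, partial intron retention, isoform-level quantification
uncertainty, or library-specific strand protocols. Passing tests
therefore demonstrate correctness of the rules and calibration of the
statistics under the stated generative assumptions — not robustness to
every artefact of real bone-marrow RNA-seq.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: 1,000
random configurations for the classifier oracle, 800 planted transcripts,
10,000 features for calibration, 10,000 reads for the ERE fraction —
sizes at which the binomial/Monte-Carlo tolerances quoted above are
meaningful. The full pipeline writes a manifest (config snapshot, seed,
per-stage row counts and SHA-256 digests); reruns from the same seed are
byte-identical, which the suite asserts file by file.

## Known limitations

- Tier assignment reports the best "full" match only; it does not emit
  the full cuffcompare class-code spectrum.
- Chimera breakpoints are not resolved to splice sites; the taxonomy is
  interval-based.
- The gene layer counts by exonic overlap of whole genes (union of
  isoform exons per gene id), without isoform-level assignment.
- `predict_consequence` assumes the index start codon is exonic in the
  variant; variants losing the start are rejected rather than rescanned
  for downstream initiation.
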