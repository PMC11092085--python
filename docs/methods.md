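# Methods

## Problem and approach

FSHD1 is caused by contraction of the D4Z4 macrosatellite at 4q35 to 1–10
repeat units (RUs) on a permissive 4qA haplotype, accompanied by
hypomethylation of the contracted allele. Genotyping is hard for short-read
methods because (i) a 10q26 paralog shares ~98% identity with the 4q35
array, (ii) the pathogenic signal is the *length* of a 3.3-kb tandem array,
and (iii) the permissive/non-permissive distinction (4qA/4qB) lives in the
pLAM sequence just distal to the array. `nanofshd` implements a read-centric
long-read workflow: instead of aligning reads to a reference genome, a small
library of feature sequences — the proximal single-copy anchor *D4F104S1*,
the D4Z4 unit, and the two pLAM haplotype variants, each in a 4q and a 10q
version — is locally aligned to every read.

Per read: (1) the best alignment bitscore per feature is summed separately
for the 4q and the 10q variant sets, and the read is assigned to the locus
that wins by ≥ `margin_bits` (default 10 bits; pLAM contributes the better
of its two haplotype variants, because both cover the same read span);
(2) the haplotype is the pLAM variant with the higher bitscore; (3) D4Z4
hits covering ≥ 60% of the unit each count as one RU. Reads spanning
*D4F104S1* → units → pLAM ("complete") carry exact RU counts; reads with
pLAM but no anchor ("haplotype") or with no pLAM ("incomplete") carry lower
bounds. Lower-bound reads with ≥ 10 observed units are flagged as
non-pathogenetic markers — the ≥ is implemented literally even though an
observed 10 could in principle come from a pathogenetic 10-RU allele, and
reports therefore flag rather than act on the boundary case.

## Alignment engines

The hit contract is affine-gap local alignment (match +1, mismatch −2, gap
open −2, gap extend −1; a length-g gap costs `open + g·ext`). Scores are
normalised to bits with the Karlin–Altschul form `(λS − ln K)/ln 2` using
the classic ungapped constants λ = 1.28, K = 0.46; bitscores are only
compared with each other, so absolute calibration is immaterial.

Two engines share this contract:

* **dp** — exact Smith–Waterman, row-vectorised in numpy (gap-extension
  maxima via a prefix-max identity), with traceback for identity/coverage
  and mask-and-realign for multiple non-overlapping hits. Verified in tests
  against an independent O(nm) triple-loop oracle.
* **fast** — strided 15-mer seeds locate candidate windows (tandem copies
  separate cleanly because adjacent copies sit ~unit-length apart in
  diagonal space), each window is scored by banded edit distance (edlib),
  and the raw score is derived as `len − 3·d`. This underestimates the
  optimal affine score for gap-rich alignments by a few points, which is
  irrelevant against classification margins of hundreds of bits; on
  substitution-only instances it coincides with the exact score, and tests
  verify agreement with the dp engine. The cohort-scale pipeline uses this
  engine (~7 ms per read).

Strand normalisation compares seed counts of the read and its reverse
complement and flips once before scanning; for true locus reads the vote is
decided by hundreds of seeds.

## Allele calling

Complete reads are grouped per haplotype by observed RU count; counts within
`merge_tolerance` (default 1, absorbing rare edge-unit dropouts) merge to
the modal value, ties resolving toward the smaller count (conservative
toward calling a contraction). Clusters with ≥ `min_support` (default 2)
complete reads become exact alleles. Lower-bound reads attach to the
compatible allele with the smallest exact count that contains them;
leftovers with a haplotype found a "≥ max observed" allele. An allele is
pathogenetic iff 4qA, exact, and ≤ 10 RUs; lower bounds are never
pathogenetic. A sample with more than two distinct 4q alleles is mosaic.

Two same-haplotype alleles of equal (or unresolvably long) length collapse
into one read cluster. They are recovered by depth accounting: every allele
contributes exactly one distal (pLAM) end, so the number of pLAM-covering
reads uniquely compatible with a cluster is ~Poisson around a per-allele
constant. That constant is self-calibrated as the cohort-wide median of the
per-cluster statistic (single-allele clusters dominate any realistic
cohort); a cluster exceeding it by more than 3 standard deviations
(one-sided z test) is emitted with the corresponding multiplicity, the extra
calls reported as lower bounds. Reads compatible with several clusters of
the same haplotype (short distal reads that could come from a longer allele)
are excluded from the statistic, so a small exact allele is never inflated
by its longer sibling. No diploidy prior is imposed anywhere — one, two, or
three-plus alleles per sample are all representable, which is what keeps
mosaicism detectable.

## Methylation

CpG calls are consumed as TSV (read id, position, probability methylated),
the export format of modified-base callers. Positions are expressed
relative to the start of the most distal D4Z4 unit, which makes the region
definitions shared across alleles of any RU count: distal unit `[0, 3300)`,
*DUX4* upstream `[0, 1320)`, gene body `[1320, 3800)` (through the end of
pLAM). The upstream/gene-body breakpoint at 40% of the distal unit is a
design choice — the gene structure places *DUX4* exon 1 inside the distal
unit with exons extending into pLAM, and the exact breakpoint only decides
which CpGs land in which region.

A region level is the ratio of methylated calls (probability ≥ 0.5,
inclusive) to total calls — the same ratio definition as clone-based
bisulfite summaries, so long-read and clone-based levels are directly
comparable. Allele-specific levels use only reads compatible
with exactly one allele (complete reads match their exact cluster;
lower-bound reads must be containable by exactly one allele); ambiguous
reads are dropped, trading depth for purity. The pooled "overall" level
over all assigned reads equals the call-count-weighted mean of the
per-allele levels exactly, which is what reproduces the masking phenomenon:
a hypermethylated non-pathogenetic 4qA allele can hold the pooled level
above any diagnostic cut-off while the contracted allele sits far below it.

## Diagnostics

Pearson correlation (two-sided t-based p), Welch's t-test, and ROC analysis
with AUC by Mann–Whitney pair counting (ties 0.5), which tests verify equals
the trapezoidal area under the constructed curve. The positive class is
"pathogenetic", predicted when the methylation value is *below* the cut-off.
The Youden-optimal cut-off maximises sensitivity + specificity − 1 and is
reported as the midpoint of the two observed values bracketing the optimal
interval (ties prefer sensitivity). On the packaged per-allele upstream
dataset (16 pathogenetic values: 11 sample-level + 5 printed read-level; 15
non-pathogenetic: 10 control sample-level + 5 printed read-level) this
yields AUC 0.996 and cut-off 46.85% with sensitivity 0.938 and specificity
1.000 — the packaged fixture provenance records the same cut-off with
sensitivity 1 and specificity 0.938, an apparent transposition; the package
reports the recomputed pairing. Clone bisulfite tables are summarised as per-site
methylated-clone ratios and their unweighted mean over the 10 sites.

## Synthetic cohort generator

The generator emulates locus-restricted ONT WGS of the 4q35/10q26 regions.

| Parameter | Default | Rationale |
|---|---|---|
| per-allele depth | 30× at diploid abundance | cohort mean sequencing depth ~30×; an allele at cell fraction *a* receives `30·a/0.5` |
| read length | log-normal, median 8.14 kb, σ 1.2 | median matches the cohort; σ chosen so the tail reproduces the observed read-category mix (exact counts attainable to ~20 RUs, ~100-kb reads covering > 30 units occur at WGS depth); implies N50 ≈ 34 kb |
| errors | 3% sub, 1% ins, 1% del | R9-era ONT error profile (~5% total) |
| upstream context | 60 kb | reads enter the locus from surrounding genome; starts are sampled over the allele plus this window and clipped at the allele bounds |
| methylation rates | 0.25 pathogenetic 4qA; 0.70 otherwise | motivated by the cohort's observed per-allele level ranges |
| mosaic pathogenetic abundance | 0.15 | "low-level" mosaicism; yields ~4–6 expected complete reads for a 2-RU allele, matching the scale of the reported mosaic evidence |
| 10q background | two 10qA alleles, 11–40 RUs per sample | all cohort 10q haplotypes were 10qA; exercises paralog disambiguation |

Feature sequences are synthetic: random 4q features with the 10q paralogs
diverged at ~2% (binomial), pLAM-B at ~10% from pLAM-A, and CpG
dinucleotides planted at ~0.02/bp at positions shared between paralogs.
Per-molecule methylation states are independent Bernoulli draws per covered
CpG; emitted probabilities are pushed to ~0.9/~0.1 with Gaussian jitter,
always on the correct side of 0.5.

What the generator does **not** emulate: basecalling from raw signal,
homopolymer-biased or context-dependent errors, chimeric reads, mappability
of the genomic background (decoy specificity is tested with separately
generated random reads), real 4q/10q sequence (synthetic stand-ins preserve
the divergence structure, not the sequence), or borderline methylation
probabilities near 0.5. Passing tests therefore demonstrate the logic of
classification, counting, calling, and aggregation under realistic length,
error, and divergence regimes — not performance on any particular real
dataset.

## Numerical and procedural choices

* QC keeps reads with mean quality ≥ 9 **and** length ≥ 500 bp (the
  filter removes `< 9` / `< 500`, so both boundaries survive).
* Classification margin 10 bits; below it a read is ambiguous and excluded.
* Unit hits need ≥ 60% feature coverage to count; window-boundary overlaps
  up to 60 bp are trimmed toward the lower-scoring hit, larger overlaps
  drop it.
* Methylation probability threshold 0.5, inclusive.
* Degenerate inputs: empty reads scan to empty hit tables; zero informative
  reads yield an empty allele list; a region with no calls reports a
  missing level rather than 0.
* All randomness flows from a single integer seed per run; simulation,
  pipeline, and reports are bit-reproducible for a fixed seed.

## Problem sizes

The full-cohort recovery analysis simulates 29 samples (59 truth 4q alleles
plus 58 background 10q alleles, ~21,000 reads, ~280 Mb) and runs end to end
in about 3 minutes on one CPU. Unit and property tests run on scaled-down
feature sets (400-bp units) or constructed hit tables and complete in
seconds.

## Known limitations

* Mosaic *ratios* are not estimated, only the presence of extra alleles.
* Two same-haplotype alleles of equal length are reported via depth-based
  multiplicity: the second call is a lower bound with no independent length
  estimate, and detection is statistical (a ~2× depth signal), not certain.
* Lower-bound alleles inherit the largest observed unit count, which
  understates long arrays exactly as the read-length distribution dictates.
* The 10q26 array is classified and countable but not reported in the
  default genotype tables, which focus on the clinically relevant 4q35
  locus.
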