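# Methods

This note documents the models, decision rules, numerical choices and
limitations behind `isodiv`. It states definitions and defaults; every
empirical number it mentions is one the test suite or
`scripts/acceptance.py` computes.

## Coordinate model

All internal coordinates are 0-based half-open `[start, end)`; GTF's
1-based inclusive convention is converted only at I/O boundaries. TSS
and TES are derived strand-aware (TES is the genomic end on `+`, the
genomic start on `-`), never stored, which removes an entire class of
off-by-one and strand bugs from the UTRR midpoint arithmetic.
Expression matrices carry an explicit unit tag (`counts`, `cpm`,
`fpkm`); each operation checks the tag it requires. FPKM uses the
annotated exonic (spliced) length of each transcript.

## Structural classification

The cascade, evaluated against same-strand reference genes overlapping
the transcript span:

1. exonic overlap with ≥ 2 distinct genes → **fusion**;
2. intron chain equal to a reference transcript's → **FSM**;
3. chain a proper contiguous sub-chain of a reference chain → **ISM**;
4. multi-exonic, all splice sites known within the assigned gene →
   **NIC**;
5. multi-exonic with ≥ 1 novel site → **NNC**;
6. mono-exonic inside a same-strand gene → **genic** (exception: a
   mono-exon transcript reciprocally overlapping a mono-exon reference
   transcript ≥ 80% is FSM);
7. overlap only on the opposite strand → **antisense**;
8. no overlap → **intergenic**.

The assigned gene is the one contributing the most matched junctions,
ties broken by exonic overlap. Junction comparison is exact by default
(`junction_tolerance = 0`); a ± nt fuzz is available but off, because
no principled window exists without alignment-error calibration.
Novel (antisense/intergenic) transcripts are merged into novel gene
loci by single-linkage same-strand overlap.

Two tallies are reported deliberately side by side: *known
transcripts* counts FSM only (an ISM certifies its junctions but not
an annotated transcript's termini), while the *annotated category*
tally counts FSM+ISM. They answer different questions and collapsing
them silently would misstate one of the two.

ORF prediction is the longest ATG→stop reading frame on the spliced
sense strand (default coding call at ≥ 100 aa); it exists to supply
stop-codon positions for 3′-UTR lengths, not to replace a dedicated
coding-potential classifier.

## Alternative-splicing events

Events are detected pairwise within a gene. The genomic axis is
partitioned at *sync points* — coordinates that are exon boundaries of
the same polarity (exon start vs exon end) in both transcripts,
transcript termini included — and every region between consecutive
sync points where the exonic structures differ is typed:

* **ES**: one form intronic across the region, the other contributing
  complete exons strictly inside (several consecutively skipped exons
  are a single event);
* **IR**: an intron of one form strictly contained in an exon of the
  other, detected by direct containment so a mono-exonic transcript
  can retain (mono-exonic transcripts participate in no other type);
* **A5SS/A3SS**: single fragments sharing one anchor and differing at
  the other boundary; the label follows the biological 5′/3′ side, so
  flipping only the strand label swaps A5SS↔A3SS while a true mirror
  (reflect coordinates and flip strand) preserves labels;
* **MEE**: exactly one complete, non-overlapping exon per form between
  shared flanks;
* **complex**: anything else — reported, but excluded from the
  five-way proportions.

Differences outside the outermost sync points (terminus jitter,
5′-degradation) produce no events. Events are deduplicated gene-wide
on `(type, anchors, region)`, so counts do not inflate quadratically
with transcript number. The implementation is checked against an
independent oracle that recomputes boundaries, sync points and
templates from per-base exonic sets on randomized toy genes.

## Major transcripts

The MT of a gene in a condition is the argmax of mean FPKM across
replicates. Margin modes: `absolute` (default) requires
`top − second > margin` with `margin = 10` in FPKM units, the literal
reading of a "greater by 10" dominance rule; `fold` requires
`top / second > margin` (runner-up of zero passes). Single-isoform
genes pass trivially. A gene is AMT when both conditions have a
confident MT and the identities differ; genes failing the margin in
either condition are reported as *indeterminate*, not silently folded
into either group (`--require-margin-both` relaxes this to compare
top-ranked isoforms regardless of margin). Gene-level expression
change `(E2 − E1)/E1` is binned on its absolute value into
`[0,0.5), [0.5,1), [1,2), [2,∞)`; distributions for AMT vs MT-constant
genes are compared with a chi-square homogeneity test.

## Differential expression

A deliberately small, self-contained two-group NB model:
median-of-ratios size factors; per-gene method-of-moments dispersion
pooled within groups, floored at the catalog-wide median (the floor is
what keeps genes whose moment estimate collapses to zero from yielding
overconfident Wald statistics — the null simulations in the test suite
hold the empirical type-I error at nominal 0.05 within [0.03, 0.08]
at n = 3+3); Wald z on the log₂ fold change with a delta-method
standard error under `Var = μ + αμ²`. Calling rule: |log₂FC| ≥ 1 and
raw p < 0.05. Benjamini–Hochberg adjustment is available behind a
flag but off by default because the stated calling rule uses raw
p-values. Filtering precedes testing: CPM ≥ 1 in at least 3 libraries
of one condition.

## Alternative polyadenylation

Transcript 3′ ends are clustered per gene by single linkage with a
24-nt window (configurable; recorded in output headers) and clusters
below `min_support = 2` summed long reads are dropped — a single
clustering with dual evidence thresholds (end evidence + read
support) standing in for a two-caller intersection. The
representative site is the support-weighted modal end, ties resolved
downstream. APA gene: ≥ 2 surviving clusters.

UTRR = distance between the first and last PAS in transcription
order; isoforms ending strictly downstream of the midpoint are M,
strictly upstream m, and ends exactly on the midpoint are excluded
from both sums (only strict sides are defined). Gene status: M if
M/m > 1, P if < 1 (a zero m with positive M is M). mPAS usage defaults
to per-condition long-read support when a per-stage support table is
supplied (matching stage-pooled long-read libraries), otherwise to
isoform FPKM; ties go to the downstream site. Hexamer scanning counts
all overlapping 6-mers in the 50 nt upstream of each PAS on the sense
strand; AATAAA's rank is reported rather than a motif model.

## Synthetic data

The generator emulates: non-overlapping gene loci on two chromosomes
and both strands (6–10 exons of 80–300 bp, introns 100–400 bp); per
gene up to three additional isoforms, each derived from the full chain
by one planted AS event drawn from a 40/30/15/10/5 ES/IR/A3SS/A5SS/MEE
mix, placed at mutually non-adjacent exon slots so pairwise
decomposition reproduces exactly the planted events; an observed
catalog with category shares defaulting to the catalog-style
proportions (14.15% FSM, 25.39% ISM, 24.39% NIC, 32.24% NNC, 0.83%
fusion, 1% each genic/antisense/intergenic); 1–4 PASs per gene spaced
100–300 nt with AATAAA planted 10–30 nt upstream at rate 0.8; FSM
termini jittered ±30 nt at the 5′ end and ±10 nt at the 3′ end
(below the cluster window, so jitter cannot create a PAS); and
three-replicate two-condition NB counts with gene means 50–500 and
dispersion 0.1.

Planted biases are specified in FPKM space (dominant PAS 0.6 of the
gene, a favored isoform taking 0.8 of its PAS's share, distal PAS
preferred; AMT genes switch the favored isoform, shift genes the
dominant PAS, DE genes scale the gene mean by 2^±2) and converted to
count weights via transcript length, so length differences between
3′-isoforms cannot erode the planted margins. Crucially, every truth
label is then *derived* from the expected expression with the
pipeline's own decision rules — the generator plants tendencies and
the truth records what they actually imply — which makes the truth
attainable exactly in the zero-dispersion limit (where counts equal
rounded means). Internal PASs are kept ≥ 3× the end jitter away from
the UTRR midpoint, because a site within jitter range of the midpoint
has no well-defined distal/proximal side.

Long-read support is split between conditions proportionally to the
planted weights on a scale of 50 reads per gene; support for
transcripts outside annotated genes is drawn from a small uniform
range. One root seed drives per-stage spawned substreams, so each
stage is independently reproducible and the whole bundle is
byte-deterministic.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: alignment and sequencing error (novel
splice sites arise only by construction, never by noise), internal
priming artifacts, 3′-bias or coverage-dependent truncation (ISM
truncation is uniform, 5′-only), inter-gene correlation, library
composition effects beyond depth, and overdispersion heterogeneity
across genes.

## Problem sizes

The recovery experiments run at the sizes the analyses are specified
at: 400-transcript catalogs for classification, 250 genes (~400
planted events) for AS typing, 500 genes at 20% AMT for switching,
200 APA genes at 30% shift for 3′-end analysis, and 2000-gene null
simulations over three seeds for test calibration. Each completes in
seconds; the whole acceptance script runs in well under a minute.

## Known limitations

* Fusion transcripts are assigned to a single gene (most matched
  junctions), so gene-level counts of fusion-containing loci blend
  two genes' signal.
* The NB Wald test has no dispersion shrinkage across genes beyond the
  median floor; at n = 3+3 its power profile differs from moderated
  estimators.
* PAS clustering is single-linkage: a chain of ends each within the
  window can bridge sites farther apart than the window; the planted
  spacing constraint in the generator avoids this regime rather than
  resolving it.
* The five-way AS typing covers regions between shared same-polarity
  boundaries; first/last-exon alternatives (alternative TSS/TES) are
  deliberately out of scope.
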