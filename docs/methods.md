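# Methods

This note records the models, conventions, and numerical choices behind
`nanoterm`, and what the simulator-based tests do and do not demonstrate.

## Coordinates and strand conventions

All internal coordinates are 0-based half-open; GFF3 input (1-based,
closed) is converted on read, BED passes through. A read's biological 3′
end on the `+` strand is the exclusive alignment end; on `-` it is the
inclusive alignment start — the same convention under which poly(A) sites
are recorded, so end positions and pA positions compare directly. Signed
distances (`d5`, `d3`) are strand-aware with downstream positive. Every
positional operation is covered by a strand-mirror test: reflecting the
genome through an arbitrary pivot and flipping all strands must leave
classes, termination windows, and tRNA distances unchanged.

## Read ingestion and adapter detection

Alignments with flags in mask 2308 (unmapped, secondary, supplementary)
are removed; the mapping-quality floor defaults to 0 because long nascent
reads are filtered by flags, not MAPQ. Soft-clip sequences plus 20 nt of
adjacent aligned sequence are searched for the template-switching oligo
(`AAGCAGTGGTATCAACGCAGAGTACATGGG`, terminal GGG included, no untemplated-C
trimming) and the 3′ adapter (`ATTGATGGTGCCTACAG`), in both orientations,
with edlib semi-global alignment. Edit budgets default to 6 (TSO) and 4
(3′ adapter), about 20–25% of adapter length — common long-read practice;
the upstream protocol publishes no tolerance, so both are config-exposed.
Clips shorter than the adapter are searched for terminal adapter fragments
down to a 12-nt overlap with a proportionally scaled budget. On
edit-distance ties the hit nearest the alignment boundary wins; a
substitution at the adapter base abutting a poly(A) tail therefore shifts
the reported adapter offset by design (the position is genuinely
ambiguous). Only reads with both adapters on a consistent strand are kept:
the TSO fixes the biological 5′ end, the adapter the 3′ end, and the pair
fixes the strand independently of the alignment flag (both cDNA strands of
a gene are sequenced).

## Poly(A) tail calling

The tail is called from the clip segment between the aligned 3′ end and
the 3′-adapter hit, reverse-complemented into biological orientation for
minus-strand alignments. A tail is the longest interval with A-purity
≥ 0.85 whose endpoints are A and which lies within 5 *non-A* bases of
either segment boundary; ties resolve toward the alignment end (the
templated cleavage position). Counting non-A bases (rather than raw
distance) in the anchor makes the call monotone — appending A's never
shrinks a tail — while still rejecting internal genomic A-rich stretches.
This is a deliberately deterministic, sequence-level replacement for
raw-signal tail estimation, which is out of scope; its accuracy claim
(±10% on ≥95% of 10–100-nt tails at 5% substitution error) is verified by
simulation, not on real squiggle data. Empty segments report length 0 and
purity 1.0 by convention.

## Poly(A) site clusters

Observed sites are the aligned 3′ ends of reads with tails > 15 nt,
assigned to the same-strand gene whose TES-extended span (default +500 nt)
covers the read. Single-linkage chaining merges consecutive sorted sites
≤ 24 nt apart (boundary inclusive); clusters with support < 3 are dropped.
"Support" counts reads by default — the PAC-methodology convention — with
a `positions` mode counting distinct end positions instead, since the
source text is ambiguous. The representative site is the max-count
position, ties broken to the most upstream (5′-most, strand-aware) site
for determinism. Genes with exactly one surviving PAC proceed; this
removes alternative-polyadenylation ambiguity at the cost of discarding
multi-PAC genes entirely.

## Intermediate classification

The decision ladder (thresholds all config-exposed, defaults shown):

1. tail > 15 nt → `POLYA`;
2. 3′-adapter gap ≥ 5 nt → `UNCLASSIFIED` (3′ end untrusted);
3. d5 < −50 and d3 > +50 → `READTHROUGH`;
4. d5 < −50 and −50 ≤ d3 ≤ +50 → `CLEAVED_5P`;
5. 0 ≤ d5 ≤ +500 → `CLEAVED_3P`, except when a same-strand neighbour's TSS
   lies within the 500-nt window and d5 > TSS − 100 (the neighbour's own
   nascent reads would contaminate the class);
6. otherwise `UNCLASSIFIED`.

Boundary readings: "more than 50" is strict, "within 50/within 500" are
inclusive, which makes rules 3 and 4 disjoint. `CLEAVED_3P` does not
require d5 = 0: 5′→3′ nibbling of the downstream fragment still counts.
`UNCLASSIFIED` is an explicit, counted category so read accounting is
conservative (classified + unclassified = double-adapter reads, asserted
at run time). Gene assignment prefers the same-strand candidate containing
the read's 5′ end, else maximal overlap; reads starting upstream of the
annotated TSS are accepted as gene-body reads provided d5 < −50.

## Termination windows

Contributing reads are `READTHROUGH` ∪ `CLEAVED_3P` with d3 > 50 (a flag
restricts to readthrough only, since the source definitions can be read
either way); each read contributes to exactly one gene. TW is the median
distance, even counts taking the central-pair mean (0.5-nt resolution);
TWE = pA shifted downstream by TW rounded half-up; genes need ≥ 15
contributing reads. The median, not the maximum, summarizes the window
because it is depth-robust: on heavy-tailed simulated distance
distributions the standard deviation of the median across 15-read depth
subsamples is about 4× smaller than that of the maximum (measured ratio
≈ 0.23). Meta-profiles of 5′/3′ end positions around pA or TWE anchors are
per-position counts normalized to unit sum, with no smoothing.

## Genotype comparison and chimeras

Per-gene TW comparison uses the two-sided Mann–Whitney U on the raw
distance lists: exact null distribution when both n ≤ 25 and the pooled
sample is tie-free, otherwise the normal approximation with tie and
continuity corrections. The exact cutoff at 25 (not the more common 8)
keeps the test's realized type-I error at its achievable nominal level for
the typical 15-read gene (0.0453 at n = 15/15, p < 0.05). Significance is
declared at raw α = 0.001 with no multiplicity correction, matching the
published convention; a Benjamini–Hochberg q-value column is emitted
alongside for users who want it.

Chimera detection scans tandem gene pairs for two signatures of failed
torpedo degradation: upstream `CLEAVED_3P` reads whose 3′ ends pass the
downstream TSS (with a stricter full-gene-span count as an extra column),
and poly(A) reads at the downstream pA whose 5′ ends lie between the
upstream pA and the downstream TSS (serial cleavage-and-polyadenylation).
Pairs report at ≥ 3 reads on either count — a decision, since the original
criterion is unpublished.

## tRNA-adjacent termination

Protein-coding genes whose nearest downstream gene (strand-aware from the
TES, overlapping genes skipped) is a tRNA within 200 nt are paired with
it. The distance of interest runs from the TWE to the tRNA's proximal
genomic edge — the tRNA start for tandem pairs, the tRNA 3′ end for
convergent pairs — positive when the TWE is upstream. A gap-matched
control cohort (genes with non-tRNA downstream neighbours, matched by
25-nt gap bins) supports efficiency contrasts on simulated data.

## The simulator

The simulator emits a random genome, disjoint gene cassettes (each
reserving 1.5 kb of downstream clearance so run-on reads never invade the
next gene body), pre-aligned coordinate-sorted SAM records, and per-read /
per-gene truth tables. Reads are TSO + transcript segment (+ tail for
`POLYA`) + 3′ adapter with soft clips exactly delimiting the non-genomic
parts, uniform substitution errors (default 5%, no indels — substitutions
are what stress the edit-distance search), and a random flag-strand flip
emulating sequencing of both cDNA strands. Read classes are drawn from
configurable proportions, default (0.60, 0.25, 0.14, 0.01) for (POLYA,
READTHROUGH, CLEAVED_5P, CLEAVED_3P) — polyadenylated transcripts
dominate nuclear libraries and free 3′ cleavage products are rare because
the torpedo exonuclease degrades them co-transcriptionally.

Key generative choices:

* **Readthrough law.** Distances past the pA are 50 nt + an excess drawn
  from an exponential (default), gamma, or constant law whose median is
  exact by construction (default total median 160 nt, the typical
  termination window). The constant law exists for fixtures that need
  deterministic TWEs, e.g. recovering the configured 60-nt (tandem) and
  10-nt (convergent) TWE-to-tRNA offsets as exact modal distances; under
  the exponential law a 30-read median has ~29-nt sampling error, so exact
  modal recovery is not a meaningful target there. An optional
  median-preserving lognormal spread of per-gene medians (log-sd ~0.8)
  reproduces the broad, long-tailed between-gene TW variation needed for
  replicate-consistency experiments.
* **Poly(A)-site heterogeneity.** Poly(A)-read 3′ ends use the gene's
  dominant cleavage site with probability 0.6 and otherwise scatter with
  Gaussian jitter (default sd 10 nt, clipped to ±50). The dominant-site
  mixture reflects how real plant poly(A) site clusters look — one major
  site plus minor scatter — and is what makes the max-count representative
  a consistent estimator of the true site; under an unstructured Gaussian
  at sd 10 the modal site recovers the truth within ±5 nt for only
  ~50–70% of genes at realistic depth, an estimator-level fact, not an
  implementation defect.
* **tRNA placement.** tRNA-adjacent genes get a shorter readthrough median
  (default 80 nt) so the tRNA, placed at the configured offset past the
  TWE, still falls within the 200-nt pairing gap — which is also the
  biology being modelled: downstream tRNAs enforce early termination.
* **Cleaved ends.** `CLEAVED_5P` 3′ ends are Normal(0, jitter sd) clipped
  to ±50; `CLEAVED_3P` 5′ ends sit 0–30 nt past the pA.

What the simulator does **not** model: splicing, homopolymer-aware error
profiles, indels (optional errors are substitutions only), chromatin
effects, and intergenic transcription. Passing recovery tests therefore
demonstrates the pipeline's correctness given the stated read anatomy and
error model, not performance on real squiggle-space artefacts.

## Problem sizes in tests and the acceptance script

Simulation-backed checks use 30–100 genes at 60–120 reads per gene
(6,000–12,000 reads), sizes at which every recovery property is stable
across seeds while the full suite runs in well under a minute per check.
Mann–Whitney calibration uses 6,000 null genes (the exact test's true
rejection rate at n = 15/15 is 0.0453, and this replication bounds the
Monte-Carlo error at ~0.003) and 200 paired-shift replicates for power.
The classifier–oracle sweep covers every integer grid point of
d5 ∈ [−500, 600] × d3 ∈ [−100, 1200] at eight (tail, gap) combinations,
~11.5 million cases, plus a coarser sweep over neighbour-TSS positions.

## Known limitations

* The tail caller is sequence-only; very short tails (< ~8 nt) flanked by
  genomic A's are not reliably separable from the genome.
* Overlapping or nested annotated genes are excluded from neighbour
  relations; closely spaced-gene analyses assume disjoint gene bodies.
* The pipeline streams alignments sequentially and never random-accesses,
  so unindexed SAM input is fine, but reads spanning chromosome boundaries
  of concatenated references are not detected.
* Multi-PAC (alternative-polyadenylation) genes are dropped, not analysed.
* `CLEAVED_3P` reads overlapping a close same-strand neighbour are
  conservatively unclassified; true serial-cleavage products inside that
  100-nt guard zone are invisible to the chimera counter.
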