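# Methods

This note records the model behind each stage, the parameters that matter,
what the simulator does and does not emulate, and the numerical and design
choices made where the procedure was genuinely open.

## Read cleaning

Adapter trimming is gapless: at each read position *i* (scanned left to
right) a prefix of the adapter is aligned against the read suffix, over
`L = min(read_len − i, adapter_len)` bases, and a hit requires
`L ≥ min_overlap` (default 3) with at most `⌊max_error_rate · L⌋` mismatches
(default rate 0.1). The leftmost hit marks the insert end; everything from it
onward is removed. Reads with no hit are kept whole (configurable), reads
trimmed to nothing are discarded. Indel-tolerant alignment, as full trimming
tools implement it, is deliberately omitted: the simulator introduces no
indels, and the gapless rule is transparent and exactly testable. One
consequence is that trimming is single-pass; a pathological read whose
trimmed product happens to end in a short adapter prefix is not re-trimmed.
Quality filtering is limited to an N-count rule (default: none allowed) plus
an optional mean-Phred ≥ Q20 switch, off by default — published small-RNA
protocols rarely state more.

Length retention is 18–44 nt after trimming; putative piRNA selection later
narrows to 24–35 nt. Both ranges are configurable.

## Known-RNA subtraction

Rather than a homology search against an external database, a tag is
attributed to a known small RNA when ≥ `min_overlap_fraction` (default 0.8)
of its length overlaps an annotated rRNA/tRNA/snRNA/snoRNA/miRNA locus at
any of its genomic placements, on either strand (structural RNA fragments
arise from both). An optional exact-substring match against a reference
ncRNA FASTA covers loci missing from the annotation. Class ties resolve by
the fixed priority rRNA > tRNA > snRNA > snoRNA > miRNA. This
annotation-overlap surrogate has the same intent as a database search but is
self-contained and desk-testable; it is a declared substitution, not a
reconstruction of any particular search tool's scoring.

## Placement and fractional weighting

The built-in mapper reports **all** exact occurrences of a tag on both
strands via a 12-mer seed index with full verification; it accepts no
mismatches. Mismatch tolerance is delegated to ingestion of external SAM/BAM
or BED alignments, where records above `max_mismatches` (default 1, matching
the common `-v 1` aligner setting) are dropped and `n_hits` is always
recounted from the surviving records per query — never trusted from file
tags. Aligner-specific hit-set semantics (best-stratum reporting and the
like) are not emulated: `n_hits` means "placements present", a documented
dialect difference.

Weighting: `weight = count / n_hits` (count-weighted, the default — window
densities are read-level quantities) or `1 / n_hits` (unique-tag mode, for
sensitivity analysis). Per-tag weight sums are conserved to 1e-9 and
property-tested.

## Window scan and cluster calling

Windows of `window` bp (default 2000) start at every multiple of `step`
(default 400) from 0; a placement belongs to a window iff its strand-aware
5′ end (start on +, end−1 on −) lies in the window. 5′-end assignment was
chosen over full-overlap counting because it is unambiguous for overlapping
windows and conserves total weight across each non-overlapping phase of the
tiling; full-overlap counting is available behind `count_mode="overlap"`.
RPKM = count / (window/1000) / (library/1e6), with library = total weight of
all putative piRNA placements.

Clusters are maximal runs of significant windows (RPKM ≥ cutoff, default 1)
that overlap or abut; cluster counts are recomputed once over the merged
interval. Merging is idempotent and order-independent, and lowering the
cutoff never shrinks the covered length (property-tested). Cluster strand is
called "plus"/"minus" when the +-strand weight share is ≥0.8 / ≤0.2, else
"dual"; these thresholds are a package convention, since cluster strand
assignment has no standard rule. "Candidate" piRNAs are defined here as the
unique putative tags whose placements fall inside a called cluster, and are
labelled as such in the outputs.

An RPKM cutoff of 1 is calibrated for multi-million-read libraries: with a
library of *N* reads of weight ~1, a single read in a window already scores
RPKM = 1e6/(2·N), so for desk-scale simulations (N ~ 10⁴) the cutoff alone
accepts any non-empty window. The Poisson companion test exists for exactly
this situation: under the uniform null a window's count is Poisson with mean
λ = library · window / effective_genome_length (effective length = non-N
bases; the annotation-free choice), the p-value is the upper tail at
⌈observed⌉ (fractional counts round up, which is conservative), and windows
are corrected by Benjamini–Hochberg — named procedures chosen by the
package, as no correction is standard for this step.

### Calibration of the Poisson test

The test statistic is discrete, so its exact size at p < 0.05 is the largest
attainable tail probability below 0.05 and depends on λ. The type-I-error
check therefore fixes the design a priori: non-overlapping windows
(step = window) so the 10,000 simulated windows are independent, and
λ = 9.2382, the root of P(Poisson(λ) ≥ 15) = 0.0497, so the exact size is
≈0.05 rather than an arbitrary point below it. This is a property of the
calibration experiment, not a tunable of the test itself.

## Classification

Each putative tag is judged at its best placement (highest weight, ties to
the leftmost coordinate) so that categories partition the tag set even for
multimappers: ≥ `min_overlap_fraction` (default 0.5) overlap with a repeat
makes it TE-type, otherwise with a gene makes it gene-type, otherwise
intergenic; sense means placement strand equals feature strand. Repeats take
precedence over genes (configurable) — the conventional choice given that
repeat-derived piRNAs dominate germline libraries. Category totals are
reported both as unique-tag counts and read-weighted, since both conventions
appear in published catalogs. The TE composition table instead uses every
placement and splits each repeat group's weight into sense/antisense shares;
genome-coverage percentages per repeat class are recomputed from the
supplied annotation (`annotation_coverage`), never asserted.

## The simulator

`SyntheticSpec` plants, on a random genome split into equal chromosomes:
repeat families as near-identical copies (identical at mutation rate 0, so
reads from them are genuine k-fold multimappers), piRNA cluster intervals
(pairwise separated by `cluster_min_gap`, default 5000 bp, so 2 kb-window
calls cannot run together), one rRNA/tRNA/snoRNA/miRNA locus each, and a few
gene intervals — all non-overlapping. Reads are exact genomic substrings:
cluster and repeat reads draw lengths from the piRNA-sized component
(N(29, 1.5²) rounded), background reads from the full two-component mixture
(miRNA-sized N(22, 1.5²) vs piRNA-sized, the parametric form being a
modeling choice — only the bimodal shape with peaks at 22 and >28 nt is
given), and ncRNA contaminants from the short component. Every read gets the
3′ adapter appended and is truncated to the 50 bp sequencer read length;
qualities are a constant Phred 30.

The 5′-U bias is planted by rejection-sampling the read start so the genomic
base under the 5′ end is T with probability exactly `u1_probability`
(default 0.75) and non-T otherwise. This keeps reads exact substrings and
makes the expected 5′-T fraction equal the parameter itself; forcing T only
with probability u1 and leaving the remainder unconditioned would inflate
the fraction to u1 + (1−u1)/4. Repeat-derived reads are drawn antisense to
their copy with probability `repeat_antisense_fraction` (default 0.9),
emulating the antisense dominance of TE-targeting piRNAs.

Background reads are uniform over the genome on a uniform random strand —
matching the Poisson null the cluster caller assumes. Contaminant count is
set so ncRNA reads are `ncrna_contaminant_fraction` of the final total. All
randomness flows from one integer seed; identical spec + seed reproduce
byte-identical FASTA/FASTQ/BED/TSV outputs.

What the simulator does **not** emulate — and hence what passing tests do
not establish about real libraries: sequencing errors and quality-score
variation, indels in adapters, ping-pong 10-nt 5′-overlap read pairs,
transcription-unit structure under clusters, and realistic repeat-family
divergence landscapes. Results on real data additionally depend on the
external aligner's reporting policy.

## Problem sizes in the test suite

Unit fixtures use 100–200 kb genomes with a few thousand reads. The
planted-cluster recovery experiment plants 20 clusters of 5–9 kb on a 1 Mb
genome and draws 2,000,100 weighted placements directly at the positions the
read simulator would use (100,000 per cluster plus 100 background): the
library must be of order 10⁶ for "background RPKM ≪ 1" to be literally true
at the default cutoff (see the calibration remark above), and at that scale
the placement stage — not the read-sequence stage, which is exercised
end-to-end at smaller n elsewhere — is what the experiment measures. The
Poisson calibration uses 10,000 independent 2 kb windows on a 20 Mb
coordinate space with ~92,000 uniform placements. The 1U-recovery experiment
simulates 10,000 full reads (20 clusters × 500) through trimming and the
bias estimator.

## Known limitations

- The exact-match mapper is for fixtures and small genomes; real analyses
  should ingest alignments from a production aligner.
- Gapless trimming slightly under-trims reads with indels in the adapter.
- Cluster boundaries inherit ±(window − step) slop from the window grid; at
  the defaults this widens a called cluster by up to ~2 kb per side.
- Cluster strand thresholds (0.8/0.2) and the TE-over-gene precedence are
  conventions; both are configurable.
- The per-sample accounting labels the post-trim/post-filter collapse as the
  "raw" unique pool's successor; lane-level artifacts (PCR duplicates,
  quality trimming beyond the N rule) are out of scope.
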