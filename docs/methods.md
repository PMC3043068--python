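# Methods

This note records the models, calibrations and numerical choices behind
`mdagenome`, and what the synthetic experiments do and do not
demonstrate about real data.

## The recovery problem and the consensus recipe

The package targets the setting where a low-GC organism of interest
(~32% G+C) must be recovered from (a) several MDA-amplified single-cell
read sets, contamination-free but with severe locus-dependent
amplification bias, and (b) one bulk enrichment read set with gentle
bias but ~16% high-GC bacterial contamination. The consensus workflow
(`pipeline.run_consensus`) runs, in order: GC-filter derivation from
the single-cell sets and application to the bulk set → reference rescue
of removed high-GC reads → de novo assembly of the filtered bulk reads
→ split-alignment chimera exclusion of single-cell reads against that
assembly → per-cell assembly → shredding of cell contigs into
550-mers with 50-base overlaps → consensus assembly over filtered +
rescued bulk reads plus pseudo-reads → paired-end scaffolding →
contaminant screening → reference-guided orientation and ordering.
Each stage logs record counts to a provenance log; runs are
deterministic under the configured seed.

## The MDA bias model and its calibration

MDA produces wildly uneven locus representation; the literature
describes the phenomenon (per-cell assemblies plateau near 60% of the
genome across 10–30× depth, with independent profiles between cells)
rather than a generative model. We model a bias profile as a segmental
process:

* segment lengths ~ Exponential(mean 10 kb), tiling the genome;
* per-segment log-gains ~ Normal(0, σ²), i.e. lognormal gains;
* segments whose gain falls below the lognormal's q-quantile drop out
  (gain exactly 0). The cut is the *distribution* quantile, not the
  per-profile empirical one, so profiles with different seeds are fully
  independent.

A base is *recoverable* at sequencing effort d (mean depth) if its
expected depth d·gain/mean(gain) reaches a minimum assembly depth,
default 3 — roughly the depth below which greedy overlap assembly
fragments.

Calibration (fixed in code, not re-fit at run time): σ = 1.2 and
dropout quantile 0.40 for single cells. With these values the dropout
cut exceeds the depth threshold for all depths ≳ 8×, so the recoverable
fraction equals P(gain ≥ cut) = 0.60 essentially independently of depth
across 10–30× — exactly the depth-insensitive "each cell gives a
different 60%" phenomenon, with the union over k cells following
1 − 0.4^k by independence. The bulk profile uses σ = 0.8 with no
dropout, leaving ≈97% recoverable at 20×. A larger σ cannot reach the
60% plateau under any dropout setting (the lognormal mean explodes and
concentrates the simulated reads in a few segments), which is why σ is
a calibrated default rather than a free stylistic choice.

Chimeric reads (default 1% of shotgun reads) join two loci ≥ 2 kb
apart, junction uniform within the read, distal segment inverted with
probability 1/2 — the predominant distal/inverted character of MDA
strand-switch artifacts. Substitution errors combine a quality-derived
rate (constant mean Phred, default Q30 → 10⁻³) with an MDA polymerase
rate of 10⁻⁵ per base. 454-style homopolymer indels are not modelled:
every downstream stage is alignment-based and none depends on the
error type. Read lengths are Normal(400, 50) truncated to [50, 800];
pairs span Normal(3000, 300) with innie orientation.

What passing tests therefore show: the *pipeline logic* is correct
under a faithful statistical cartoon of MDA data. What they do not
show: robustness to indel-rich reads, to repeat-rich genomes (the
synthetic genomes are i.i.d. and essentially repeat-free), to uneven
GC within a genome, or to taxonomically structured contamination
beyond GC classes.

## GC filtering

Read GC is (#G+#C)/(#A+#C+#G+#T) with N excluded from both counts. The
retention cut is strict: a read is removed iff GC > threshold, so
boundary reads are kept. The default threshold is 0.46; it can also be
derived from the single-cell datasets as
mode + f·sqrt(mode·(1−mode)/mean read length), rounded up to the next
0.01, with f = 5.8 by default. The rationale for f: at a 32.4% mode and
400 bp reads the binomial read-GC sd is 0.0234, and 5.8 sd lands the
cut at 0.46 — far enough above the target mode that ≤0.1% of target
reads are lost, yet ~5 sd below a 58%-GC contaminant so ≥99.9% of its
reads are removed. Removed reads that map to a related reference at
90% identity over 40 bases are rescued; this recovers high-GC conserved
islands (rRNA-like) of the target.

## Alignment

The aligner is k-mer seeded (k = 11), scores +2/−3 with affine gaps
(open 5, extend 2 — megablast-like, suited to the ≥90%-identity mapping
regime), and reports identity as matches/columns. Seeds are grouped by
diagonal; a single diagonal is scored by an exact maximal-scoring-
segment scan (vectorised Kadane over the seed extent ± 2 kb), and
clusters of nearby diagonals on sequences ≤ 2 kb are resolved by a
banded affine Smith–Waterman over the cluster's diagonals ± 8. On the
substitution-dominated data this package targets, the gapless path is
exact; the banded path matches full Smith–Waterman whenever the optimal
path stays within the band (verified against an exhaustive
implementation in the tests). Long-vs-long comparisons use the gapless
path only — a documented limitation for indel-rich genomes. Best-hit
ties break by (lower subject id, lower subject start) so runs are
reproducible.

Chimera calls require that no single hit covers ≥80% of the read and
that two query-disjoint segments (each ≥40 bases at ≥90% identity) land
>2 kb apart or on inconsistent strands on the same subject. Split hits
on *different* subjects are deliberately not called — they may simply
span a reference gap — which trades recall for precision. Geometry also
caps recall: with junctions uniform in the read, ~35% of true chimeras
have a segment below 40 bases or above 80% coverage and are invisible
to any rule with these thresholds. The tests therefore check precision
≥0.95 overall and recall ≥0.80 *among geometrically detectable*
chimeras; overall recall sits near 0.6–0.75.

## Assembly and scaffolding

The assembler is a contract (reads → Assembly); any external assembler
can be plugged in. The built-in greedy assembler exists so the whole
pipeline is hermetically testable: reads are canonically ordered
(length desc, then id) for shuffle-invariance, contigs grow by
absorbing contained reads and appending the highest-scoring
suffix–prefix overlap (gapless, ≥40 bases at ≥97% identity, both
strands; ties by larger overlap then lexicographic id), and the final
sequence is a per-column majority vote (ties alphabetical). Chimeric
reads that survive upstream filters typically end as singleton junk
contigs rather than misjoins, because a genuine full-overlap read
outscores a half-overlapping chimera; this inflates element counts but
not error rates, and is the main reason synthetic element counts exceed
what a production assembler would report.

Scaffolding links contig ends supported by ≥3 read pairs with
consistent orientation and an implied gap within 3 library sd of
plausibility (gap ∈ [−3σ, span + 3σ]); bundles are accepted
strongest-first, one per contig end, refusing links that would close a
cycle (so the weakest link of any would-be cycle is dropped); gap
estimates are bundle means. Scaffold lengths include estimated gaps;
N50 is the length of the smallest element in the minimal set of largest
elements covering half the total.

Shredding cuts contigs into k-mers (default 550) stepping k−overlap
(default 500); a final window that would overrun is anchored to end
exactly at the contig end, guaranteeing full coverage; contigs shorter
than k pass through whole.

## Rarefaction

Nested subsamples (without replacement, seeded per fraction ×
replicate) are assembled and total assembly bases fitted with
S(d) = G·(1 − exp(−d/κ)) by least squares (Michaelis–Menten form
available; both report RMS residuals). Under uniform coverage the fit
recovers the genome size to well within 5% (and exactly on noiseless
model points). Under MDA-biased coverage the curve is a mixture of
saturation rates and the single-rate fit overshoots the asymptote by
~10–15% — the estimate should then be read as an upper bound, and the
per-cell vs bulk contrast (slower approach, same plateau) is the robust
signal.

## Reference-guided layout

Element orientation maximises the summed alignment score per strand;
ties default to '+' with a logged warning. Order keys use only hits
co-oriented with the chosen strand: Σ(hit subject length × subject
midpoint)/Σ(hit subject length). The midpoint convention makes the key
symmetric and invariant to splitting a hit in two; subject-side length
is used as the weight (identical to query-side for gapless hits).
Unplaced elements (no co-oriented hits) are appended after placed ones
in input order. Contigs ≥50% covered by hits to any single contaminant
reference are excluded, with the offending reference named; the 50%
coverage rule is config-exposed.

## Comparative statistics

* **RBH**: best hit per gene by score (ties → lower id), pairs kept iff
  mutual; confidence 'high' iff the forward hit covers ≥60% of the
  query. Protein scoring goes through BLOSUM62 (Biopython backend)
  behind the same scorer contract; nucleotide RBH uses the package
  aligner.
* **ANI**: corresponding regions are the union of *reference* positions
  covered by accepted hits (default: ≥50% identity over ≥100 columns);
  identity is the hit-length-weighted mean; the whole-genome average
  scores the non-corresponding remainder at a 25% floor. Measuring
  correspondence on the reference's coordinate space is what makes the
  published-scale worked example reproduce exactly.
* **Novelty**: per target position, each reference contributes the
  identity of the best accepted hit covering it (0 if none); novelty =
  R − Σ over the R references (R = 2 by default), bounded in [0, R] and
  monotone under added homology. Best-hit (not summed-hit) identity
  keeps the index bounded and split-invariant.
* **Microheterogeneity**: contigs of one assembly aligned to another;
  accepted best-hit regions give length-weighted identity, substitution
  counts (gap columns reported separately, excluded from SNPs) and
  SNPs per aligned Mb.
* **Expected errors**: two-tier n_low·10^(−q_low/10) +
  n_high·10^(−q_high/10) (defaults Q10/Q40), the exact per-base sum
  when full qualities are available, and a separate MDA term of
  10⁻⁵ × genome length. The two-tier formula is reported as stated; on
  the published-scale inputs it yields ≈767 low+high-tier errors, and
  the MDA term stays below 20 bases on a 1.77 Mb genome.

## Codon usage and skews

Codon usage counts in-frame codons (sequences truncated to whole
codons; codons containing N skipped) and reports per-mille frequencies;
the scrambled control permutes each CDS's nucleotides independently
(exact base multiset preserved), destroying codon structure while
matching composition. The comparison metric is Euclidean distance on
per-mille vectors (cosine available) — the comparison method is a
package choice, documented here because no standard exists. GC skew is
(G−C)/(G+C) per window; the "GGG+T" skew is implemented as the tetramer
GGGT versus its reverse complement ACCC (the replication-strand
oligomer-skew convention), with the motif exposed as a parameter.
Cumulative variants sum per-window count differences over
non-overlapping windows, so the final value telescopes to the total
count difference; transition points are local extrema ranked by
prominence. Tracks are computed on the concatenated ordered assembly by
default (per-element mode available).

## Problem sizes

The shipped study conditions are desk-scale by design: a 200 kb target
with two 100 kb contaminants, five cells at 12× (within the 10–30×
single-cell regime; the bias plateau is depth-insensitive there) and a
20× bulk, which the end-to-end consensus run reconstructs to ≥97% with
zero contaminant contigs in a few minutes on one CPU. Full-scale
(multi-Mb) genomes are supported by the same code paths but are not
exercised by the default test suite.

## Known limitations

* Substitution-only error and divergence models; the long-sequence
  alignment path is gapless.
* The greedy assembler is O(reads × depth) with small constants but is
  not repeat-aware; element counts run high because unfiltered chimeras
  become singleton contigs.
* Rarefaction asymptotes overshoot on strongly rate-mixed (MDA-biased)
  curves.
* The synthetic contaminants are GC-class cartoons, not real taxa;
  filter performance on organisms whose GC distributions overlap the
  target's is untested and would be worse.
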