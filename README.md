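# mdagenome

Hybrid single-cell + metagenomic recovery of a microbial genome, as a
tested, reusable Python pipeline.

## The problem

Many environmentally important microbes — the motivating case is an
ammonia-oxidizing archaeon living in low-salinity estuarine sediment —
cannot be grown in pure culture. Two imperfect sequencing routes exist
for such organisms:

* **Single-cell sequencing.** Individual cells are isolated and their
  genomes amplified by multiple displacement amplification (MDA) before
  sequencing. The reads are contamination-free, but MDA bias is severe:
  at 10–30× mean depth each cell typically yields only ~60% of its
  genome, and MDA strand-switching produces chimeric reads. Crucially,
  each cell's bias profile is independent, so *different* cells recover
  *different* 60%s.
* **Bulk enrichment metagenomics.** Sequencing an enrichment culture
  gives gentler amplification bias, but the reads are a mixture — here
  ~84% target archaea and ~16% high-GC contaminant bacteria.

`mdagenome` implements the consensus recipe that combines both: the
contamination-free single-cell datasets define a stringent G+C read
filter (reads above 46% G+C are purged from the bulk data, with
reference-based rescue of high-GC conserved regions such as rRNA);
split-alignment mapping rejects chimeric single-cell reads; per-cell
assemblies are shredded into 550-mers with 50-base overlaps and fed,
together with the filtered bulk reads, into one consensus assembly that
is then scaffolded with read pairs, screened against known contaminant
genomes, and oriented/ordered against a reference relative.

Around that core the package provides the accompanying analyses:

* rarefaction genome-size estimation — assemble nested read subsamples
  and fit the saturating model S(d) = G·(1 − e^(−d/κ)); the asymptote G
  estimates genome size and bases(A)/G the completeness of assembly A;
* windowed G+C, GC-skew ((G−C)/(G+C)) and oligomer-skew (GGGT vs ACCC)
  tracks, cumulative forms and their transition points;
* codon usage against a nucleotide-matched scrambled control;
* reciprocal best hits (RBH) with the 60%-query-coverage confidence
  rule; corresponding-region ANI and the floored whole-genome identity
  wgi = (ANI·corr + 0.25·(L_ref − corr)) / L_ref;
* a per-position novelty index (2 − Σ best-hit identities to two
  reference genomes) with an alignment-depth track;
* microheterogeneity (pairwise ANI / SNPs per Mb between per-cell
  assemblies) and Phred expected-error budgets.

Because the original 454 read sets are not redistributable, the package
ships a first-class synthetic-data module: ground-truthed communities
with segmental-lognormal MDA bias (calibrated so one cell at 20× leaves
~60% of the genome recoverable), chimeric reads, 454-like lengths and
qualities, paired ends and sample barcodes. Every stage can therefore
be scored against known truth.

## Worked example

```python
import json
from mdagenome.pipeline import PipelineConfig, run_consensus
from mdagenome.simulate import CommunitySpec, GenomeSpec

target = GenomeSpec("target", 60_000, 0.324, composition_switch=30_000, seed=0)
contamA = GenomeSpec("contamA", 30_000, 0.58, seed=1)
contamB = GenomeSpec("contamB", 30_000, 0.65, seed=2)
community = CommunitySpec(target, ((contamA, 1.0), (contamB, 1.0)))

cfg = PipelineConfig(outdir="run", seed=1, community=community,
                     n_cells=3, n_scaffold_pairs=300,
                     rarefaction_fractions=(0.2, 0.5, 1.0))
result = run_consensus(cfg)
print(json.dumps(result.evaluation, indent=1))
```

prints (about 15 s on one CPU):

```json
{
 "target_coverage": 0.9947,
 "contaminant_contigs_after_screen": 0,
 "excluded_contigs": 0,
 "excluded_contaminant_origin": 0,
 "genome_size_estimate": 65573.69298517433,
 "true_genome_size": 60000
}
```

Reading: from three heavily biased single cells (each covering only
~60% of a 60 kb synthetic target) plus a contaminated bulk sample, the
consensus assembly reconstructs 99.5% of the true genome; no
contaminant-origin contig survives the screen; and the rarefaction
asymptote estimates the genome size at ~66 kb (+9% — MDA-biased
curves saturate as a mixture of rates, which the single-rate fit
slightly overshoots; see `docs/methods.md`). `result.stats` carries the
usual assembly statistics (N50, scaffold bases, element counts), and
the run directory holds FASTA/TSV/BedGraph/JSON artifacts plus a
provenance log in which every read is accounted for.

The same stages are exposed on the command line:

```sh
mdagenome run --outdir run --seed 1      # full synthetic consensus workflow
mdagenome simulate --out sim --seed 0    # ground-truthed reads + truth table
mdagenome filter sim/reads.fastq --out-retained low.fastq --out-removed high.fastq
mdagenome assemble low.fastq --out contigs.fasta
mdagenome compare contigs.fasta reference.fasta
```

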