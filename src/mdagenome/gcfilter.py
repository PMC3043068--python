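"""G+C-content statistics, the stringent high-GC read filter, and
reference-based rescue of high-GC conserved reads.

The filter exploits the bimodal read-GC mixture of a low-GC target
organism amplified together with high-GC contaminants: reads above a
threshold (default 46% G+C, strict) are removed, then the removed pool
is mapped against reference genomes (90% identity over 40 bases) to
rescue reads from high-GC conserved regions such as rRNA operons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .align import KmerIndex, MapCriteria, map_reads
from .records import ReadSet, SequenceRecord


@dataclass
class GCDistribution:
    bin_edges: np.ndarray
    counts: np.ndarray
    mode: float  # GC at the peak bin centre (ties -> lowest GC)
    dispersion: float  # sample sd of per-read GC
    mean_read_length: float

    def __post_init__(self) -> None:
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if not (0 <= self.mode <= 1):
            raise ValueError("mode must lie in [0, 1]")


@dataclass(frozen=True)
class FilterParams:
    """``gc_threshold`` is a strict upper bound for retention: reads with
    GC *greater than* the threshold are removed."""

    gc_threshold: float = 0.46
    rescue_criteria: MapCriteria = field(default_factory=MapCriteria)

    def __post_init__(self) -> None:
        if not (0 < self.gc_threshold < 1):
            raise ValueError("gc_threshold must be in (0, 1)")


def gc_content(seq: SequenceRecord | str) -> float:
    """(#G + #C) / (#A + #C + #G + #T); N excluded from both numerator
    and denominator.  All-N sequences return NaN."""
    bases = seq.bases if isinstance(seq, SequenceRecord) else seq
    if not bases:
        raise ValueError("sequence must be non-empty")
    gc = bases.count("G") + bases.count("C")
    acgt = gc + bases.count("A") + bases.count("T")
    if acgt == 0:
        return float("nan")
    return gc / acgt


def gc_histogram(reads: ReadSet, bin_width: float = 0.01) -> GCDistribution:
    """Histogram of per-read GC fractions over [0, 1]."""
    if len(reads) == 0:
        raise ValueError("at least one read required")
    vals = np.array([gc_content(r) for r in reads])
    vals = vals[~np.isnan(vals)]
    nbins = int(round(1.0 / bin_width))
    counts, edges = np.histogram(vals, bins=nbins, range=(0.0, 1.0))
    peak = int(np.argmax(counts))  # argmax takes the first (lowest-GC) tie
    mode = float((edges[peak] + edges[peak + 1]) / 2)
    dispersion = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    mean_len = float(np.mean([len(r) for r in reads]))
    return GCDistribution(edges, counts, mode, dispersion, mean_len)


def round_up_to(x: float, step: float = 0.01) -> float:
    """Smallest multiple of ``step`` strictly greater than ``x`` minus a
    hair of float slack (0.4595 -> 0.46; exactly 0.46 -> 0.47)."""
    return (math.floor(x / step + 1e-9) + 1) * step


def threshold_from_mode(
    mode: float, mean_read_length: float, sigma_factor: float = 5.8
) -> float:
    """GC retention threshold = mode + sigma_factor * binomial read-GC
    sd, rounded up to the next 0.01.

    The binomial sd of read GC at mode p and read length L is
    sqrt(p(1-p)/L).  The default factor 5.8 places the cut far enough
    above the target's mode that essentially no target read is lost
    (mode 0.324 at 400 bp reads gives 0.324 + 5.8*0.0234 = 0.4595 ->
    0.46) while sitting several sd below a >55%-GC contaminant mode.
    """
    sd = math.sqrt(mode * (1 - mode) / mean_read_length)
    return round(round_up_to(mode + sigma_factor * sd), 2)


def derive_gc_threshold(
    single_cell_reads: Sequence[ReadSet], sigma_factor: float = 5.8
) -> float:
    """Derive the filter threshold from pooled single-cell read GC.

    Single-cell datasets are contamination-free by construction, so
    their pooled GC mode and read length define where the target's read
    GC distribution ends; see :func:`threshold_from_mode`.
    """
    if not single_cell_reads:
        raise ValueError("need at least one single-cell ReadSet")
    pooled = ReadSet(
        [r for rs in single_cell_reads for r in rs], source_label="pooled"
    )
    dist = gc_histogram(pooled)
    return threshold_from_mode(dist.mode, dist.mean_read_length, sigma_factor)


def gc_filter(
    reads: ReadSet, params: FilterParams = FilterParams()
) -> tuple[ReadSet, ReadSet]:
    """Partition reads into (retained, removed); removed iff GC strictly
    above the threshold.  Reads at exactly the threshold are retained."""
    retained, removed = [], []
    for rec in reads:
        gc = gc_content(rec)
        (removed if gc > params.gc_threshold else retained).append(rec)
    label = reads.source_label
    return (
        ReadSet(retained, source_label=label),
        ReadSet(removed, source_label=f"{label}:high_gc"),
    )


def rescue_high_gc(
    removed: ReadSet,
    references: Sequence[SequenceRecord],
    criteria: MapCriteria = MapCriteria(),
    index: Optional[KmerIndex] = None,
) -> ReadSet:
    """Reads from the removed (high-GC) pool that map to any reference
    under ``criteria`` — recovers high-GC conserved regions of the
    target (e.g. rRNA) using related reference genomes."""
    if not references:
        raise ValueError("references must be non-empty")
    if len(removed) == 0:
        return ReadSet([], source_label=f"{removed.source_label}:rescued")
    mapped, _ = map_reads(removed, references, criteria, index=index)
    rescued = [r for r in removed if r.id in mapped]
    return ReadSet(rescued, source_label=f"{removed.source_label}:rescued")


def write_gc_histogram_tsv(dist: GCDistribution, path) -> None:
    with open(path, "w") as fh:
        fh.write("# bin_center\tcount\n")
        centers = (dist.bin_edges[:-1] + dist.bin_edges[1:]) / 2
        for c, n in zip(centers, dist.counts):
            fh.write(f"{c:.3f}\t{int(n)}\n")


def write_filter_decisions_tsv(reads: ReadSet, params: FilterParams, path) -> None:
    with open(path, "w") as fh:
        fh.write("# read_id\tgc\tdecision\n")
        for rec in reads:
            gc = gc_content(rec)
            decision = "removed" if gc > params.gc_threshold else "retained"
            fh.write(f"{rec.id}\t{gc:.4f}\t{decision}\n")
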