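"""Windowed composition tracks (GC, GC skew, oligomer skew, cumulative
forms and their transition points), codon usage with a
nucleotide-matched scrambled control, and annotation summaries.

Skew conventions: per-window GC skew is (G - C) / (G + C); the
cumulative variant is the running sum of per-window (G - C) *counts*
over non-overlapping windows, whose final value telescopes to the total
count difference over the windowed span.  The oligomer skew (default
motif GGGT vs its reverse complement ACCC) follows the same pattern on
overlapping motif occurrences counted on the forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .records import SequenceRecord, revcomp

_SENSE_BASES = "ACGT"
CODONS = [a + b + c for a in _SENSE_BASES for b in _SENSE_BASES for c in _SENSE_BASES]
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class Track:
    """A windowed statistic along a genome (fixed step)."""

    starts: np.ndarray
    values: np.ndarray
    window: int
    step: int
    statistic: str

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.starts) != len(self.values):
            raise ValueError("starts and values must have equal length")
        if self.step > self.window:
            raise ValueError("step must not exceed window")

    def __len__(self) -> int:
        return len(self.values)


def _window_starts(n: int, window: int, step: int) -> np.ndarray:
    if window > n:
        raise ValueError("window exceeds sequence length")
    return np.arange(0, n - window + 1, step)


def _base_indicator(genome: SequenceRecord, base: str) -> np.ndarray:
    arr = np.frombuffer(genome.bases.encode(), dtype=np.uint8)
    return (arr == ord(base)).astype(np.int64)


def _window_sums(ind: np.ndarray, starts: np.ndarray, window: int) -> np.ndarray:
    cum = np.concatenate([[0], np.cumsum(ind)])
    return cum[starts + window] - cum[starts]


def windowed_gc(
    genome: SequenceRecord, window: int = 5000, step: int = 1000
) -> Track:
    """Per-window GC fraction, N excluded; a final partial window is dropped."""
    starts = _window_starts(len(genome.bases), window, step)
    g = _window_sums(_base_indicator(genome, "G"), starts, window)
    c = _window_sums(_base_indicator(genome, "C"), starts, window)
    a = _window_sums(_base_indicator(genome, "A"), starts, window)
    t = _window_sums(_base_indicator(genome, "T"), starts, window)
    denom = g + c + a + t
    vals = np.where(denom > 0, (g + c) / np.maximum(denom, 1), np.nan)
    return Track(starts, vals, window, step, "gc")


def gc_skew(
    genome: SequenceRecord,
    window: int = 5000,
    step: int = 1000,
    cumulative: bool = False,
) -> Track:
    """Per-window (G - C)/(G + C), or the cumulative running sum of
    per-window (G - C) counts (cumulative mode uses step = window)."""
    if cumulative:
        step = window
    starts = _window_starts(len(genome.bases), window, step)
    g = _window_sums(_base_indicator(genome, "G"), starts, window)
    c = _window_sums(_base_indicator(genome, "C"), starts, window)
    if cumulative:
        vals = np.cumsum(g - c).astype(float)
        return Track(starts, vals, window, step, "gc_skew_cumulative")
    denom = g + c
    vals = np.where(denom > 0, (g - c) / np.maximum(denom, 1), 0.0)
    return Track(starts, vals, window, step, "gc_skew")


def _count_occurrences(genome: str, motif: str) -> np.ndarray:
    """Indicator of overlapping motif occurrence start positions."""
    arr = np.frombuffer(genome.encode(), dtype=np.uint8)
    m = np.frombuffer(motif.encode(), dtype=np.uint8)
    n = len(arr) - len(m) + 1
    if n <= 0:
        return np.zeros(len(arr), dtype=np.int64)
    hit = np.ones(n, dtype=bool)
    for i, ch in enumerate(m):
        hit &= arr[i : i + n] == ch
    out = np.zeros(len(arr), dtype=np.int64)
    out[:n] = hit
    return out


def oligo_skew(
    genome: SequenceRecord,
    motif: str = "GGGT",
    window: int = 5000,
    step: int = 1000,
    cumulative: bool = False,
) -> Track:
    """Strand skew of an oligomer vs its reverse complement.

    Per-window value is (n(motif) - n(revcomp)) / (n(motif) + n(revcomp))
    over overlapping forward-strand occurrences (0 when both are 0); the
    cumulative variant is the running sum of count differences over
    non-overlapping windows.
    """
    motif = motif.upper()
    if not motif:
        raise ValueError("motif must be non-empty")
    rc = revcomp(motif)
    if rc == motif:
        raise ValueError(f"motif {motif} is its own reverse complement; skew undefined")
    if cumulative:
        step = window
    starts = _window_starts(len(genome.bases), window, step)
    fwd = _window_sums(_count_occurrences(genome.bases, motif), starts, window)
    rev_ = _window_sums(_count_occurrences(genome.bases, rc), starts, window)
    if cumulative:
        vals = np.cumsum(fwd - rev_).astype(float)
        return Track(starts, vals, window, step, f"{motif}_skew_cumulative")
    denom = fwd + rev_
    vals = np.where(denom > 0, (fwd - rev_) / np.maximum(denom, 1), 0.0)
    return Track(starts, vals, window, step, f"{motif}_skew")


@dataclass
class TransitionPoint:
    position: int  # genome coordinate (window centre)
    kind: str  # 'max' or 'min'
    prominence: float


def find_transitions(track: Track) -> list[TransitionPoint]:
    """Local extrema of a cumulative track ranked by prominence.

    Monotone tracks return the two endpoints flagged with kind 'max'/'min'
    and prominence 0 ("no internal transition").
    """
    if len(track) < 3:
        raise ValueError("track must have at least 3 windows")
    v = track.values
    centres = track.starts + track.window // 2
    out: list[TransitionPoint] = []
    for sign, kind in ((1.0, "max"), (-1.0, "min")):
        peaks, props = find_peaks(sign * v, prominence=0)
        for p, prom in zip(peaks, props["prominences"]):
            out.append(TransitionPoint(int(centres[p]), kind, float(prom)))
    if not out:
        hi, lo = int(np.argmax(v)), int(np.argmin(v))
        return [
            TransitionPoint(int(centres[hi]), "max", 0.0),
            TransitionPoint(int(centres[lo]), "min", 0.0),
        ]
    out.sort(key=lambda t: (-t.prominence, t.position))
    return out


@dataclass
class CodonUsageTable:
    counts: dict  # codon -> count, all 64 codons present
    total_codons: int

    def __post_init__(self) -> None:
        if set(self.counts) != set(CODONS):
            raise ValueError("counts must cover all 64 codons")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be nonnegative")

    def frequencies_per_mille(self) -> dict:
        if self.total_codons == 0:
            return {c: 0.0 for c in CODONS}
        return {c: 1000.0 * n / self.total_codons for c, n in self.counts.items()}

    def vector(self) -> np.ndarray:
        f = self.frequencies_per_mille()
        return np.array([f[c] for c in CODONS])


def codon_usage(cds_sequences: Sequence[SequenceRecord | str]) -> CodonUsageTable:
    """In-frame codon counts over a CDS collection.

    Sequences whose length is not divisible by 3 are truncated to the
    last full codon; codons containing N are skipped.
    """
    if not cds_sequences:
        raise ValueError("empty CDS set")
    counts = {c: 0 for c in CODONS}
    total = 0
    for rec in cds_sequences:
        seq = rec.bases if isinstance(rec, SequenceRecord) else rec.upper()
        seq = seq[: 3 * (len(seq) // 3)]
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if codon in counts:
                counts[codon] += 1
                total += 1
    return CodonUsageTable(counts, total)


def scrambled_control(
    cds_sequences: Sequence[SequenceRecord], seed: int = 0
) -> list[SequenceRecord]:
    """Nucleotide-matched scrambled control: each CDS is independently
    shuffled at the nucleotide level (exact base multiset preserved)."""
    rng = np.random.default_rng(seed)
    out = []
    for rec in cds_sequences:
        arr = np.frombuffer(rec.bases.encode(), dtype=np.uint8).copy()
        rng.shuffle(arr)
        out.append(SequenceRecord(f"{rec.id}_scrambled", arr.tobytes().decode()))
    return out


def codon_usage_distance(
    a: CodonUsageTable, b: CodonUsageTable, metric: str = "euclidean"
) -> float:
    """Distance between per-thousand codon frequency vectors."""
    va, vb = a.vector(), b.vector()
    if metric == "euclidean":
        return float(np.linalg.norm(va - vb))
    if metric == "cosine":
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0 or nb == 0:
            return 1.0
        return float(1.0 - va @ vb / (na * nb))
    raise ValueError(f"unknown metric {metric!r}")


GENE_CATEGORIES = ("CDS", "pseudogene", "tRNA", "rRNA", "other RNA")
ANNOT_STATUS = ("functional", "conserved-hypothetical", "hypothetical")


def validate_gene_table(genes: pd.DataFrame) -> pd.DataFrame:
    """Validate the per-gene table (id, element, start, end, strand,
    category, status); coordinates 0-based half-open."""
    required = {"id", "element", "start", "end", "strand", "category"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    if (genes["start"] >= genes["end"]).any():
        raise ValueError("gene start must be < end")
    bad = set(genes["category"]) - set(GENE_CATEGORIES)
    if bad:
        raise ValueError(f"unknown gene categories: {sorted(bad)}")
    return genes


@dataclass
class AnnotationSummary:
    total_genes: int
    orfs: int
    pseudogenes: int
    rna_genes: int
    coding_fraction: float
    orf_density: float  # ORFs per kb, 2 decimals
    average_gene_length: float

    def __post_init__(self) -> None:
        if self.total_genes != self.orfs + self.pseudogenes + self.rna_genes:
            raise ValueError("total must equal the category sum")
        if not (0 <= self.coding_fraction <= 1):
            raise ValueError("coding fraction must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "Predicted genes": self.total_genes,
            "Total number of ORFs": self.orfs,
            "Pseudogenes": self.pseudogenes,
            "RNA genes": self.rna_genes,
            "Coding percentage, %": round(100 * self.coding_fraction),
            "ORF density (ORF/kb)": self.orf_density,
            "Average gene length (bp)": round(self.average_gene_length),
        }


def _interval_union(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last = -1
    for a, b in sorted(intervals):
        a = max(a, last)
        if b > a:
            total += b - a
            last = b
    return total


def annotation_summary(genes: pd.DataFrame, assembly_length: int) -> AnnotationSummary:
    """Genome-feature summary from a gene table.

    ORF density = ORFs / (assembly length / 1000), 2 decimals; coding
    fraction = union of CDS + pseudogene intervals / assembly length
    (overlaps and nesting handled by interval union, per element).
    """
    genes = validate_gene_table(genes)
    orfs = int((genes["category"] == "CDS").sum())
    pseudo = int((genes["category"] == "pseudogene").sum())
    rna = int(genes["category"].isin(["tRNA", "rRNA", "other RNA"]).sum())
    coding = genes[genes["category"].isin(["CDS", "pseudogene"])]
    covered = sum(
        _interval_union(list(zip(sub["start"], sub["end"])))
        for _, sub in coding.groupby("element")
    )
    lengths = genes["end"] - genes["start"]
    return AnnotationSummary(
        total_genes=orfs + pseudo + rna,
        orfs=orfs,
        pseudogenes=pseudo,
        rna_genes=rna,
        coding_fraction=covered / assembly_length,
        orf_density=round(orfs / (assembly_length / 1000.0), 2),
        average_gene_length=float(lengths.mean()) if len(genes) else 0.0,
    )


def write_track_bedgraph(track: Track, element: str, path) -> None:
    """4-column BedGraph (element, start, end, value); end = start + window."""
    with open(path, "w") as fh:
        for s, v in zip(track.starts, track.values):
            fh.write(f"{element}\t{int(s)}\t{int(s) + track.window}\t{v:.6g}\n")


def write_codon_table_tsv(table: CodonUsageTable, path) -> None:
    freqs = table.frequencies_per_mille()
    with open(path, "w") as fh:
        fh.write("# codon\tcount\tper_mille\n")
        for c in CODONS:
            fh.write(f"{c}\t{table.counts[c]}\t{freqs[c]:.2f}\n")
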