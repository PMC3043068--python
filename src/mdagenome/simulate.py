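"""Ground-truthed synthetic communities with MDA-style amplification bias.

The generator emulates the statistical structure a hybrid single-cell +
metagenomic genome recovery has to cope with:

* a low-GC target genome (~32% G+C) mixed with high-GC contaminants,
  with the target making up ~84% of cells in the bulk sample;
* per-cell multiple displacement amplification (MDA) bias — segmental
  lognormal amplification gains with hard dropout, independent between
  cells, calibrated so a single cell sequenced to ~20x mean depth leaves
  about 60% of the genome recoverable while a bulk (gentler) profile
  leaves >97%;
* MDA chimeric reads joining loci >= 2 kb apart, the distal segment
  inverted with probability 1/2;
* 454-Titanium-like reads: ~400 +/- 50 bp shotgun reads, ~3 kb-span read
  pairs, constant mean Phred qualities, substitution errors from the
  quality model plus a 1e-5 per-base MDA polymerase error rate.

Every read carries a truth record (origin genome, locus, strand, chimera
junction) so downstream filters, mappers and assemblers can be scored
against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .records import ReadSet, SequenceRecord, revcomp

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of one synthetic genome.

    ``composition_switch`` marks a position where the G:C strand balance
    flips from even to ``switch_g_fraction`` : (1 - switch_g_fraction)
    at constant total G+C — used to plant a detectable skew transition.
    """

    name: str
    length: int
    gc: float
    composition_switch: Optional[int] = None
    switch_g_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.gc <= 1):
            raise ValueError("gc must be in (0, 1]")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.composition_switch is not None and not (
            0 <= self.composition_switch < self.length
        ):
            raise ValueError("composition_switch must lie within the genome")


@dataclass(frozen=True)
class CommunitySpec:
    """The target organism plus weighted high-GC contaminants."""

    target: GenomeSpec
    contaminants: tuple[tuple[GenomeSpec, float], ...] = ()
    target_fraction: float = 0.84

    def __post_init__(self) -> None:
        if not (0 < self.target_fraction <= 1):
            raise ValueError("target_fraction must be in (0, 1]")
        for spec, w in self.contaminants:
            if w <= 0:
                raise ValueError(f"abundance of {spec.name} must be positive")
        names = [self.target.name] + [s.name for s, _ in self.contaminants]
        if len(names) != len(set(names)):
            raise ValueError("genome names must be unique")

    def abundances(self) -> dict[str, float]:
        if not self.contaminants:
            return {self.target.name: 1.0}
        out = {self.target.name: self.target_fraction}
        total_w = sum(w for _, w in self.contaminants)
        for spec, w in self.contaminants:
            out[spec.name] = (1.0 - self.target_fraction) * w / total_w
        return out

    def specs(self) -> dict[str, GenomeSpec]:
        out = {self.target.name: self.target}
        out.update({s.name: s for s, _ in self.contaminants})
        return out


@dataclass
class BiasProfile:
    """Segmental amplification gains tiling [0, genome_length).

    ``gains[i]`` is the relative amplification weight of segment i;
    dropped-out segments have gain exactly 0.
    """

    starts: np.ndarray  # segment start positions, starts[0] == 0
    lengths: np.ndarray
    gains: np.ndarray
    genome_length: int
    seed: int = 0

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.gains = np.asarray(self.gains, dtype=float)
        if self.lengths.sum() != self.genome_length:
            raise ValueError("segments must tile [0, genome_length)")
        if (self.gains < 0).any():
            raise ValueError("gains must be nonnegative")
        if not (self.gains > 0).any():
            raise ValueError("at least one gain must be positive")

    @property
    def dropout(self) -> np.ndarray:
        return self.gains == 0.0

    def per_base_gain(self) -> np.ndarray:
        return np.repeat(self.gains, self.lengths)

    def mean_gain(self) -> float:
        return float((self.lengths * self.gains).sum() / self.genome_length)


@dataclass(frozen=True)
class ReadModel:
    """454-Titanium-like read length, pairing, quality and error model."""

    mean_len: float = 400.0
    sd_len: float = 50.0
    min_len: int = 50
    max_len: int = 800
    pair_span: float = 3000.0
    sd_span: float = 300.0
    base_quality: int = 30
    sub_error_rate_from_quality: bool = True
    chimera_rate: float = 0.01
    mda_sub_rate: float = 1e-5

    def __post_init__(self) -> None:
        for rate in (self.chimera_rate, self.mda_sub_rate):
            if not (0 <= rate <= 1):
                raise ValueError("rates must be in [0, 1]")
        if self.mean_len <= 0 or self.pair_span <= 0:
            raise ValueError("lengths must be positive")

    def per_base_error(self) -> float:
        p = self.mda_sub_rate
        if self.sub_error_rate_from_quality:
            p += 10.0 ** (-self.base_quality / 10.0)
        return p


@dataclass
class SimulatedSample:
    """Reads plus complete per-read ground truth for one simulated dataset."""

    reads: ReadSet
    truth: pd.DataFrame
    bias: dict[str, BiasProfile]
    community: CommunitySpec
    genomes: dict[str, SequenceRecord]


def simulate_genome(spec: GenomeSpec) -> SequenceRecord:
    """Draw an i.i.d. genome at the requested G+C fraction.

    Before ``composition_switch`` P(G) = P(C) = gc/2; after it the G
    share of gc rises to ``switch_g_fraction`` (total gc unchanged), so
    cumulative GC skew has a planted transition at the switch.
    """
    rng = np.random.default_rng(spec.seed)
    at = 1.0 - spec.gc

    def draw(n: int, g_frac: float) -> np.ndarray:
        p = [at / 2, (1 - g_frac) * spec.gc, g_frac * spec.gc, at / 2]  # A C G T
        return rng.choice(4, size=n, p=p)

    if spec.composition_switch is None:
        codes = draw(spec.length, 0.5)
    else:
        head = draw(spec.composition_switch, 0.5)
        tail = draw(spec.length - spec.composition_switch, spec.switch_g_fraction)
        codes = np.concatenate([head, tail])
    return SequenceRecord(spec.name, "".join(_BASES[codes]))


def simulate_bias_profile(
    genome_length: int,
    mean_segment: float = 10_000.0,
    sigma: float = 1.2,
    dropout_quantile: float = 0.40,
    seed: int = 0,
) -> BiasProfile:
    """Draw a segmental lognormal MDA bias profile.

    Segment lengths are exponential(mean_segment); per-segment log-gains
    are N(0, sigma^2); segments whose gain falls below the lognormal's
    ``dropout_quantile`` quantile drop out (gain 0).  The dropout cut is
    the distribution quantile, not the per-profile empirical one, so
    profiles with different seeds are fully independent.

    Defaults (sigma 1.2, dropout 0.40, see methods note) are calibrated
    so that at ~20x mean depth about 60% of the genome clears a minimum
    expected depth of 3, near-independently of depth in the 10-30x range.
    """
    if genome_length <= mean_segment:
        raise ValueError("genome_length must exceed mean_segment")
    rng = np.random.default_rng(seed)
    lengths: list[int] = []
    total = 0
    while total < genome_length:
        seg = max(1, int(round(rng.exponential(mean_segment))))
        seg = min(seg, genome_length - total)
        lengths.append(seg)
        total += seg
    lengths_arr = np.array(lengths, dtype=np.int64)
    gains = np.exp(rng.normal(0.0, sigma, size=len(lengths_arr))) if sigma > 0 else np.ones(len(lengths_arr))
    if dropout_quantile > 0 and sigma > 0:
        cut = float(np.exp(sigma * norm.ppf(dropout_quantile)))
        gains = np.where(gains < cut, 0.0, gains)
        if not (gains > 0).any():  # pathological draw: keep the best segment
            gains = np.exp(rng.normal(0.0, sigma, size=len(lengths_arr)))
    starts = np.concatenate([[0], np.cumsum(lengths_arr)[:-1]])
    return BiasProfile(starts, lengths_arr, gains, genome_length, seed=seed)


def bulk_bias_profile(genome_length: int, seed: int = 0) -> BiasProfile:
    """Gentle bulk-MDA profile: sigma 0.8, no dropout."""
    return simulate_bias_profile(
        genome_length, sigma=0.8, dropout_quantile=0.0, seed=seed
    )


def recoverable_fraction(
    profile: BiasProfile, depth: float = 20.0, min_depth: float = 3.0
) -> float:
    """Fraction of the genome whose expected read depth reaches ``min_depth``.

    Expected per-base depth is depth * gain / mean(gain); bases below
    ``min_depth`` are considered lost to amplification bias (dropout or
    under-amplification) at this sequencing effort.
    """
    lam = depth * profile.gains / profile.mean_gain()
    ok = lam >= min_depth
    return float(profile.lengths[ok].sum() / profile.genome_length)


def recoverable_mask(
    profile: BiasProfile, depth: float = 20.0, min_depth: float = 3.0
) -> np.ndarray:
    """Per-base boolean recoverability under the same criterion."""
    lam = depth * profile.gains / profile.mean_gain()
    return np.repeat(lam >= min_depth, profile.lengths)


def union_recoverable_fraction(
    profiles: list[BiasProfile], depth: float = 20.0, min_depth: float = 3.0
) -> float:
    """Fraction of the genome recoverable in at least one profile."""
    mask = recoverable_mask(profiles[0], depth, min_depth)
    for p in profiles[1:]:
        mask |= recoverable_mask(p, depth, min_depth)
    return float(mask.mean())


def _sample_positions(
    rng: np.random.Generator, profile: BiasProfile, n: int
) -> np.ndarray:
    """Draw genome positions proportional to per-base amplification gain."""
    w = profile.lengths * profile.gains
    seg = rng.choice(len(w), size=n, p=w / w.sum())
    return profile.starts[seg] + (rng.random(n) * profile.lengths[seg]).astype(np.int64)


def _apply_errors(rng: np.random.Generator, seq: str, p: float) -> str:
    if p <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < p)[0]
    if len(hits) == 0:
        return seq
    lut = {ord(b): [ord(c) for c in "ACGT" if c != b] for b in "ACGT"}
    for i in hits:
        choices = lut.get(arr[i])
        if choices:
            arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def simulate_reads(
    community: CommunitySpec,
    bias: dict[str, BiasProfile],
    n_reads: int,
    model: ReadModel = ReadModel(),
    paired: bool = False,
    seed: int = 0,
    source_label: str = "sample",
    genomes: Optional[dict[str, SequenceRecord]] = None,
) -> SimulatedSample:
    """Simulate a shotgun (or paired-end) dataset with full ground truth.

    Read start positions are drawn proportional to per-base amplification
    gain times genome abundance.  With probability ``model.chimera_rate``
    a read is chimeric: two segments from loci >= 2 kb apart, the second
    reverse-complemented with probability 1/2, junction uniform within
    the read.  With ``paired=True``, ``n_reads`` fragments of span
    ~N(pair_span, sd_span) each yield a /1,/2 read pair (chimeras off in
    paired mode; pair-level artifacts are out of scope).
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)
    if genomes is None:
        genomes = {
            name: simulate_genome(spec) for name, spec in community.specs().items()
        }
    abund = community.abundances()
    names = sorted(abund)
    probs = np.array([abund[n] for n in names])
    for name in names:
        if name not in bias:
            raise ValueError(f"no bias profile for genome {name!r}")
        if abund[name] > 0 and not (bias[name].gains > 0).any():
            raise ValueError(f"all-dropout bias profile for abundant genome {name!r}")

    which = rng.choice(len(names), size=n_reads, p=probs)
    p_err = model.per_base_error()
    reads: list[SequenceRecord] = []
    truth_rows: list[dict] = []
    pairing: dict[str, str] = {}

    def read_len(limit: int) -> int:
        L = int(round(rng.normal(model.mean_len, model.sd_len)))
        return int(np.clip(L, model.min_len, min(model.max_len, limit)))

    def emit(read_id: str, gname: str, start: int, length: int, minus: bool,
             chimera: Optional[dict] = None) -> None:
        g = genomes[gname].bases
        seq = g[start : start + length]
        strand = "-" if minus else "+"
        if minus:
            seq = revcomp(seq)
        row = dict(
            read_id=read_id, genome=gname, start=start, end=start + length,
            strand=strand, is_chimeric=False, genome2=None, start2=-1,
            end2=-1, strand2=None, junction=-1,
        )
        if chimera is not None:
            g2 = genomes[chimera["genome2"]].bases
            seq2 = g2[chimera["start2"] : chimera["end2"]]
            if chimera["strand2"] == "-":
                seq2 = revcomp(seq2)
            row.update(chimera, is_chimeric=True, junction=len(seq))
            seq = seq + seq2
        seq = _apply_errors(rng, seq, p_err)
        qual = np.full(len(seq), model.base_quality, dtype=np.int16)
        reads.append(SequenceRecord(read_id, seq, qual))
        truth_rows.append(row)

    for i in range(n_reads):
        gname = names[which[i]]
        glen = len(genomes[gname].bases)
        prof = bias[gname]
        if paired:
            span = int(np.clip(rng.normal(model.pair_span, model.sd_span),
                               2 * model.min_len, glen))
            frag = int(_sample_positions(rng, prof, 1)[0])
            frag = max(0, min(frag, glen - span))
            l1, l2 = read_len(span // 2), read_len(span // 2)
            minus = bool(rng.random() < 0.5)
            # innie pair: /1 at the left end forward, /2 at the right end reverse
            a = (frag, l1, False) if not minus else (frag + span - l1, l1, True)
            b = (frag + span - l2, l2, True) if not minus else (frag, l2, False)
            id1, id2 = f"{source_label}.{i}/1", f"{source_label}.{i}/2"
            emit(id1, gname, a[0], a[1], a[2])
            emit(id2, gname, b[0], b[1], b[2])
            pairing[id1], pairing[id2] = id2, id1
            continue
        length = read_len(glen)
        chimeric = rng.random() < model.chimera_rate
        if chimeric and glen > 4000 + length and length > model.min_len:
            junction = int(rng.integers(model.min_len // 2, length - model.min_len // 2))
            l1, l2 = junction, length - junction
            for _ in range(100):
                s1 = int(_sample_positions(rng, prof, 1)[0])
                s2 = int(_sample_positions(rng, prof, 1)[0])
                s1 = min(s1, glen - l1)
                s2 = min(s2, glen - l2)
                if abs(s1 - s2) >= 2000 + length:
                    break
            strand2 = "-" if rng.random() < 0.5 else "+"
            emit(
                f"{source_label}.{i}", gname, s1, l1, False,
                chimera=dict(genome2=gname, start2=s2, end2=s2 + l2, strand2=strand2),
            )
        else:
            start = int(_sample_positions(rng, prof, 1)[0])
            start = min(start, glen - length)
            emit(f"{source_label}.{i}", gname, start, length,
                 bool(rng.random() < 0.5))

    truth = pd.DataFrame(truth_rows)
    readset = ReadSet(reads, source_label=source_label, pairing=pairing or None)
    return SimulatedSample(readset, truth, bias, community, genomes)


def attach_barcode(sample: SimulatedSample, barcode: str,
                   quality: int = 30) -> ReadSet:
    """Prepend a sample barcode to every read (for demultiplexing tests)."""
    out = []
    for rec in sample.reads:
        qual = np.concatenate(
            [np.full(len(barcode), quality, dtype=np.int16),
             rec.quality if rec.quality is not None
             else np.full(len(rec.bases), quality, dtype=np.int16)]
        )
        out.append(SequenceRecord(rec.id, barcode + rec.bases, qual))
    return ReadSet(out, source_label=sample.reads.source_label)


def default_community(seed: int = 0) -> CommunitySpec:
    """Desk-scale study community: 200 kb low-GC target (32.4% G+C, with a
    planted composition switch at its midpoint) plus two 100 kb high-GC
    contaminants (58% and 65% G+C), target cell fraction 0.84."""
    target = GenomeSpec("target", 200_000, 0.324, composition_switch=100_000,
                        seed=seed)
    cont1 = GenomeSpec("contamA", 100_000, 0.58, seed=seed + 1)
    cont2 = GenomeSpec("contamB", 100_000, 0.65, seed=seed + 2)
    return CommunitySpec(target, ((cont1, 1.0), (cont2, 1.0)))


def pure_target_community(community: CommunitySpec) -> CommunitySpec:
    """The same target with no contaminants (a sorted single cell)."""
    return replace(community, contaminants=(), target_fraction=1.0)
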