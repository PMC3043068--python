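"""Comparative genome statistics: reciprocal best hits, ANI over
corresponding regions with a floored whole-genome average, per-position
novelty and alignment-depth tracks, microheterogeneity between
single-cell assemblies, and quality-score expected-error budgets.

The whole-genome identity convention: corresponding regions are the
union of *reference* positions covered by accepted hits; the remainder
of the reference is scored at a floor identity (default 25%), giving

    wgi = (ani * corr + floor * (ref_len - corr)) / ref_len.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentHit, KmerIndex, MapCriteria, Scoring, align_to_index
from .assembly import Assembly
from .records import SequenceRecord

#: default hit-acceptance rule for genome-scale ANI / novelty comparisons
ANI_CRITERIA = MapCriteria(min_identity=0.5, min_length=100)


@dataclass
class RBHPair:
    gene_a: str
    gene_b: str
    identity_fwd: float
    identity_rev: float
    coverage_fwd: float  # fraction of the query (gene_a) covered by the forward hit
    coverage_rev: float
    confidence: str  # 'high' iff forward coverage >= the 60% rule

    def __post_init__(self) -> None:
        if self.confidence not in ("high", "low"):
            raise ValueError("confidence must be 'high' or 'low'")


GenePair = tuple[str, str]  # (id, sequence)
Scorer = Callable[[str, str], Optional[tuple[float, float, float]]]
# scorer(query_seq, subject_seq) -> (score, identity, query_coverage) or None


def nucleotide_scorer(scoring: Scoring = Scoring()) -> Scorer:
    """Gene-vs-gene scorer backed by the package's seeded DNA aligner."""

    def score(q: str, s: str) -> Optional[tuple[float, float, float]]:
        hits = align_to_index(
            SequenceRecord("q", q), KmerIndex([SequenceRecord("s", s)]), scoring
        )
        if not hits:
            return None
        h = max(hits, key=lambda x: x.score)
        return h.score, h.identity, (h.q_end - h.q_start) / len(q)

    return score


def protein_scorer(open_gap: float = -11.0, extend_gap: float = -1.0) -> Scorer:
    """BLOSUM62 local protein scorer (Biopython backend) satisfying the
    shared aligner contract."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap

    def score(q: str, s: str) -> Optional[tuple[float, float, float]]:
        try:
            aln = aligner.align(q, s)
        except ValueError:
            return None
        if len(aln) == 0:
            return None
        best = aln[0]
        counts = best.counts()
        cols = counts.identities + counts.mismatches + counts.gaps
        if cols == 0:
            return None
        qspan = best.aligned[0][-1][1] - best.aligned[0][0][0]
        return float(best.score), counts.identities / cols, qspan / len(q)

    return score


def _best_partner(
    genes_a: Sequence[GenePair], genes_b: Sequence[GenePair], scorer: Scorer
) -> dict[str, tuple[str, float, float, float]]:
    """Best hit in B for every gene of A: id_a -> (id_b, score, identity,
    coverage); ties broken by lower subject id."""
    out: dict[str, tuple[str, float, float, float]] = {}
    for ida, seqa in genes_a:
        best = None
        for idb, seqb in sorted(genes_b):
            res = scorer(seqa, seqb)
            if res is None:
                continue
            sc, ident, cov = res
            if best is None or sc > best[1]:
                best = (idb, sc, ident, cov)
        if best is not None:
            out[ida] = best
    return out


def rbh(
    genes_a: Sequence[GenePair],
    genes_b: Sequence[GenePair],
    scorer: Optional[Scorer] = None,
    coverage_threshold: float = 0.60,
    protein: bool = False,
) -> list[RBHPair]:
    """Reciprocal best hits between two gene collections.

    A pair is reported iff each gene is the other's highest-scoring
    match; confidence is 'high' iff the forward (A->B) hit covers at
    least ``coverage_threshold`` of the query gene.
    """
    if not genes_a or not genes_b:
        raise ValueError("gene collections must be non-empty")
    if scorer is None:
        scorer = protein_scorer() if protein else nucleotide_scorer()
    fwd = _best_partner(genes_a, genes_b, scorer)
    rev = _best_partner(genes_b, genes_a, scorer)
    pairs = []
    for ida, (idb, _, ident_f, cov_f) in sorted(fwd.items()):
        back = rev.get(idb)
        if back is None or back[0] != ida:
            continue
        _, _, ident_r, cov_r = back
        pairs.append(
            RBHPair(
                gene_a=ida, gene_b=idb,
                identity_fwd=ident_f, identity_rev=ident_r,
                coverage_fwd=cov_f, coverage_rev=cov_r,
                confidence="high" if cov_f >= coverage_threshold else "low",
            )
        )
    return pairs


@dataclass
class ANIReport:
    corresponding_bases: int
    identity_corresponding: float
    reference_length: int
    floor_identity: float = 0.25

    def __post_init__(self) -> None:
        if self.corresponding_bases > self.reference_length:
            raise ValueError("corresponding bases cannot exceed the reference length")

    def to_dict(self) -> dict:
        return {
            "number of bases in corresponding regions": self.corresponding_bases,
            "% identity of corresponding regions": round(100 * self.identity_corresponding, 1),
            "whole genome average % identity": round(100 * whole_genome_identity(self), 1),
        }


def whole_genome_identity(report: ANIReport) -> float:
    """Length-weighted identity over the whole reference, scoring the
    non-corresponding remainder at the floor identity."""
    corr = report.corresponding_bases
    rest = report.reference_length - corr
    return (
        report.identity_corresponding * corr + report.floor_identity * rest
    ) / report.reference_length


def ani_corresponding(
    target: SequenceRecord,
    reference: SequenceRecord,
    criteria: MapCriteria = ANI_CRITERIA,
    scoring: Scoring = Scoring(),
    floor_identity: float = 0.25,
    q_stride: int = 2,
) -> ANIReport:
    """ANI over corresponding regions.

    Corresponding regions are the union of reference positions covered
    by accepted hits; identity is the hit-length-weighted mean.
    """
    if not target.bases or not reference.bases:
        raise ValueError("genomes must be non-empty")
    hits = [
        h
        for h in align_to_index(
            target, KmerIndex([reference]), scoring, q_stride=q_stride
        )
        if h.identity >= criteria.min_identity and h.length >= criteria.min_length
    ]
    covered = np.zeros(len(reference.bases), dtype=bool)
    wsum = isum = 0.0
    for h in hits:
        covered[h.s_start : h.s_end] = True
        wsum += h.length
        isum += h.length * h.identity
    corr = int(covered.sum())
    ident = isum / wsum if wsum else 0.0
    return ANIReport(corr, ident, len(reference.bases), floor_identity)


@dataclass
class NoveltyTrack:
    """Per-position novelty over the target: R minus the summed best-hit
    identities to R references (2 references by default, range [0, 2]);
    positions with no hit to any reference score the full R."""

    values: np.ndarray
    depth: np.ndarray  # number of accepted hits covering each position
    references: list

    def __post_init__(self) -> None:
        r = len(self.references)
        if ((self.values < 0) | (self.values > r)).any():
            raise ValueError(f"novelty values must lie in [0, {r}]")


def novelty_track(
    target: SequenceRecord,
    references: Sequence[SequenceRecord],
    criteria: MapCriteria = ANI_CRITERIA,
    scoring: Scoring = Scoring(),
    q_stride: int = 2,
) -> NoveltyTrack:
    """Sequence novelty index along the target genome.

    For each reference, each target position takes the identity of the
    best accepted hit covering it (0 if none); novelty = R - sum over
    the R references.  The depth track counts all accepted hits covering
    each position.
    """
    if not references:
        raise ValueError("need at least one reference")
    L = len(target.bases)
    best = np.zeros((len(references), L))
    depth = np.zeros(L, dtype=np.int32)
    for ri, ref in enumerate(references):
        hits = [
            h
            for h in align_to_index(
                target, KmerIndex([ref]), scoring, q_stride=q_stride
            )
            if h.identity >= criteria.min_identity and h.length >= criteria.min_length
        ]
        for h in hits:
            seg = best[ri, h.q_start : h.q_end]
            np.maximum(seg, h.identity, out=seg)
            depth[h.q_start : h.q_end] += 1
    values = len(references) - best.sum(axis=0)
    return NoveltyTrack(values, depth, [r.id for r in references])


def microheterogeneity(
    assemblies: Sequence[Assembly],
    labels: Optional[Sequence[str]] = None,
    criteria: MapCriteria = MapCriteria(min_identity=0.9, min_length=100),
    scoring: Scoring = Scoring(),
    q_stride: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise ANI and SNP rate between assemblies of different cells.

    For each assembly pair the contigs of one are aligned to the other;
    accepted best-hit regions give a length-weighted identity, a
    substitution count (gap columns excluded from SNPs, reported
    separately) and SNPs per aligned megabase.

    Returns (ANI matrix, long-format detail table).
    """
    if len(assemblies) < 2:
        raise ValueError("need at least two assemblies")
    labels = list(labels) if labels else [f"asm{i}" for i in range(len(assemblies))]
    ani = pd.DataFrame(np.ones((len(assemblies), len(assemblies))), index=labels, columns=labels)
    rows = []
    for i in range(len(assemblies)):
        for j in range(i + 1, len(assemblies)):
            refs = [SequenceRecord(c.id, c.bases) for c in assemblies[j].contigs]
            index = KmerIndex(refs)
            cols = matches = snps = gapcols = 0
            for c in assemblies[i].contigs:
                hits = [
                    h
                    for h in align_to_index(
                        SequenceRecord(c.id, c.bases), index, scoring, q_stride=q_stride
                    )
                    if h.identity >= criteria.min_identity
                    and h.length >= criteria.min_length
                ]
                for h in hits:
                    cols += h.length
                    matches += round(h.identity * h.length)
                    snps += h.mismatches
                    gapcols += h.gaps
            pair_ani = matches / cols if cols else float("nan")
            snp_per_mb = 1e6 * snps / cols if cols else float("nan")
            ani.loc[labels[i], labels[j]] = pair_ani
            ani.loc[labels[j], labels[i]] = pair_ani
            rows.append(
                dict(a=labels[i], b=labels[j], aligned_bases=cols, ani=pair_ani,
                     snps=snps, snps_per_mb=snp_per_mb, gap_columns=gapcols)
            )
    return ani, pd.DataFrame(rows)


@dataclass
class ErrorBudget:
    """Expected consensus errors from base qualities plus the MDA
    polymerase contribution (reported separately)."""

    n_low_quality_bases: int
    n_high_quality_bases: int
    assumed_q_low: float = 10.0
    assumed_q_high: float = 40.0
    expected_errors_two_tier: float = 0.0
    expected_errors_exact: Optional[float] = None
    mda_error_rate: float = 1e-5
    mda_expected_errors: Optional[float] = None

    def __post_init__(self) -> None:
        if self.expected_errors_two_tier < 0:
            raise ValueError("expected errors must be nonnegative")


def phred_error_prob(q) -> np.ndarray:
    return 10.0 ** (-np.asarray(q, dtype=float) / 10.0)


def expected_errors(
    n_low_quality_bases: int,
    n_high_quality_bases: int,
    assumed_q_low: float = 10.0,
    assumed_q_high: float = 40.0,
    quality_scores: Optional[np.ndarray] = None,
    mda_error_rate: float = 1e-5,
    genome_length: Optional[int] = None,
) -> ErrorBudget:
    """Expected error counts in an assembly.

    Two-tier estimate: n_low * 10^(-q_low/10) + n_high * 10^(-q_high/10).
    The exact estimate (when full per-base qualities are given) is the
    sum of per-base error probabilities.  The MDA polymerase term is
    mda_error_rate * genome_length, reported separately.
    """
    if n_low_quality_bases < 0 or n_high_quality_bases < 0:
        raise ValueError("counts must be nonnegative")
    two_tier = float(
        n_low_quality_bases * 10.0 ** (-assumed_q_low / 10.0)
        + n_high_quality_bases * 10.0 ** (-assumed_q_high / 10.0)
    )
    exact = None
    if quality_scores is not None:
        exact = float(phred_error_prob(quality_scores).sum())
    mda = None
    if genome_length is not None:
        mda = float(mda_error_rate * genome_length)
    return ErrorBudget(
        n_low_quality_bases=n_low_quality_bases,
        n_high_quality_bases=n_high_quality_bases,
        assumed_q_low=assumed_q_low,
        assumed_q_high=assumed_q_high,
        expected_errors_two_tier=two_tier,
        expected_errors_exact=exact,
        mda_error_rate=mda_error_rate,
        mda_expected_errors=mda,
    )


def write_rbh_tsv(pairs: Sequence[RBHPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("# gene_a\tgene_b\tidentity_fwd\tidentity_rev\tcoverage_fwd\tconfidence\n")
        for p in pairs:
            fh.write(
                f"{p.gene_a}\t{p.gene_b}\t{p.identity_fwd:.4f}\t"
                f"{p.identity_rev:.4f}\t{p.coverage_fwd:.3f}\t{p.confidence}\n"
            )
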