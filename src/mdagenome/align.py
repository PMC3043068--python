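"""Seeded local pairwise alignment and read mapping.

The aligner is k-mer seeded (default k = 11).  Seeds shared between
query and subject are grouped by diagonal; isolated diagonals are scored
by an exact vectorised maximal-scoring-segment scan (gapless), and
clusters of nearby diagonals on short sequences are resolved by a banded
affine-gap Smith-Waterman restricted to the cluster's diagonals.  Long
sequences (contig-vs-genome comparisons) use the gapless path only,
which is exact for the substitution-dominated data this package targets.

Scoring defaults are megablast-like (+2 match, -3 mismatch, gap open 5,
extend 2) — the high-identity regime of read mapping at a 90%-identity /
40-base acceptance rule.  Identity is matches / alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .records import ReadSet, SequenceRecord

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode bases as uint8 codes A=0 C=1 G=2 T=3, anything else 4 (N)."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def encode_revcomp(codes: np.ndarray) -> np.ndarray:
    out = np.where(codes < 4, 3 - codes, np.uint8(4)).astype(np.uint8)
    return out[::-1]


@dataclass(frozen=True)
class Scoring:
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5  # cost of opening a gap (first gapped base costs open+extend)
    gap_extend: int = 2
    min_score: int = 30  # floor below which hits are not reported


@dataclass(frozen=True)
class MapCriteria:
    """Read-mapping acceptance rule: 90% identity over 40 bases by default."""

    min_identity: float = 0.90
    min_length: int = 40

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_length < 1:
            raise ValueError("min_length must be positive")


@dataclass
class AlignmentHit:
    """A local alignment; coordinates are 0-based half-open on the
    forward strand of both sequences.  ``strand`` is '-' when the query's
    reverse complement aligns to the subject forward strand."""

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    identity: float
    score: float
    length: int  # alignment columns
    mismatches: int = 0
    gaps: int = 0

    def __post_init__(self) -> None:
        if not (self.q_start < self.q_end and self.s_start < self.s_end):
            raise ValueError("hit intervals must be non-empty")
        if not (0 <= self.identity <= 1):
            raise ValueError("identity must be in [0, 1]")


@dataclass
class ChimeraCall:
    read_id: str
    is_chimeric: bool
    evidence: tuple[AlignmentHit, ...] = ()

    def __post_init__(self) -> None:
        if self.is_chimeric != bool(self.evidence):
            raise ValueError("evidence must be present iff is_chimeric")


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of every k-mer window; windows containing N get -1."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    vals = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    c = codes.astype(np.int64)
    for i in range(k):
        win = c[i : i + n]
        vals = vals * 4 + np.where(win < 4, win, 0)
        bad |= win >= 4
    vals[bad] = -1
    return vals


class KmerIndex:
    """Exact k-mer index over a collection of subject sequences."""

    def __init__(self, subjects: Sequence[SequenceRecord], k: int = 11):
        self.k = k
        self.subjects = list(subjects)
        self.codes = [encode(s.bases) for s in self.subjects]
        self.ids = [s.id for s in self.subjects]
        self._table: dict[int, list[tuple[int, int]]] = {}
        for si, codes in enumerate(self.codes):
            for pos, val in enumerate(_kmer_codes(codes, k)):
                if val >= 0:
                    self._table.setdefault(int(val), []).append((si, pos))

    def lookup(self, val: int) -> list[tuple[int, int]]:
        return self._table.get(val, ())


def _best_segment(scores: np.ndarray) -> tuple[int, int, float]:
    """Maximal-scoring contiguous segment (Kadane via prefix minima).

    Returns (start, end, score) with end exclusive; empty segment -> score 0.
    """
    pre = np.concatenate([[0.0], np.cumsum(scores)])
    run_min = np.minimum.accumulate(pre[:-1])
    gains = pre[1:] - run_min
    j = int(np.argmax(gains))
    best = float(gains[j])
    if best <= 0:
        return 0, 0, 0.0
    i = int(np.argmin(pre[: j + 1]))
    return i, j + 1, best


def _gapless_hit(
    q: np.ndarray, s: np.ndarray, diag: int, scoring: Scoring,
    q_window: Optional[tuple[int, int]] = None,
) -> Optional[tuple[int, int, float, int, int]]:
    """Best gapless segment along one diagonal (s_pos = q_pos + diag).

    ``q_window`` optionally restricts the scan to a query interval
    (used to bound work around the seed extent on long sequences).
    Returns (q_start, q_end, score, matches, length) or None.
    """
    q_lo = max(0, -diag)
    q_hi = min(len(q), len(s) - diag)
    if q_window is not None:
        q_lo = max(q_lo, q_window[0])
        q_hi = min(q_hi, q_window[1])
    if q_hi - q_lo < 1:
        return None
    qs = q[q_lo:q_hi]
    ss = s[q_lo + diag : q_hi + diag]
    match = (qs == ss) & (qs < 4)
    scores = np.where(match, float(scoring.match), float(scoring.mismatch))
    i, j, sc = _best_segment(scores)
    if j <= i:
        return None
    m = int(match[i:j].sum())
    return q_lo + i, q_lo + j, sc, m, j - i


def _banded_sw(
    q: np.ndarray, s: np.ndarray, d_lo: int, d_hi: int, scoring: Scoring
) -> Optional[tuple[int, int, int, int, float, int, int, int]]:
    """Affine-gap Smith-Waterman restricted to diagonals [d_lo, d_hi].

    Returns (q_start, q_end, s_start, s_end, score, matches, columns,
    gap_columns) for the best local path, or None.  Plain-Python row
    scan: intended for short sequences (cluster resolution and oracle
    parity tests), not bulk mapping.
    """
    m, n = len(q), len(s)
    width = d_hi - d_lo + 1
    if width <= 0:
        return None
    NEG = -1e9
    go, ge = scoring.gap_open + scoring.gap_extend, scoring.gap_extend
    H = [0.0] * width
    E = [NEG] * width
    F = [NEG] * width
    ptr = np.zeros((m + 1, width), dtype=np.uint8)  # 0 stop 1 diag 2 up 3 left
    eptr = np.zeros((m + 1, width), dtype=bool)  # E extended from E
    fptr = np.zeros((m + 1, width), dtype=bool)
    best, best_cell = 0.0, None
    for i in range(1, m + 1):
        Hp, Fp = H, F
        H, E, F = [0.0] * width, [NEG] * width, [NEG] * width
        qc = q[i - 1]
        for w in range(width):
            j = i + d_lo + w
            if j < 1 or j > n:
                H[w] = 0.0 if 0 <= j <= n else NEG
                continue
            subst = (
                scoring.match
                if (qc == s[j - 1] and qc < 4)
                else scoring.mismatch
            )
            diag = Hp[w] + subst  # (i-1, j-1) is same w in previous row
            # up move (gap in subject): from (i-1, j) -> w' = j-(i-1)-d_lo = w+1
            if w + 1 < width:
                f_open = Hp[w + 1] - go
                f_ext = Fp[w + 1] - ge
                F[w] = max(f_open, f_ext)
                fptr[i, w] = f_ext > f_open
            # left move (gap in query): from (i, j-1) -> same row, w-1
            if w - 1 >= 0:
                e_open = H[w - 1] - go
                e_ext = E[w - 1] - ge
                E[w] = max(e_open, e_ext)
                eptr[i, w] = e_ext > e_open
            h = max(0.0, diag, E[w], F[w])
            H[w] = h
            if h == 0:
                ptr[i, w] = 0
            elif h == diag:
                ptr[i, w] = 1
            elif h == F[w]:
                ptr[i, w] = 2
            else:
                ptr[i, w] = 3
            if h > best:
                best, best_cell = h, (i, w)
    if best_cell is None or best < scoring.min_score:
        return None
    # traceback
    i, w = best_cell
    q_end = i
    s_end = i + d_lo + w
    matches = cols = gapcols = 0
    state = 0  # 0 in H
    while i > 0:
        code = ptr[i, w]
        if state == 0:
            if code == 0:
                break
            if code == 1:
                j = i + d_lo + w
                cols += 1
                if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                    matches += 1
                i -= 1
            elif code == 2:
                state = 2
            else:
                state = 3
        elif state == 2:  # F: up moves
            cols += 1
            gapcols += 1
            ext = fptr[i, w]
            i -= 1
            w += 1
            if not ext:
                state = 0
        else:  # E: left moves
            cols += 1
            gapcols += 1
            ext = eptr[i, w]
            w -= 1
            if not ext:
                state = 0
    q_start = i
    s_start = i + d_lo + w
    return q_start, q_end, s_start, s_end, best, matches, cols, gapcols


def _cluster_diagonals(
    extents: dict[int, list[int]], gap: int
) -> list[list[int]]:
    """Group seed diagonals lying within ``gap`` of each other.

    ``extents`` maps diagonal -> [qmin, qmax] seed extent; returns lists
    of member diagonals per cluster.
    """
    ds = sorted(extents)
    clusters: list[list[int]] = [[ds[0]]]
    for d in ds[1:]:
        if d - clusters[-1][-1] <= gap:
            clusters[-1].append(d)
        else:
            clusters.append([d])
    return clusters


def _align_oriented(
    q_codes: np.ndarray,
    query_id: str,
    query_len: int,
    strand: str,
    index: KmerIndex,
    scoring: Scoring,
    q_stride: int,
    diag_gap: int,
    dp_limit: int,
    band_pad: int,
    seed_margin: int,
) -> list[AlignmentHit]:
    k = index.k
    kcodes = _kmer_codes(q_codes, k)
    if len(kcodes) == 0:
        return []
    per_subject: dict[int, dict[int, list[int]]] = {}
    for qpos in range(0, len(kcodes), q_stride):
        val = kcodes[qpos]
        if val < 0:
            continue
        for si, spos in index.lookup(int(val)):
            ext = per_subject.setdefault(si, {}).setdefault(spos - qpos, [qpos, qpos])
            if qpos < ext[0]:
                ext[0] = qpos
            if qpos > ext[1]:
                ext[1] = qpos
    hits: list[AlignmentHit] = []
    for si, extents in per_subject.items():
        s_codes = index.codes[si]
        for members in _cluster_diagonals(extents, diag_gap):
            d_lo, d_hi = members[0], members[-1]
            if d_lo != d_hi and max(len(q_codes), len(s_codes)) <= dp_limit:
                res = _banded_sw(
                    q_codes, s_codes, d_lo - band_pad, d_hi + band_pad, scoring
                )
                if res is not None:
                    qs, qe, ss, se, sc, mat, cols, gapcols = res
                    hits.append(
                        _make_hit(query_id, query_len, strand, index.ids[si],
                                  qs, qe, ss, se, sc, mat, cols, gapcols)
                    )
                    continue
            # gapless: score each seed diagonal over a window around its
            # seed extent, keep the best (extension margin `seed_margin`)
            best = None
            for d in members:
                qmin, qmax = extents[d]
                window = (qmin - seed_margin, qmax + k + seed_margin)
                g = _gapless_hit(q_codes, s_codes, d, scoring, q_window=window)
                if g and (best is None or g[2] > best[1][2]):
                    best = (d, g)
            if best is None:
                continue
            d, (qs, qe, sc, mat, length) = best
            if sc < scoring.min_score:
                continue
            hits.append(
                _make_hit(query_id, query_len, strand, index.ids[si],
                          qs, qe, qs + d, qe + d, sc, mat, length, 0)
            )
    return hits


def _make_hit(query_id, query_len, strand, subject_id,
              qs, qe, ss, se, score, matches, cols, gapcols) -> AlignmentHit:
    if strand == "-":
        qs, qe = query_len - qe, query_len - qs
    return AlignmentHit(
        query_id=query_id, subject_id=subject_id,
        q_start=qs, q_end=qe, s_start=ss, s_end=se, strand=strand,
        identity=matches / cols if cols else 0.0, score=score, length=cols,
        mismatches=cols - gapcols - matches, gaps=gapcols,
    )


def _dedupe(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Drop hits whose query interval is mostly inside a better hit on the
    same subject/strand/diagonal neighbourhood."""
    hits = sorted(hits, key=lambda h: (-h.score, h.subject_id, h.s_start))
    kept: list[AlignmentHit] = []
    for h in hits:
        redundant = False
        for g in kept:
            if g.subject_id != h.subject_id or g.strand != h.strand:
                continue
            q_ov = min(g.q_end, h.q_end) - max(g.q_start, h.q_start)
            s_ov = min(g.s_end, h.s_end) - max(g.s_start, h.s_start)
            if q_ov > 0.5 * (h.q_end - h.q_start) and s_ov > 0.5 * (h.s_end - h.s_start):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def align_to_index(
    query: SequenceRecord,
    index: KmerIndex,
    scoring: Scoring = Scoring(),
    q_stride: int = 1,
    diag_gap: int = 16,
    dp_limit: int = 2000,
    band_pad: int = 8,
    seed_margin: int = 2000,
) -> list[AlignmentHit]:
    """All local hits of ``query`` (both strands) against an indexed
    subject collection, best-first."""
    q = encode(query.bases)
    hits = _align_oriented(q, query.id, len(q), "+", index, scoring,
                           q_stride, diag_gap, dp_limit, band_pad, seed_margin)
    hits += _align_oriented(encode_revcomp(q), query.id, len(q), "-", index,
                            scoring, q_stride, diag_gap, dp_limit, band_pad,
                            seed_margin)
    return _dedupe(hits)


def local_align(
    query: SequenceRecord,
    subject: SequenceRecord,
    scoring: Scoring = Scoring(),
    k: int = 11,
    **kwargs,
) -> list[AlignmentHit]:
    """Seeded local alignment of one query against one subject."""
    if not query.bases or not subject.bases:
        raise ValueError("sequences must be non-empty")
    return align_to_index(query, KmerIndex([subject], k=k), scoring, **kwargs)


def _hit_order(h: AlignmentHit) -> tuple:
    return (-h.score, h.subject_id, h.s_start)


def map_reads(
    reads: ReadSet,
    reference: Sequence[SequenceRecord],
    criteria: MapCriteria = MapCriteria(),
    scoring: Scoring = Scoring(),
    index: Optional[KmerIndex] = None,
    q_stride: int = 4,
) -> tuple[dict[str, AlignmentHit], list[str]]:
    """Map reads against a reference; a read maps iff some hit reaches
    ``criteria`` (identity over alignment columns).  Best hit = maximum
    score, ties broken by (lower subject id, lower subject start).

    Returns (read id -> best hit, list of unmapped read ids).
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    if index is None:
        index = KmerIndex(reference)
    mapped: dict[str, AlignmentHit] = {}
    unmapped: list[str] = []
    for rec in reads:
        hits = [
            h
            for h in align_to_index(rec, index, scoring, q_stride=q_stride)
            if h.identity >= criteria.min_identity and h.length >= criteria.min_length
        ]
        if hits:
            mapped[rec.id] = min(hits, key=_hit_order)
        else:
            unmapped.append(rec.id)
    return mapped, unmapped


def flag_chimeras(
    reads: ReadSet,
    reference: Sequence[SequenceRecord],
    criteria: MapCriteria = MapCriteria(),
    scoring: Scoring = Scoring(),
    min_separation: int = 2000,
    full_cover: float = 0.80,
    max_segment_overlap: int = 10,
    index: Optional[KmerIndex] = None,
    q_stride: int = 4,
) -> list[ChimeraCall]:
    """Split-alignment chimera detection.

    A read is chimeric iff no single hit covers >= ``full_cover`` of the
    read AND two query-disjoint segments (each meeting ``criteria``) map
    to loci on the same subject more than ``min_separation`` apart or
    with inconsistent strands.  Split hits landing on *different*
    subjects are not called (they may simply span a reference gap).
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    if index is None:
        index = KmerIndex(reference)
    calls: list[ChimeraCall] = []
    for rec in reads:
        hits = [
            h
            for h in align_to_index(rec, index, scoring, q_stride=q_stride)
            if h.identity >= criteria.min_identity and h.length >= criteria.min_length
        ]
        L = len(rec.bases)
        if any(h.q_end - h.q_start >= full_cover * L for h in hits):
            calls.append(ChimeraCall(rec.id, False))
            continue
        evidence = None
        for i in range(len(hits)):
            for j in range(i + 1, len(hits)):
                a, b = hits[i], hits[j]
                ov = min(a.q_end, b.q_end) - max(a.q_start, b.q_start)
                if ov > max_segment_overlap:
                    continue
                if a.subject_id != b.subject_id:
                    continue
                gap = max(a.s_start, b.s_start) - min(a.s_end, b.s_end)
                if a.strand != b.strand or gap > min_separation:
                    evidence = (a, b)
                    break
            if evidence:
                break
        if evidence:
            calls.append(ChimeraCall(rec.id, True, evidence))
        else:
            calls.append(ChimeraCall(rec.id, False))
    return calls


def write_hits_tsv(hits: Sequence[AlignmentHit], path) -> None:
    """Export hits in BLAST outfmt-6 column order (1-based inclusive
    subject/query coordinates, E-value column emitted as NA)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.subject_id, f"{100 * h.identity:.2f}",
                        h.length, h.mismatches, h.gaps,
                        h.q_start + 1, h.q_end, h.s_start + 1, h.s_end,
                        "NA", f"{h.score:.1f}",
                    )
                )
                + "\n"
            )
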