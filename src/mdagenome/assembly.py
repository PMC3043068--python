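"""Contig shredding, a built-in greedy assembler, paired-end
scaffolding, assembly statistics, and rarefaction genome-size
estimation.

The assembler is a *contract*: any callable ``reads -> Assembly`` can be
plugged into rarefaction and the consensus pipeline.  The built-in
greedy assembler exists so every downstream stage is testable
hermetically: it merges the highest-scoring suffix-prefix overlaps
(both strands, gapless, substitution-tolerant) and takes a
majority-vote consensus.  It is deterministic: reads are first
canonically ordered by (length desc, id), so shuffled input yields an
identical contig set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import warnings

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .align import KmerIndex, MapCriteria, Scoring, encode, encode_revcomp, map_reads, _kmer_codes
from .records import ReadSet, SequenceRecord, revcomp

_DECODE = np.array(list("ACGTN"))


@dataclass
class Contig:
    id: str
    bases: str
    member_reads: list = field(default_factory=list)  # (read_id, offset, strand)
    per_base_quality: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("contig bases must be non-empty")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class Scaffold:
    """Ordered, oriented contigs with estimated gaps between neighbours."""

    id: str
    members: list  # [(contig_id, orientation '+'/'-')]
    gaps: list  # len(members) - 1 estimated gap sizes (may be negative)

    def __post_init__(self) -> None:
        if len(self.gaps) != max(0, len(self.members) - 1):
            raise ValueError("need one gap estimate per adjacent contig pair")
        for _, o in self.members:
            if o not in "+-":
                raise ValueError("orientation must be + or -")


@dataclass
class Assembly:
    contigs: list
    scaffolds: list = field(default_factory=list)

    def __post_init__(self) -> None:
        by_id = self.contig_by_id()
        if len(by_id) != len(self.contigs):
            raise ValueError("duplicate contig ids")
        for sc in self.scaffolds:
            for cid, _ in sc.members:
                if cid not in by_id:
                    raise ValueError(f"scaffold {sc.id} references unknown contig {cid}")

    def contig_by_id(self) -> dict[str, Contig]:
        return {c.id: c for c in self.contigs}

    @property
    def scaffolded_ids(self) -> set[str]:
        return {cid for sc in self.scaffolds for cid, _ in sc.members}

    @property
    def unscaffolded(self) -> list[str]:
        inside = self.scaffolded_ids
        return [c.id for c in self.contigs if c.id not in inside]

    def total_contig_bases(self) -> int:
        return sum(len(c) for c in self.contigs)

    def scaffold_length(self, sc: Scaffold) -> int:
        by_id = self.contig_by_id()
        bases = sum(len(by_id[cid]) for cid, _ in sc.members)
        return bases + sum(max(0, int(round(g))) for g in sc.gaps)


@dataclass
class AssemblyStats:
    n_elements: int
    n_scaffolds: int
    scaffold_bases: int
    contig_bases: int
    scaffold_n50: int
    contig_n50: int
    largest_scaffold: int
    largest_contig: int
    unscaffolded_contigs: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class ShredParams:
    """550-mers with 50-base overlaps by default."""

    k: int = 550
    overlap: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.overlap < self.k):
            raise ValueError("need 0 < overlap < k")


@dataclass
class RarefactionCurve:
    points: list  # (n_reads, fraction, replicate, assembly_bases)
    asymptote: Optional[float]  # fitted genome size G, None if the fit failed
    kappa: Optional[float]
    residual: Optional[float]
    model: str = "exponential"

    @property
    def ok(self) -> bool:
        return self.asymptote is not None

    def completeness(self, assembly_bases: float) -> Optional[float]:
        if not self.ok:
            return None
        return assembly_bases / self.asymptote


def shred_contigs(contigs: Sequence[Contig], params: ShredParams = ShredParams()) -> ReadSet:
    """Cut contigs into overlapping pseudo-reads.

    Windows start at 0, step, 2*step (step = k - overlap); a final
    window that would overrun is shifted left to end exactly at the
    contig end, guaranteeing full coverage.  Contigs shorter than k
    yield one pseudo-read equal to the whole contig.  Pseudo-read ids
    encode source contig and offset.
    """
    step = params.k - params.overlap
    out = []
    for contig in contigs:
        L = len(contig)
        if L <= params.k:
            out.append(SequenceRecord(f"{contig.id}:0", contig.bases))
            continue
        starts = list(range(0, L - params.k + 1, step))
        if starts[-1] + params.k < L:
            starts.append(L - params.k)
        for s in starts:
            out.append(SequenceRecord(f"{contig.id}:{s}", contig.bases[s : s + params.k]))
    return ReadSet(out, source_label="pseudo_reads")


class _Buffer:
    """Growable uint8 sequence buffer (amortised appends)."""

    def __init__(self, init: np.ndarray):
        self.data = np.empty(max(4096, 2 * len(init)), dtype=np.uint8)
        self.n = len(init)
        self.data[: self.n] = init

    def append(self, arr: np.ndarray) -> None:
        need = self.n + len(arr)
        if need > len(self.data):
            grown = np.empty(max(need, 2 * len(self.data)), dtype=np.uint8)
            grown[: self.n] = self.data[: self.n]
            self.data = grown
        self.data[self.n : need] = arr
        self.n = need

    def view(self) -> np.ndarray:
        return self.data[: self.n]


def greedy_assemble(
    reads: ReadSet,
    min_overlap: int = 40,
    min_overlap_identity: float = 0.97,
    k: int = 21,
    index_stride: int = 8,
    scoring: Scoring = Scoring(),
) -> Assembly:
    """Greedy overlap assembly with majority-vote consensus.

    Contigs are grown from unused reads in canonical order: at each
    step all reads sharing an exact k-mer with the contig end are
    evaluated by gapless overlap (score = +2 match / -3 mismatch);
    contained reads are absorbed, and the highest-scoring extending
    overlap (ties: larger overlap, then lexicographic id) extends the
    contig.  Both strands are considered.  Consensus is a per-column
    majority vote over all placed reads (ties resolved alphabetically).
    """
    if len(reads) == 0:
        raise ValueError("reads must be non-empty")
    order = sorted(range(len(reads)), key=lambda i: (-len(reads.reads[i]), reads.reads[i].id))
    recs = [reads.reads[i] for i in order]
    n = len(recs)
    fwd = [encode(r.bases) for r in recs]
    rev = [encode_revcomp(f) for f in fwd]
    lens = np.array([len(f) for f in fwd])
    max_len = int(lens.max())

    # index sampled k-mers of every read, both orientations
    table: dict[int, list[tuple[int, int, int]]] = {}
    for i in range(n):
        for oi, codes in ((0, fwd[i]), (1, rev[i])):
            kc = _kmer_codes(codes, k)
            for p in range(0, len(kc), index_stride):
                v = kc[p]
                if v >= 0:
                    table.setdefault(int(v), []).append((i, p, oi))

    used = np.zeros(n, dtype=bool)
    min_id = min_overlap_identity
    contigs: list[Contig] = []

    def evaluate(working: np.ndarray, i: int, off: int, oi: int) -> Optional[tuple]:
        """Score read i at contig offset ``off`` (may be negative or
        beyond the end).  Returns (score, overlap_len, matches) or None."""
        L = len(working)
        rl = int(lens[i])
        a = max(0, off)
        b = min(L, off + rl)
        ov = b - a
        if ov < min(min_overlap, rl):
            return None
        rcodes = (rev[i] if oi else fwd[i])[a - off : b - off]
        wseg = working[a:b]
        matches = int(((rcodes == wseg) & (rcodes < 4)).sum())
        if matches < min_id * ov:
            return None
        score = scoring.match * matches + scoring.mismatch * (ov - matches)
        return score, ov, matches

    def extend_right(buf: _Buffer, placements: list) -> None:
        failed: set[tuple[int, int, int]] = set()
        while True:
            working = buf.view()
            L = len(working)
            w0 = max(0, L - (max_len + k))
            window = working[w0:]
            kc = _kmer_codes(window, k)
            cands: dict[tuple[int, int, int], None] = {}
            for wp in range(len(kc)):
                v = kc[wp]
                if v < 0:
                    continue
                for (i, p, oi) in table.get(int(v), ()):
                    if used[i]:
                        continue
                    off = w0 + wp - p
                    cands[(i, off, oi)] = None
            best = None
            for (i, off, oi) in cands:
                if (i, off, oi) in failed:
                    continue
                res = evaluate(working, i, off, oi)
                if res is None:
                    # a partial-overlap failure may still succeed once the
                    # contig grows past the read; only cache final verdicts
                    if off + lens[i] <= L:
                        failed.add((i, off, oi))
                    continue
                score, ov, _ = res
                if off + lens[i] <= L:
                    # contained: absorb immediately
                    used[i] = True
                    placements.append((i, off, oi))
                    continue
                if best is None:
                    best = (score, ov, i, off, oi)
                else:
                    bscore, bov, bi, _, _ = best
                    if (score, ov) > (bscore, bov) or (
                        (score, ov) == (bscore, bov) and recs[i].id < recs[bi].id
                    ):
                        best = (score, ov, i, off, oi)
            if best is None:
                return
            _, _, i, off, oi = best
            used[i] = True
            placements.append((i, off, oi))
            tail = (rev[i] if oi else fwd[i])[len(buf.view()) - off :]
            buf.append(tail)

    serial = 0
    for seed in range(n):
        if used[seed]:
            continue
        used[seed] = True
        buf = _Buffer(fwd[seed])
        placements = [(seed, 0, 0)]
        extend_right(buf, placements)
        # extend left: reverse-complement the contig, extend right, flip back
        L = buf.n
        buf2 = _Buffer(encode_revcomp(buf.view()))
        placements = [(i, L - (off + int(lens[i])), 1 - oi) for (i, off, oi) in placements]
        extend_right(buf2, placements)
        L2 = buf2.n
        working = encode_revcomp(buf2.view())
        placements = [(i, L2 - (off + int(lens[i])), 1 - oi) for (i, off, oi) in placements]
        # majority-vote consensus
        counts = np.zeros((L2, 4), dtype=np.int32)
        for (i, off, oi) in placements:
            codes = rev[i] if oi else fwd[i]
            a = max(0, off)
            b = min(L2, off + len(codes))
            seg = codes[a - off : b - off]
            ok = seg < 4
            idx = np.arange(a, b)[ok]
            np.add.at(counts, (idx, seg[ok].astype(np.int64)), 1)
        covered = counts.sum(axis=1) > 0
        cons = np.where(covered, np.argmax(counts, axis=1), working.astype(np.int64))
        bases = "".join(_DECODE[cons])
        members = [
            (recs[i].id, int(off), "-" if oi else "+") for (i, off, oi) in placements
        ]
        contigs.append(Contig(f"ctg{serial:05d}", bases, member_reads=members))
        serial += 1
    return Assembly(contigs=contigs, scaffolds=[])


def scaffold_with_pairs(
    assembly: Assembly,
    pairs: ReadSet,
    criteria: MapCriteria = MapCriteria(),
    lib_span: float = 3000.0,
    lib_sd: float = 300.0,
    min_links: int = 3,
) -> Assembly:
    """Link contigs with consistent paired-end evidence into scaffolds.

    Two contig ends are linked when >= ``min_links`` pairs map across
    them with consistent orientation and an implied gap within 3
    library standard deviations of plausibility (gap in
    [-3*lib_sd, lib_span + 3*lib_sd]).  Conflicting bundles are resolved
    by majority (most supporting pairs); cycles are broken at the
    weakest link.  Gap estimates are bundle means.
    """
    if not pairs.pairing:
        raise ValueError("pairs ReadSet must carry pairing")
    if not assembly.contigs:
        return assembly
    refs = [SequenceRecord(c.id, c.bases) for c in assembly.contigs]
    index = KmerIndex(refs)
    mapped, _ = map_reads(pairs, refs, criteria, index=index)
    lengths = {c.id: len(c) for c in assembly.contigs}

    bundles: dict[tuple, list[float]] = {}
    done = set()
    for rid, mate in pairs.pairing.items():
        if rid in done or mate in done:
            continue
        done.add(rid)
        done.add(mate)
        ha, hb = mapped.get(rid), mapped.get(mate)
        if ha is None or hb is None or ha.subject_id == hb.subject_id:
            continue
        # each mate points toward its partner: '+' faces the right end
        da = lengths[ha.subject_id] - ha.s_start if ha.strand == "+" else ha.s_end
        db = lengths[hb.subject_id] - hb.s_start if hb.strand == "+" else hb.s_end
        side_a = "R" if ha.strand == "+" else "L"
        side_b = "R" if hb.strand == "+" else "L"
        gap = lib_span - da - db
        if not (-3 * lib_sd <= gap <= lib_span + 3 * lib_sd):
            continue
        key_fwd = (ha.subject_id, side_a, hb.subject_id, side_b)
        key_rev = (hb.subject_id, side_b, ha.subject_id, side_a)
        key = min(key_fwd, key_rev)
        bundles.setdefault(key, []).append(gap)

    links = [
        (len(gaps), key, float(np.mean(gaps)))
        for key, gaps in bundles.items()
        if len(gaps) >= min_links
    ]
    links.sort(key=lambda t: (-t[0], t[1]))  # strongest first, then deterministic

    # accept links greedily; each contig end is used at most once and
    # accepting a link that closes a cycle is refused (weakest links lose)
    end_used: set[tuple[str, str]] = set()
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    accepted = []
    for count, (a, sa, b, sb), gap in links:
        if (a, sa) in end_used or (b, sb) in end_used:
            continue
        ra, rb = find(a), find(b)
        if ra == rb:
            continue  # would close a cycle
        parent[ra] = rb
        end_used.add((a, sa))
        end_used.add((b, sb))
        accepted.append((a, sa, b, sb, gap, count))

    # build chains from accepted links
    adj: dict[str, dict[str, tuple]] = {}
    for a, sa, b, sb, gap, count in accepted:
        adj.setdefault(a, {})[sa] = (b, sb, gap)
        adj.setdefault(b, {})[sb] = (a, sa, gap)

    visited = set()
    scaffolds = []
    serial = 0
    for c in assembly.contigs:
        if c.id in visited or c.id not in adj:
            continue
        # walk to the chain's end
        cur, arrive = c.id, None
        while True:
            sides = [s for s in adj[cur] if s != arrive]
            if not sides:
                break
            nxt, nside, _ = adj[cur][sides[0]]
            if nxt in (c.id,):
                break
            prev, arrive, cur = cur, nside, nxt
            if cur == c.id:
                break
            if len(adj.get(cur, {})) < 2:
                break
        # now traverse from `cur` (an endpoint) through the chain
        start = cur
        members, gaps = [], []
        arrive = None
        orient = None
        while True:
            visited.add(cur)
            sides = [s for s in adj.get(cur, {}) if s != arrive]
            if orient is None:
                # first contig: oriented + if it exits via its right end
                exit_side = sides[0] if sides else "R"
                orient = "+" if exit_side == "R" else "-"
            members.append((cur, orient))
            if not sides:
                break
            nxt, nside, gap = adj[cur][sides[0]]
            gaps.append(gap)
            # entering the next contig at side `nside`: oriented + if entered from left
            orient = "+" if nside == "L" else "-"
            arrive, cur = nside, nxt
            if cur in visited:
                members.append((cur, orient))
                break
        if len(members) >= 2:
            scaffolds.append(Scaffold(f"scaffold{serial:03d}", members, gaps))
            serial += 1
    return Assembly(contigs=assembly.contigs, scaffolds=scaffolds)


def _n50(lengths: Sequence[int]) -> int:
    if not lengths:
        return 0
    arr = sorted(lengths, reverse=True)
    half = sum(arr) / 2
    acc = 0
    for x in arr:
        acc += x
        if acc >= half:
            return x
    return arr[-1]


def assembly_stats(assembly: Assembly) -> AssemblyStats:
    """Summary statistics; scaffold lengths include estimated gaps, the
    element count is scaffolds plus unscaffolded contigs."""
    contig_lens = [len(c) for c in assembly.contigs]
    scaf_lens = [assembly.scaffold_length(sc) for sc in assembly.scaffolds]
    unscaf = assembly.unscaffolded
    return AssemblyStats(
        n_elements=len(assembly.scaffolds) + len(unscaf),
        n_scaffolds=len(assembly.scaffolds),
        scaffold_bases=sum(scaf_lens),
        contig_bases=sum(contig_lens),
        scaffold_n50=_n50(scaf_lens),
        contig_n50=_n50(contig_lens),
        largest_scaffold=max(scaf_lens, default=0),
        largest_contig=max(contig_lens, default=0),
        unscaffolded_contigs=len(unscaf),
    )


def _exp_model(d, G, kappa):
    return G * (1.0 - np.exp(-d / kappa))


def _mm_model(d, G, kappa):
    return G * d / (kappa + d)


def rarefy_and_fit(
    reads: ReadSet,
    fractions: Sequence[float] = (0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0),
    replicates: int = 2,
    assembler: Callable[[ReadSet], Assembly] = greedy_assemble,
    seed: int = 0,
    model: str = "exponential",
) -> RarefactionCurve:
    """Assemble nested subsamples and fit a saturating genome-size model.

    For each (fraction, replicate) the reads are subsampled without
    replacement (seeded per cell), assembled, and the total assembly
    bases recorded.  The curve S(d) = G * (1 - exp(-d / kappa))
    (or the Michaelis-Menten form G * d / (kappa + d)) is fit by least
    squares over read counts d; G estimates the genome size.
    """
    fr = list(fractions)
    if fr != sorted(fr) or not all(0 < f <= 1 for f in fr):
        raise ValueError("fractions must be sorted and within (0, 1]")
    fn = _exp_model if model == "exponential" else _mm_model
    N = len(reads)
    points = []
    for fi, f in enumerate(fr):
        reps = 1 if f >= 1.0 else replicates
        for r in range(reps):
            rng = np.random.default_rng([seed, fi, r])
            m = max(1, int(round(f * N)))
            idx = rng.choice(N, size=m, replace=False) if m < N else np.arange(N)
            sub = ReadSet([reads.reads[i] for i in sorted(idx)],
                          source_label=f"{reads.source_label}:f{f}:r{r}")
            bases = assembler(sub).total_contig_bases()
            points.append((m, f, r, bases))
    d = np.array([p[0] for p in points], dtype=float)
    S = np.array([p[3] for p in points], dtype=float)
    try:
        G0 = float(S.max()) * 1.1
        k0 = max(float(d.max()) / 4, 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(fn, d, S, p0=[G0, k0], maxfev=20000)
        G, kappa = float(popt[0]), float(popt[1])
        resid = float(np.sqrt(np.mean((fn(d, *popt) - S) ** 2)))
        if G <= 0 or not np.isfinite(G):
            raise RuntimeError("non-saturating fit")
    except (RuntimeError, ValueError):
        return RarefactionCurve(points, None, None, None, model=model)
    return RarefactionCurve(points, G, kappa, resid, model=model)


def fit_rarefaction_points(
    d: Sequence[float], S: Sequence[float], model: str = "exponential"
) -> RarefactionCurve:
    """Fit the saturating model to pre-computed (read count, bases) points."""
    fn = _exp_model if model == "exponential" else _mm_model
    d = np.asarray(d, dtype=float)
    S = np.asarray(S, dtype=float)
    points = [(int(di), float("nan"), 0, float(si)) for di, si in zip(d, S)]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(fn, d, S, p0=[float(S.max()) * 1.1 + 1, max(float(d.max()) / 4, 1.0)], maxfev=20000)
        resid = float(np.sqrt(np.mean((fn(d, *popt) - S) ** 2)))
        return RarefactionCurve(points, float(popt[0]), float(popt[1]), resid, model=model)
    except (RuntimeError, ValueError):
        return RarefactionCurve(points, None, None, None, model=model)


def write_assembly_fasta(assembly: Assembly, path) -> None:
    from .io import write_fasta

    write_fasta([SequenceRecord(c.id, c.bases) for c in assembly.contigs], path)


def write_scaffold_table(assembly: Assembly, path) -> None:
    """AGP-like TSV: scaffold id, part number, contig id, orientation, gap
    to the next part (1-based part numbering; gap -1 means none)."""
    with open(path, "w") as fh:
        fh.write("# scaffold\tpart\tcontig\torientation\tgap_after\n")
        for sc in assembly.scaffolds:
            for i, (cid, o) in enumerate(sc.members):
                gap = int(round(sc.gaps[i])) if i < len(sc.gaps) else -1
                fh.write(f"{sc.id}\t{i + 1}\t{cid}\t{o}\t{gap}\n")


def write_rarefaction_tsv(curve: RarefactionCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write("# n_reads\tfraction\treplicate\tassembly_bases\n")
        for m, f, r, b in curve.points:
            fh.write(f"{m}\t{f}\t{r}\t{int(b)}\n")
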