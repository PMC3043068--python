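"""End-to-end consensus genome-recovery workflow.

Stage order follows the hybrid single-cell + metagenomic recipe:

1. derive a stringent G+C filter from the (contamination-free)
   single-cell datasets and purge high-GC reads from the bulk
   enrichment dataset;
2. rescue removed reads that map (90% identity over 40 bases) to
   related reference genomes — high-GC conserved regions;
3. assemble the filtered enrichment reads de novo;
4. map single-cell reads to that initial assembly and exclude reads
   flagged as chimeric by split alignment;
5. assemble the single-cell reads per cell, shred the contigs into
   550-mers with 50-base overlaps, and run the consensus assembly over
   filtered + rescued enrichment reads plus the pseudo-reads;
6. scaffold with paired-end links, screen contigs against known
   contaminant references, and orient/order the surviving elements
   against a reference genome.

Every stage logs input/output record counts into a provenance log, so
no read is silently lost; the whole run is deterministic under the
configured seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import align, assembly as asmod, compare, gcfilter, refguide, simulate, tracks
from .align import MapCriteria
from .assembly import Assembly, ShredParams
from .gcfilter import FilterParams
from .io import write_fasta, write_fastq
from .records import ReadSet, SequenceRecord
from .simulate import CommunitySpec, ReadModel


@dataclass
class PipelineConfig:
    """Configuration of a synthetic-community consensus run.

    Depths are mean sequencing depths over the target genome; the
    single-cell default (12x) sits inside the 10-30x range typical of
    single-cell MDA sequencing, and the bulk default is 20x.
    """

    outdir: str = "run"
    seed: int = 1
    community: CommunitySpec = field(default_factory=simulate.default_community)
    n_cells: int = 5
    cell_depth: float = 12.0
    bulk_depth: float = 20.0
    n_scaffold_pairs: int = 800
    read_model: ReadModel = field(default_factory=ReadModel)
    filter_params: FilterParams = field(default_factory=FilterParams)
    derive_threshold: bool = True
    map_criteria: MapCriteria = field(default_factory=MapCriteria)
    shred: ShredParams = field(default_factory=ShredParams)
    min_overlap: int = 40
    min_overlap_identity: float = 0.97
    reference_divergence: float = 0.10  # relative used for rescue + ordering
    rescue_into_enrichment: bool = True
    run_rarefaction: bool = True
    rarefaction_fractions: tuple = (0.1, 0.25, 0.5, 0.75, 1.0)
    rarefaction_replicates: int = 1
    track_window: int = 5000
    track_step: int = 1000


@dataclass
class ProvenanceLog:
    stages: list = field(default_factory=list)

    def record(self, stage: str, counts: dict, params: Optional[dict] = None) -> None:
        self.stages.append(
            dict(stage=stage, counts=counts, params=params or {},
                 wall_time=time.time())
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.stages, fh, indent=1, default=str)


@dataclass
class PipelineResult:
    assembly: Assembly
    kept_elements: list  # SequenceRecords after contaminant screen
    layouts: list
    stats: asmod.AssemblyStats
    evaluation: dict
    rarefaction: Optional[asmod.RarefactionCurve]
    provenance: ProvenanceLog
    outdir: Path


def mutate_genome(genome: SequenceRecord, divergence: float, seed: int,
                  name: Optional[str] = None) -> SequenceRecord:
    """A diverged relative: substitutions at the given rate, no indels."""
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(genome.bases.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < divergence)[0]
    lut = {ord(b): [ord(c) for c in "ACGT" if c != b] for b in "ACGT"}
    for i in hits:
        if arr[i] in lut:
            arr[i] = lut[arr[i]][rng.integers(3)]
    return SequenceRecord(name or f"{genome.id}_relative", arr.tobytes().decode())


def _coverage_of_truth(elements, truth_genome: SequenceRecord) -> float:
    """Fraction of the true genome covered by alignments of the given
    contigs/scaffold sequences (union of reference intervals)."""
    index = align.KmerIndex([truth_genome])
    covered = np.zeros(len(truth_genome.bases), dtype=bool)
    for e in elements:
        for h in align.align_to_index(e, index, q_stride=4):
            if h.identity >= 0.9 and h.length >= 100:
                covered[h.s_start : h.s_end] = True
    return float(covered.mean())


def _contig_origins(assembly: Assembly, truths: dict[str, pd.DataFrame]) -> dict[str, str]:
    """Majority read-provenance genome per contig, via the simulation
    truth tables (read id -> origin genome)."""
    read_origin: dict[str, str] = {}
    for df in truths.values():
        read_origin.update(dict(zip(df["read_id"], df["genome"])))
    origins = {}
    for c in assembly.contigs:
        votes: dict[str, int] = {}
        for rid, _, _ in c.member_reads:
            base = rid.split(":")[0]  # pseudo-read ids encode their contig
            g = read_origin.get(rid) or read_origin.get(base)
            if g:
                votes[g] = votes.get(g, 0) + 1
        origins[c.id] = max(votes, key=votes.get) if votes else "unknown"
    return origins


def run_consensus(config: PipelineConfig) -> PipelineResult:
    """Execute the full synthetic-community consensus workflow."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    prov = ProvenanceLog()
    seed = config.seed
    model = config.read_model
    community = config.community
    target_spec = community.target
    L = target_spec.length

    # --- simulate ground truth -------------------------------------------
    genomes = {n: simulate.simulate_genome(s) for n, s in community.specs().items()}
    target = genomes[target_spec.name]
    relative = mutate_genome(target, config.reference_divergence, seed=seed + 900)
    reads_per_cell = int(round(config.cell_depth * L / model.mean_len))
    n_bulk = int(round(config.bulk_depth * L / model.mean_len / community.target_fraction))

    pure = simulate.pure_target_community(community)
    cells = []
    truths: dict[str, pd.DataFrame] = {}
    for i in range(config.n_cells):
        prof = simulate.simulate_bias_profile(L, seed=seed * 1000 + i)
        sample = simulate.simulate_reads(
            pure, {target_spec.name: prof}, reads_per_cell, model,
            seed=seed * 1000 + 100 + i, source_label=f"cell{i}",
            genomes={target_spec.name: target},
        )
        cells.append(sample)
        truths[f"cell{i}"] = sample.truth
    bulk_bias = {
        name: simulate.bulk_bias_profile(len(g.bases), seed=seed * 1000 + 500 + k)
        for k, (name, g) in enumerate(sorted(genomes.items()))
    }
    bulk = simulate.simulate_reads(
        community, bulk_bias, n_bulk, model, seed=seed * 1000 + 600,
        source_label="bulk", genomes=genomes,
    )
    truths["bulk"] = bulk.truth
    pairs = simulate.simulate_reads(
        community, bulk_bias, config.n_scaffold_pairs, model, paired=True,
        seed=seed * 1000 + 700, source_label="pairs", genomes=genomes,
    )
    truths["pairs"] = pairs.truth
    prov.record(
        "simulate",
        dict(cells=config.n_cells, reads_per_cell=reads_per_cell,
             bulk_reads=n_bulk, scaffold_pairs=config.n_scaffold_pairs),
        dict(seed=seed, cell_depth=config.cell_depth, bulk_depth=config.bulk_depth),
    )
    write_fasta(list(genomes.values()) + [relative], out / "true_genomes.fasta")

    # --- GC filter + rescue ----------------------------------------------
    params = config.filter_params
    if config.derive_threshold:
        thr = gcfilter.derive_gc_threshold([c.reads for c in cells])
        params = FilterParams(gc_threshold=thr, rescue_criteria=params.rescue_criteria)
    retained, removed = gcfilter.gc_filter(bulk.reads, params)
    rescue_refs = [relative]
    rescued = gcfilter.rescue_high_gc(removed, rescue_refs, params.rescue_criteria)
    prov.record(
        "gc_filter",
        dict(input=len(bulk.reads), retained=len(retained), removed=len(removed),
             rescued=len(rescued)),
        dict(gc_threshold=params.gc_threshold),
    )

    # --- initial enrichment assembly --------------------------------------
    enrich_pool = list(retained.reads) + (list(rescued.reads) if config.rescue_into_enrichment else [])
    enrich_reads = ReadSet(enrich_pool, source_label="enrichment_filtered")
    initial = asmod.greedy_assemble(
        enrich_reads, config.min_overlap, config.min_overlap_identity
    )
    prov.record(
        "enrichment_assembly",
        dict(reads=len(enrich_reads), contigs=len(initial.contigs),
             bases=initial.total_contig_bases()),
    )

    # --- chimera exclusion on single-cell reads ---------------------------
    init_refs = [SequenceRecord(c.id, c.bases) for c in initial.contigs]
    init_index = align.KmerIndex(init_refs)
    kept_cell_reads: list[ReadSet] = []
    n_chimeric = 0
    for i, cell in enumerate(cells):
        calls = align.flag_chimeras(
            cell.reads, init_refs, config.map_criteria, index=init_index
        )
        chimeric_ids = {c.read_id for c in calls if c.is_chimeric}
        n_chimeric += len(chimeric_ids)
        kept = cell.reads.subset(
            {r.id for r in cell.reads} - chimeric_ids
        )
        kept_cell_reads.append(kept)
    prov.record(
        "chimera_exclusion",
        dict(input=sum(len(c.reads) for c in cells), excluded=n_chimeric,
             kept=sum(len(k) for k in kept_cell_reads)),
    )

    # --- per-cell assembly + shredding -------------------------------------
    pseudo: list[SequenceRecord] = []
    cell_assemblies = []
    for i, kept in enumerate(kept_cell_reads):
        asm = asmod.greedy_assemble(kept, config.min_overlap, config.min_overlap_identity)
        cell_assemblies.append(asm)
        shredded = asmod.shred_contigs(
            [asmod.Contig(f"cell{i}.{c.id}", c.bases, c.member_reads) for c in asm.contigs],
            config.shred,
        )
        pseudo.extend(shredded.reads)
    prov.record(
        "shred",
        dict(cell_contigs=sum(len(a.contigs) for a in cell_assemblies),
             pseudo_reads=len(pseudo)),
        dict(k=config.shred.k, overlap=config.shred.overlap),
    )

    # --- consensus assembly -------------------------------------------------
    consensus_reads = ReadSet(
        list(enrich_reads.reads) + pseudo, source_label="consensus_pool"
    )
    consensus = asmod.greedy_assemble(
        consensus_reads, config.min_overlap, config.min_overlap_identity
    )
    consensus = asmod.scaffold_with_pairs(
        consensus, pairs.reads, config.map_criteria,
        lib_span=model.pair_span, lib_sd=model.sd_span,
    )
    prov.record(
        "consensus_assembly",
        dict(reads=len(consensus_reads), contigs=len(consensus.contigs),
             scaffolds=len(consensus.scaffolds),
             bases=consensus.total_contig_bases()),
    )

    # --- contaminant screen -------------------------------------------------
    contaminant_refs = [genomes[s.name] for s, _ in community.contaminants]
    contig_seqs = [SequenceRecord(c.id, c.bases) for c in consensus.contigs]
    kept_seqs, excluded = refguide.contaminant_screen(
        contig_seqs, contaminant_refs, config.map_criteria
    )
    kept_ids = {s.id for s in kept_seqs}
    screened = Assembly(
        contigs=[c for c in consensus.contigs if c.id in kept_ids],
        scaffolds=[
            sc for sc in consensus.scaffolds
            if all(cid in kept_ids for cid, _ in sc.members)
        ],
    )
    prov.record(
        "contaminant_screen",
        dict(input=len(consensus.contigs), kept=len(screened.contigs),
             excluded=len(excluded)),
    )

    # --- orientation and ordering ------------------------------------------
    # elements = scaffolds (concatenated with gap Ns) + unscaffolded contigs
    by_id = screened.contig_by_id()
    elements: list[SequenceRecord] = []
    for sc in screened.scaffolds:
        parts = []
        for idx, (cid, o) in enumerate(sc.members):
            seq = by_id[cid].bases
            if o == "-":
                seq = SequenceRecord(cid, seq).reverse_complement().bases
            parts.append(seq)
            if idx < len(sc.gaps):
                parts.append("N" * max(1, int(round(max(0, sc.gaps[idx])))))
        elements.append(SequenceRecord(sc.id, "".join(parts)))
    for cid in screened.unscaffolded:
        elements.append(SequenceRecord(cid, by_id[cid].bases))
    layouts = refguide.order_elements(elements, relative)
    ordered = refguide.ordered_fasta_records(layouts, elements)
    prov.record(
        "layout",
        dict(elements=len(elements), placed=sum(1 for l in layouts if l.placed)),
    )

    # --- statistics, rarefaction, tracks ------------------------------------
    stats = asmod.assembly_stats(screened)
    curve = None
    if config.run_rarefaction:
        curve = asmod.rarefy_and_fit(
            enrich_reads, config.rarefaction_fractions,
            config.rarefaction_replicates,
            lambda rs: asmod.greedy_assemble(rs, config.min_overlap, config.min_overlap_identity),
            seed=seed,
        )
        asmod.write_rarefaction_tsv(curve, out / "rarefaction.tsv")

    layout_genome = SequenceRecord("ordered_assembly", "".join(r.bases for r in ordered))
    if len(layout_genome.bases) >= config.track_window:
        for name, tr in (
            ("gc", tracks.windowed_gc(layout_genome, config.track_window, config.track_step)),
            ("gc_skew", tracks.gc_skew(layout_genome, config.track_window, config.track_step)),
            ("gc_skew_cum", tracks.gc_skew(layout_genome, config.track_window, cumulative=True)),
            ("gggt_skew_cum", tracks.oligo_skew(layout_genome, "GGGT", config.track_window, cumulative=True)),
        ):
            tracks.write_track_bedgraph(tr, "ordered_assembly", out / f"track_{name}.bedgraph")

    # --- truth-based evaluation ----------------------------------------------
    origins = _contig_origins(screened, truths)
    contaminant_names = {s.name for s, _ in community.contaminants}
    n_contam_contigs = sum(1 for g in origins.values() if g in contaminant_names)
    coverage = _coverage_of_truth(kept_seqs, target)
    excluded_origins = _contig_origins(
        Assembly(contigs=[c for c in consensus.contigs if c.id not in kept_ids]),
        truths,
    )
    evaluation = dict(
        target_coverage=coverage,
        contaminant_contigs_after_screen=n_contam_contigs,
        excluded_contigs=len(excluded),
        excluded_contaminant_origin=sum(
            1 for g in excluded_origins.values() if g in contaminant_names
        ),
        genome_size_estimate=None if curve is None or not curve.ok else curve.asymptote,
        true_genome_size=L,
    )
    prov.record("evaluate", evaluation)

    # --- write artifacts ------------------------------------------------------
    asmod.write_assembly_fasta(screened, out / "consensus_contigs.fasta")
    asmod.write_scaffold_table(screened, out / "scaffolds.tsv")
    refguide.write_layout_tsv(layouts, out / "layout.tsv")
    write_fasta(ordered, out / "ordered_assembly.fasta")
    write_fastq(bulk.reads, out / "bulk_reads.fastq")
    with open(out / "assembly_stats.json", "w") as fh:
        json.dump(stats.to_dict(), fh, indent=1)
    prov.to_json(out / "provenance.json")
    with open(out / "evaluation.json", "w") as fh:
        json.dump(evaluation, fh, indent=1)

    return PipelineResult(
        assembly=screened, kept_elements=kept_seqs, layouts=layouts,
        stats=stats, evaluation=evaluation, rarefaction=curve,
        provenance=prov, outdir=out,
    )


def report(run_dir) -> dict:
    """Consolidate a completed run directory into one summary document
    (JSON-serialisable dict; also written as report.json/report.md)."""
    run_dir = Path(run_dir)
    missing = []
    doc: dict = {}
    for key, fname in (
        ("assembly_stats", "assembly_stats.json"),
        ("evaluation", "evaluation.json"),
        ("provenance", "provenance.json"),
    ):
        p = run_dir / fname
        if not p.exists():
            missing.append(fname)
            continue
        with open(p) as fh:
            doc[key] = json.load(fh)
    doc["missing_outputs"] = missing
    if "provenance" in doc:
        doc["read_accounting"] = {
            s["stage"]: s["counts"] for s in doc["provenance"]
        }
        # timestamps are excluded so equal-seed runs produce identical reports
        for s in doc["provenance"]:
            s.pop("wall_time", None)
    with open(run_dir / "report.json", "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
    lines = ["# Consensus run report", ""]
    if "assembly_stats" in doc:
        lines.append("## Assembly statistics")
        for k, v in doc["assembly_stats"].items():
            lines.append(f"- {k}: {v}")
        lines.append("")
    if "evaluation" in doc:
        lines.append("## Evaluation against simulation truth")
        for k, v in doc["evaluation"].items():
            lines.append(f"- {k}: {v}")
        lines.append("")
    if missing:
        lines.append("## Missing stage outputs")
        lines.extend(f"- {m}" for m in missing)
    (run_dir / "report.md").write_text("\n".join(lines) + "\n")
    return doc
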