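"""Shredding, greedy assembly, paired-end scaffolding, assembly
statistics and rarefaction genome-size estimation."""

import numpy as np
import pytest

from mdagenome.align import MapCriteria
from mdagenome.assembly import (
    Assembly,
    Contig,
    Scaffold,
    ShredParams,
    assembly_stats,
    fit_rarefaction_points,
    greedy_assemble,
    rarefy_and_fit,
    scaffold_with_pairs,
    shred_contigs,
)
from mdagenome.records import ReadSet, SequenceRecord, revcomp
from mdagenome.simulate import (
    CommunitySpec,
    GenomeSpec,
    ReadModel,
    simulate_bias_profile,
    simulate_genome,
    simulate_reads,
)

from conftest import random_seq


class TestShred:
    def test_two_window_overlap(self, rng):
        c = Contig("c", random_seq(1050, rng))
        pseudo = shred_contigs([c])
        assert len(pseudo) == 2
        a, b = pseudo.reads
        assert a.bases == c.bases[0:550] and b.bases == c.bases[500:1050]
        assert a.bases[-50:] == b.bases[:50]  # exactly 50 shared bases

    def test_exact_single_window(self, rng):
        c = Contig("c", random_seq(550, rng))
        assert len(shred_contigs([c])) == 1

    def test_end_anchored_final_window(self, rng):
        c = Contig("c", random_seq(1600, rng))
        pseudo = shred_contigs([c])
        assert len(pseudo) == 4
        assert pseudo.reads[-1].bases == c.bases[1050:1600]
        assert pseudo.reads[-1].id == "c:1050"

    def test_short_contig_emitted_whole(self, rng):
        c = Contig("tiny", random_seq(120, rng))
        pseudo = shred_contigs([c])
        assert len(pseudo) == 1 and pseudo.reads[0].bases == c.bases

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            ShredParams(k=100, overlap=100)


class TestGreedyAssemble:
    def test_reconstructs_tiled_genome(self, rng):
        genome = random_seq(5000, rng)
        reads = [
            SequenceRecord(f"r{i:03d}", genome[s : s + 400])
            for i, s in enumerate(range(0, 4601, 40))
        ]
        asm = greedy_assemble(ReadSet(reads, "x"))
        assert len(asm.contigs) == 1
        got = asm.contigs[0].bases
        assert got == genome or got == revcomp(genome)

    def test_no_overlap_gives_singletons(self, rng):
        reads = [
            SequenceRecord("a", random_seq(200, rng)),
            SequenceRecord("b", random_seq(200, rng)),
        ]
        asm = greedy_assemble(ReadSet(reads, "x"))
        assert len(asm.contigs) == 2

    def test_shuffle_invariance(self, rng):
        genome = random_seq(3000, rng)
        reads = [
            SequenceRecord(f"r{i:03d}", genome[s : s + 300])
            for i, s in enumerate(range(0, 2701, 60))
        ]
        asm1 = greedy_assemble(ReadSet(reads, "x"))
        shuffled = list(reads)
        rng.shuffle(shuffled)
        asm2 = greedy_assemble(ReadSet(shuffled, "x"))
        assert [c.bases for c in asm1.contigs] == [c.bases for c in asm2.contigs]

    def test_shred_then_assemble_roundtrip(self, rng):
        """Pseudo-reads overlap by >= 40 at identity 1, so shredding then
        reassembling reconstructs every contig exactly (up to strand)."""
        contigs = [Contig(f"c{i}", random_seq(3000, rng)) for i in range(3)]
        pseudo = shred_contigs(contigs)
        asm = greedy_assemble(pseudo)
        originals = {c.bases for c in contigs} | {revcomp(c.bases) for c in contigs}
        assert len(asm.contigs) == 3
        assert all(c.bases in originals for c in asm.contigs)

    def test_consensus_majority_fixes_read_errors(self, rng):
        genome = random_seq(2000, rng)
        reads = []
        for i, s in enumerate(range(0, 1601, 20)):
            seq = list(genome[s : s + 400])
            j = int(rng.integers(0, 400))  # one error per read
            seq[j] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[j]]
            reads.append(SequenceRecord(f"r{i:03d}", "".join(seq)))
        asm = greedy_assemble(ReadSet(reads, "x"))
        assert len(asm.contigs) == 1
        got = asm.contigs[0].bases
        if got != genome:
            got = revcomp(got)
        mismatches = sum(a != b for a, b in zip(got, genome))
        assert len(got) == len(genome) and mismatches <= 2


class TestScaffold:
    def test_links_two_contigs_with_correct_gap(self, small_target_spec, small_target):
        g = small_target.bases
        asm = Assembly(contigs=[Contig("cA", g[5000:15000]), Contig("cB", g[16000:26000])])
        community = CommunitySpec(small_target_spec, (), 1.0)
        prof = simulate_bias_profile(50_000, sigma=0.0, dropout_quantile=0.0, seed=1)
        pairs = simulate_reads(
            community, {"target": prof}, 300, ReadModel(chimera_rate=0.0),
            paired=True, seed=9, genomes={"target": small_target},
        )
        out = scaffold_with_pairs(asm, pairs.reads, MapCriteria())
        assert len(out.scaffolds) == 1
        sc = out.scaffolds[0]
        ids = [cid for cid, _ in sc.members]
        assert set(ids) == {"cA", "cB"}
        assert sc.gaps[0] == pytest.approx(1000, abs=300)
        # orientations consistent with a colinear genome: both + or both -
        assert len({o for _, o in sc.members}) == 1

    def test_no_cross_pairs_leaves_assembly_unchanged(self, rng):
        asm = Assembly(contigs=[Contig("a", random_seq(2000, rng)),
                                Contig("b", random_seq(2000, rng))])
        reads = [SequenceRecord("p/1", asm.contigs[0].bases[100:400]),
                 SequenceRecord("p/2", revcomp(asm.contigs[0].bases[1500:1800]))]
        pairs = ReadSet(reads, "p", pairing={"p/1": "p/2", "p/2": "p/1"})
        out = scaffold_with_pairs(asm, pairs, MapCriteria())
        assert out.scaffolds == []

    def test_fewer_than_min_links_ignored(self, small_target):
        g = small_target.bases
        asm = Assembly(contigs=[Contig("cA", g[5000:15000]), Contig("cB", g[16000:26000])])
        # only two supporting pairs: below the 3-link threshold
        reads, pairing = [], {}
        for i, frag in enumerate((6000, 7000)):
            r1 = SequenceRecord(f"p{i}/1", g[frag + 9000 : frag + 9300])
            r2 = SequenceRecord(f"p{i}/2", revcomp(g[frag + 11700 : frag + 12000]))
            reads += [r1, r2]
            pairing[r1.id], pairing[r2.id] = r2.id, r1.id
        out = scaffold_with_pairs(asm, ReadSet(reads, "p", pairing), MapCriteria())
        assert out.scaffolds == []


class TestStats:
    def test_textbook_n50(self, rng):
        contigs = [Contig(f"c{i}", random_seq(n, rng)) for i, n in enumerate([400, 300, 200, 100])]
        s = assembly_stats(Assembly(contigs=contigs))
        assert s.contig_n50 == 300 and s.largest_contig == 400

    def test_element_count_scaffolds_plus_unscaffolded(self, rng):
        contigs = [Contig(f"c{i}", random_seq(100, rng)) for i in range(33)]
        scaffolds = [
            Scaffold("s0", [("c0", "+"), ("c1", "-")], [50]),
            Scaffold("s1", [("c2", "+"), ("c3", "+")], [10]),
        ]
        s = assembly_stats(Assembly(contigs=contigs, scaffolds=scaffolds))
        assert s.n_scaffolds == 2 and s.unscaffolded_contigs == 29
        assert s.n_elements == 31

    def test_single_contig_degenerate(self, rng):
        s = assembly_stats(Assembly(contigs=[Contig("c", random_seq(777, rng))]))
        assert s.contig_n50 == s.largest_contig == s.contig_bases == 777

    def test_scaffold_length_includes_gaps(self, rng):
        contigs = [Contig("a", random_seq(100, rng)), Contig("b", random_seq(100, rng))]
        asm = Assembly(contigs=contigs, scaffolds=[Scaffold("s", [("a", "+"), ("b", "+")], [40])])
        s = assembly_stats(asm)
        assert s.scaffold_bases == 240 and s.largest_scaffold == 240


class TestRarefaction:
    def test_noiseless_model_recovery(self):
        d = np.linspace(1000, 60_000, 12)
        G, kappa = 1.8e6, 15_000.0
        S = G * (1 - np.exp(-d / kappa))
        curve = fit_rarefaction_points(d, S)
        assert curve.ok
        assert abs(curve.asymptote - G) / G < 1e-3

    def test_saturated_curve_returns_plateau(self):
        d = np.array([1000.0, 2000, 4000, 8000])
        S = np.full(4, 50_000.0)
        curve = fit_rarefaction_points(d, S)
        assert curve.ok and curve.asymptote == pytest.approx(50_000, rel=0.01)

    def test_synthetic_curve_recovers_genome_size(self):
        """Uniform-coverage reads over a 100 kb genome: fitted asymptote
        within 5% of the truth; curve monotone within replicate noise."""
        spec = GenomeSpec("t", 100_000, 0.324, seed=11)
        genome = simulate_genome(spec)
        community = CommunitySpec(spec, (), 1.0)
        prof = simulate_bias_profile(100_000, sigma=0.0, dropout_quantile=0.0, seed=1)
        sample = simulate_reads(
            community, {"t": prof}, 5000, ReadModel(chimera_rate=0.0),
            seed=2, genomes={"t": genome},
        )
        curve = rarefy_and_fit(sample.reads, replicates=1, seed=3)
        assert curve.ok
        assert abs(curve.asymptote - 100_000) / 100_000 < 0.05
        by_n = [p[3] for p in sorted(curve.points)]
        diffs = np.diff(by_n)
        assert (diffs > -0.02 * 100_000).all()  # non-decreasing within noise

    def test_unsorted_fractions_rejected(self, rng):
        reads = ReadSet([SequenceRecord("r", random_seq(100, rng))], "x")
        with pytest.raises(ValueError):
            rarefy_and_fit(reads, fractions=(0.5, 0.1))
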