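"""Reciprocal best hits, corresponding-region ANI with the floored
whole-genome average, novelty index, microheterogeneity and
expected-error budgets."""

import numpy as np
import pytest

from mdagenome.assembly import Assembly, Contig
from mdagenome.compare import (
    ANIReport,
    ani_corresponding,
    expected_errors,
    microheterogeneity,
    novelty_track,
    rbh,
    whole_genome_identity,
)
from mdagenome.pipeline import mutate_genome
from mdagenome.records import SequenceRecord
from mdagenome.simulate import GenomeSpec, simulate_genome

from conftest import random_seq

AA = list("ACDEFGHIKLMNPQRSTVWY")


def _protein(n, rng):
    return "".join(rng.choice(AA, n))


class TestRBH:
    def test_identical_proteomes_all_high_confidence(self, rng):
        genes = [(f"p{i}", _protein(80, rng)) for i in range(10)]
        other = [(f"q{i}", s) for i, (_, s) in enumerate(genes)]
        pairs = rbh(genes, other, protein=True)
        assert len(pairs) == 10
        assert all(p.confidence == "high" and p.identity_fwd == 1.0 for p in pairs)

    def test_planted_orthologs_recovered_among_decoys(self, rng):
        """Nucleotide genes at ~80% identity are each other's best hits;
        random decoys form no pairs."""
        planted_a, planted_b = [], []
        for i in range(5):
            gene = random_seq(600, rng)
            mutated = list(gene)
            for j in rng.choice(600, 120, replace=False):
                mutated[j] = "ACGT"[rng.integers(4)]
            planted_a.append((f"a{i}", gene))
            planted_b.append((f"b{i}", "".join(mutated)))
        decoys_a = [(f"da{i}", random_seq(600, rng)) for i in range(3)]
        decoys_b = [(f"db{i}", random_seq(600, rng)) for i in range(3)]
        pairs = rbh(planted_a + decoys_a, planted_b + decoys_b)
        got = {(p.gene_a, p.gene_b) for p in pairs}
        assert {(f"a{i}", f"b{i}") for i in range(5)} <= got
        assert not any(a.startswith("da") or b.startswith("db") for a, b in got)

    def test_low_coverage_forward_hit_low_confidence(self, rng):
        """A forward hit covering only half the query is still reported
        as an RBH pair but with low confidence (the 60% coverage rule)."""
        shared = random_seq(300, rng)
        a = [("a0", shared + random_seq(300, rng))]  # hit covers 50% of query
        b = [("b0", shared)]
        pairs = rbh(a, b)
        assert len(pairs) == 1 and pairs[0].confidence == "low"
        assert pairs[0].coverage_fwd == pytest.approx(0.5, abs=0.05)

    def test_symmetry(self, rng):
        a = [(f"a{i}", random_seq(400, rng)) for i in range(4)]
        b = [(f"b{i}", s) for i, (_, s) in enumerate(a)]
        ab = {(p.gene_a, p.gene_b) for p in rbh(a, b)}
        ba = {(p.gene_b, p.gene_a) for p in rbh(b, a)}
        assert ab == ba


class TestANI:
    def test_self_comparison_full_identity(self):
        g = simulate_genome(GenomeSpec("g", 20_000, 0.4, seed=1))
        rep = ani_corresponding(g, g)
        assert rep.corresponding_bases == 20_000
        assert rep.identity_corresponding == pytest.approx(1.0)
        assert whole_genome_identity(rep) == pytest.approx(1.0)

    def test_five_percent_divergence(self):
        g = simulate_genome(GenomeSpec("g", 60_000, 0.324, seed=3))
        rel = mutate_genome(g, 0.05, seed=4)
        rep = ani_corresponding(g, rel)
        assert rep.identity_corresponding == pytest.approx(0.95, abs=0.005)
        assert rep.corresponding_bases >= 0.98 * 60_000

    def test_disjoint_genomes_no_correspondence(self):
        a = simulate_genome(GenomeSpec("a", 30_000, 0.35, seed=5))
        b = simulate_genome(GenomeSpec("b", 30_000, 0.5, seed=6))
        rep = ani_corresponding(a, b)
        assert rep.corresponding_bases < 0.01 * 30_000
        assert whole_genome_identity(rep) == pytest.approx(0.25, abs=0.01)


class TestWholeGenomeIdentity:
    def test_published_style_worked_example(self):
        # 398,085 corresponding bases at 67.4% over a 2,045,086-base
        # reference with a 25% floor -> 33.3%
        rep = ANIReport(398_085, 0.674, 2_045_086, 0.25)
        assert round(100 * whole_genome_identity(rep), 1) == 33.3

    def test_full_correspondence_returns_ani(self):
        rep = ANIReport(1000, 0.8, 1000, 0.25)
        assert whole_genome_identity(rep) == pytest.approx(0.8)

    def test_zero_correspondence_returns_floor(self):
        rep = ANIReport(0, 0.0, 1000, 0.25)
        assert whole_genome_identity(rep) == pytest.approx(0.25)

    def test_monotone_in_corresponding_bases(self):
        vals = [
            whole_genome_identity(ANIReport(c, 0.7, 10_000, 0.25))
            for c in (0, 2500, 5000, 10_000)
        ]
        assert vals == sorted(vals)


class TestNovelty:
    def test_identity_to_both_references_gives_zero(self):
        g = simulate_genome(GenomeSpec("g", 15_000, 0.4, seed=7))
        nt = novelty_track(g, [g, g])
        assert np.allclose(nt.values, 0.0)
        assert (nt.depth >= 2).all()

    def test_no_homology_scores_two(self, rng):
        g = simulate_genome(GenomeSpec("g", 10_000, 0.35, seed=8))
        aliens = [
            simulate_genome(GenomeSpec("x", 10_000, 0.5, seed=9)),
            simulate_genome(GenomeSpec("y", 10_000, 0.6, seed=10)),
        ]
        nt = novelty_track(g, aliens)
        assert np.mean(nt.values > 1.9) > 0.99

    def test_partial_identities_sum(self):
        g = simulate_genome(GenomeSpec("g", 30_000, 0.4, seed=11))
        refs = [mutate_genome(g, 0.05, seed=1), mutate_genome(g, 0.10, seed=2)]
        nt = novelty_track(g, refs)
        # 2 - (0.95 + 0.90) = 0.15 on average
        assert np.mean(nt.values) == pytest.approx(0.15, abs=0.02)
        assert nt.values.min() >= 0 and nt.values.max() <= 2

    def test_adding_reference_never_increases_novelty(self):
        g = simulate_genome(GenomeSpec("g", 20_000, 0.4, seed=12))
        rel = mutate_genome(g, 0.08, seed=3)
        one = novelty_track(g, [rel])
        two = novelty_track(g, [rel, mutate_genome(g, 0.2, seed=4)])
        # with R references the index baseline is R; compare homology mass
        assert ((2 - two.values) >= (1 - one.values) - 1e-9).all()


class TestMicroheterogeneity:
    def _assembly(self, genome, n=4, size=5000, mutate_rate=0.0, seed=0):
        contigs = []
        for i in range(n):
            seq = genome.bases[i * size : (i + 1) * size]
            if mutate_rate:
                seq = mutate_genome(
                    SequenceRecord("x", seq), mutate_rate, seed=seed + i
                ).bases
            contigs.append(Contig(f"c{i}", seq))
        return Assembly(contigs=contigs)

    def test_identical_assemblies(self):
        g = simulate_genome(GenomeSpec("g", 25_000, 0.35, seed=13))
        asm = self._assembly(g)
        ani, detail = microheterogeneity([asm, asm], labels=["a", "b"])
        assert ani.loc["a", "b"] == pytest.approx(1.0)
        assert detail["snps"].iloc[0] == 0

    def test_planted_per_mille_variants(self):
        """Two cell assemblies from one population genome with 0.1%
        within-population variants recover ~99.9% ANI."""
        g = simulate_genome(GenomeSpec("g", 40_000, 0.35, seed=14))
        a = self._assembly(g, mutate_rate=0.0005, seed=100)
        b = self._assembly(g, mutate_rate=0.0005, seed=200)
        ani, detail = microheterogeneity([a, b], labels=["a", "b"])
        assert ani.loc["a", "b"] == pytest.approx(0.999, abs=0.0004)
        snp_rate = detail["snps_per_mb"].iloc[0]
        assert snp_rate == pytest.approx(1000, rel=0.35)  # ~0.1% per base


class TestExpectedErrors:
    def test_closed_forms(self):
        b = expected_errors(0, 1000)
        assert b.expected_errors_two_tier == pytest.approx(0.1)
        b = expected_errors(5904, 0)
        assert b.expected_errors_two_tier == pytest.approx(590.4)

    def test_two_tier_combined(self):
        b = expected_errors(5904, 1_763_669)
        assert b.expected_errors_two_tier == pytest.approx(590.4 + 176.4, abs=0.1)

    def test_exact_form_additive_over_base_sets(self, rng):
        q1 = rng.integers(2, 41, 500)
        q2 = rng.integers(2, 41, 700)
        whole = expected_errors(0, 0, quality_scores=np.concatenate([q1, q2]))
        parts = (
            expected_errors(0, 0, quality_scores=q1).expected_errors_exact
            + expected_errors(0, 0, quality_scores=q2).expected_errors_exact
        )
        assert whole.expected_errors_exact == pytest.approx(parts)

    def test_mda_contribution_below_twenty_bases(self):
        b = expected_errors(0, 0, genome_length=1_769_573)
        assert b.mda_expected_errors == pytest.approx(17.7, abs=0.05)
        assert b.mda_expected_errors < 20
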