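"""Composition tracks, skews and transition points; codon usage with the
scrambled control; annotation summaries."""

import numpy as np
import pandas as pd
import pytest

from mdagenome.records import SequenceRecord
from mdagenome.simulate import GenomeSpec, simulate_genome
from mdagenome.tracks import (
    annotation_summary,
    codon_usage,
    codon_usage_distance,
    find_transitions,
    gc_skew,
    oligo_skew,
    scrambled_control,
    windowed_gc,
)

from conftest import random_seq

CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]


@pytest.fixture(scope="module")
def switch_genome():
    """100 kb genome whose G:C balance flips at the midpoint."""
    return simulate_genome(
        GenomeSpec("g", 100_000, 0.324, composition_switch=50_000, seed=5)
    )


class TestWindowedGC:
    def test_homogeneous_genome(self):
        g = simulate_genome(GenomeSpec("g", 50_000, 0.32, seed=1))
        tr = windowed_gc(g)
        assert np.all(np.abs(tr.values - 0.32) < 0.05)

    def test_pure_gc_window(self):
        g = SequenceRecord("g", "GGGGCCCC" * 2 + "ATATATAT" * 2)
        tr = windowed_gc(g, window=16, step=16)
        assert tr.values[0] == 1.0 and tr.values[1] == 0.0

    def test_window_mean_matches_global(self):
        g = simulate_genome(GenomeSpec("g", 60_000, 0.4, seed=2))
        tr = windowed_gc(g, window=1000, step=1000)
        global_gc = (g.bases.count("G") + g.bases.count("C")) / len(g.bases)
        assert abs(tr.values.mean() - global_gc) < 0.001


class TestGCSkew:
    def test_window_arithmetic(self):
        g = SequenceRecord("g", "GGGGCC" + "AATTAA")
        tr = gc_skew(g, window=6, step=6)
        assert tr.values[0] == pytest.approx((4 - 2) / 6)
        assert tr.values[1] == 0.0  # no G or C -> defined as 0

    def test_constructed_extremum(self):
        g = SequenceRecord("g", "G" * 1000 + "C" * 1000)
        tr = gc_skew(g, window=100, cumulative=True)
        # cumulative G-C counts peak exactly at the end of the G run
        peak_window = int(np.argmax(tr.values))
        assert tr.starts[peak_window] + tr.window == 1000

    def test_reverse_complement_negates(self):
        g = simulate_genome(GenomeSpec("g", 10_000, 0.45, seed=3))
        fwd = gc_skew(g, window=1000, step=1000)
        rev = gc_skew(g.reverse_complement(), window=1000, step=1000)
        assert np.allclose(fwd.values, -rev.values[::-1], atol=1e-12)

    def test_cumulative_telescoping(self):
        g = simulate_genome(GenomeSpec("g", 50_000, 0.4, seed=4))
        tr = gc_skew(g, window=5000, cumulative=True)
        total = g.bases.count("G") - g.bases.count("C")
        assert tr.values[-1] == total


class TestOligoSkew:
    def test_motif_only_window(self):
        g = SequenceRecord("g", "GGGTGGGT" + "A" * 8)
        tr = oligo_skew(g, "GGGT", window=8, step=8)
        assert tr.values[0] == 1.0 and tr.values[1] == 0.0

    def test_mirror_window(self):
        g = SequenceRecord("g", "ACCCACCC" + "A" * 8)
        tr = oligo_skew(g, "GGGT", window=8, step=8)
        assert tr.values[0] == -1.0

    def test_palindromic_motif_rejected(self):
        g = SequenceRecord("g", "ACGT" * 100)
        with pytest.raises(ValueError, match="reverse complement"):
            oligo_skew(g, "ACGT")

    def test_single_base_motif_matches_gc_skew_counts(self):
        g = simulate_genome(GenomeSpec("g", 20_000, 0.4, seed=6))
        a = oligo_skew(g, "G", window=2000, cumulative=True)
        b = gc_skew(g, window=2000, cumulative=True)
        assert np.allclose(a.values, b.values)


class TestTransitions:
    def test_v_shape_single_minimum(self):
        from mdagenome.tracks import Track

        v = np.abs(np.arange(-10, 11, dtype=float))
        tr = Track(np.arange(21) * 100, v, window=100, step=100, statistic="x")
        tps = find_transitions(tr)
        assert tps[0].kind == "min" and tps[0].position == 10 * 100 + 50

    def test_monotone_track_flags_endpoints(self):
        from mdagenome.tracks import Track

        v = np.arange(10, dtype=float)
        tr = Track(np.arange(10) * 100, v, window=100, step=100, statistic="x")
        tps = find_transitions(tr)
        assert {t.kind for t in tps} == {"max", "min"}
        assert all(t.prominence == 0 for t in tps)

    def test_planted_switch_detected(self, switch_genome):
        for track in (
            gc_skew(switch_genome, window=5000, cumulative=True),
            oligo_skew(switch_genome, "GGGT", window=5000, cumulative=True),
        ):
            top = find_transitions(track)[0]
            assert abs(top.position - 50_000) <= 2 * track.window


class TestCodonUsage:
    def test_inframe_counts(self):
        t = codon_usage([SequenceRecord("c", "ATGATGTAA")])
        assert t.counts["ATG"] == 2 and t.counts["TAA"] == 1
        assert t.frequencies_per_mille()["ATG"] == pytest.approx(666.7, abs=0.1)

    def test_concatenation_additivity(self, rng):
        a = SequenceRecord("a", random_seq(300, rng))
        b = SequenceRecord("b", random_seq(600, rng))
        both = codon_usage([a, b])
        sep = {
            c: codon_usage([a]).counts[c] + codon_usage([b]).counts[c] for c in CODONS
        }
        assert both.counts == sep

    def test_partial_codon_truncated(self):
        t = codon_usage([SequenceRecord("c", "ATGAT")])  # 5 bases -> 1 codon
        assert t.total_codons == 1

    def test_distance_metric_axioms(self, rng):
        tables = [
            codon_usage([SequenceRecord(f"c{i}", random_seq(3 * 500, rng))])
            for i in range(3)
        ]
        a, b, c = tables
        assert codon_usage_distance(a, a) == 0.0
        assert codon_usage_distance(a, b) == codon_usage_distance(b, a)
        assert codon_usage_distance(a, c) <= (
            codon_usage_distance(a, b) + codon_usage_distance(b, c) + 1e-9
        )

    def test_scramble_preserves_composition(self, rng):
        cds = [SequenceRecord(f"c{i}", random_seq(300, rng)) for i in range(5)]
        scr = scrambled_control(cds, seed=1)
        for orig, s in zip(cds, scr):
            assert sorted(orig.bases) == sorted(s.bases)

    def test_structured_usage_distinct_from_scramble(self):
        """CDS with real codon preferences sit closer to an organism
        sharing those preferences than to their own scrambled control,
        across 20 scramble seeds."""
        rng = np.random.default_rng(2)
        w = np.array([3.0 if c[2] == "A" else (2.0 if c[2] == "T" else 0.3)
                      for c in CODONS])
        p = w / w.sum()

        def cds_set(seed0):
            return [
                SequenceRecord(
                    f"c{s}", "".join(np.random.default_rng(seed0 + s).choice(CODONS, 300, p=p))
                )
                for s in range(10)
            ]

        original = cds_set(0)
        relative = cds_set(100)  # same codon preferences, different genes
        t_orig = codon_usage(original)
        d_rel = codon_usage_distance(t_orig, codon_usage(relative))
        for seed in range(20):
            t_scr = codon_usage(scrambled_control(original, seed=seed))
            assert codon_usage_distance(t_orig, t_scr) > d_rel


class TestAnnotationSummary:
    def _gene_table(self, n_cds, n_pseudo, n_trna, n_rrna, n_other, span=800):
        rows = []
        pos = 0
        for cat, n in [("CDS", n_cds), ("pseudogene", n_pseudo), ("tRNA", n_trna),
                       ("rRNA", n_rrna), ("other RNA", n_other)]:
            for i in range(n):
                rows.append(dict(id=f"{cat}{i}", element="e1", start=pos,
                                 end=pos + span, strand="+", category=cat))
                pos += span + 50
        return pd.DataFrame(rows)

    def test_coding_fraction_simple(self):
        genes = pd.DataFrame([
            dict(id="g1", element="e", start=0, end=500, strand="+", category="CDS"),
            dict(id="g2", element="e", start=400, end=830, strand="-", category="CDS"),
        ])
        s = annotation_summary(genes, 1000)
        assert s.coding_fraction == pytest.approx(0.83)

    def test_nested_intervals_not_double_counted(self):
        genes = pd.DataFrame([
            dict(id="g1", element="e", start=0, end=900, strand="+", category="CDS"),
            dict(id="g2", element="e", start=100, end=200, strand="-", category="CDS"),
        ])
        s = annotation_summary(genes, 1000)
        assert s.coding_fraction == pytest.approx(0.9)

    def test_total_is_category_sum(self):
        genes = self._gene_table(20, 3, 5, 2, 1)
        s = annotation_summary(genes, 100_000)
        assert s.total_genes == 31 == s.orfs + s.pseudogenes + s.rna_genes

    def test_unknown_category_rejected(self):
        genes = pd.DataFrame([
            dict(id="g", element="e", start=0, end=10, strand="+", category="weird")
        ])
        with pytest.raises(ValueError, match="categories"):
            annotation_summary(genes, 100)
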