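"""Synthetic-genome generator: plan round trips, determinism, overlap
handling, composition targets, and the sequence-evolution simulator."""

import collections

import numpy as np
import pytest

import mitochar as mc
from mitochar.synthetic_data import (DEFAULT_COMPOSITION, GenomeTemplate,
                                     TemplateError, TemplateFeature)

ANTICODONS = ["GAA", "UAC", "UAA", "GAU", "UUG", "CAU", "UCA", "UGC", "GUU",
              "GCA", "GUA", "UGA", "GUC", "UUU", "UCC", "UCG", "GUG", "GCU",
              "UAG", "UUC", "UGU", "UGG"]


def _pcg(name, n_codons, stop="TAA", start="ATG", intergenic=0, strand="H"):
    extra = {"T--": 1, "TA-": 2}.get(stop, 0)
    return TemplateFeature(name=name, category="PCG",
                           length=3 * n_codons + extra, strand=strand,
                           intergenic=intergenic, start_codon=start,
                           stop_type=stop)


def _trna(name, anticodon, length=69, intergenic=0, strand="H", dhu=True):
    return TemplateFeature(name=name, category="tRNA", length=length,
                           strand=strand, intergenic=intergenic,
                           anticodon=anticodon, dhu_present=dhu)


class TestDefaultTemplate:
    def test_plan_round_trip_is_exact(self, default_tpl, synthetic_genome):
        genome, truth = synthetic_genome
        rows = mc.build_characterization_table(genome)
        gaps = [r.intergenic for r in rows]
        planned = [tf.intergenic for tf in default_tpl.features]
        planned[0] = 0  # first row prints 0 by convention
        assert gaps == planned
        for row, tf in zip(rows, default_tpl.features):
            assert (row.length_bp, row.strand) == (tf.length, tf.strand)

    def test_genome_length_matches_reference(self, synthetic_genome):
        genome, _ = synthetic_genome
        assert len(genome) == 16570

    def test_same_seed_byte_identical(self, default_tpl, synthetic_genome):
        genome, _ = synthetic_genome
        again, _ = mc.generate_mitogenome(default_tpl, seed=1)
        assert again.sequence == genome.sequence

    def test_different_seed_different_sequence_same_metrics(
            self, default_tpl, synthetic_genome):
        genome, _ = synthetic_genome
        other, _ = mc.generate_mitogenome(default_tpl, seed=2)
        assert other.sequence != genome.sequence
        rows_a = mc.build_characterization_table(genome)
        rows_b = mc.build_characterization_table(other)
        for a, b in zip(rows_a, rows_b):
            assert (a.name, a.length_bp, a.start_codon, a.stop_codon,
                    a.intergenic) == (b.name, b.length_bp, b.start_codon,
                                      b.stop_codon, b.intergenic)

    def test_truth_records_trna_arms(self, synthetic_genome):
        _, truth = synthetic_genome
        assert len(truth.trna_arms) == 22
        assert truth.trna_arms["tRNA-Ser(GCU)"].dhu_arm is None
        assert truth.trna_arms["tRNA-Phe"].dhu_arm is not None

    def test_truth_json_template_round_trip(self, synthetic_genome):
        genome, truth = synthetic_genome
        tpl, seed = mc.SimulationTruth.template_from_json(truth.to_json())
        regen, _ = mc.generate_mitogenome(tpl, seed=seed)
        assert regen.sequence == genome.sequence


class TestOverlaps:
    def test_atp8_atp6_style_overlap_recovered(self):
        tpl = GenomeTemplate(features=(
            _pcg("g1", 67, stop="TAA"),          # 201 bp, like ATP8
            _pcg("g2", 227, stop="TAA", intergenic=-40),  # 681 bp, like ATP6
            _trna("t1", "GAA", intergenic=5),
        ))
        genome, _ = mc.generate_mitogenome(tpl, seed=4)
        rows = mc.build_characterization_table(genome)
        assert [r.intergenic for r in rows] == [0, -40, 5]
        assert rows[0].stop_codon == "TAA" and rows[1].stop_codon == "TAA"

    def test_overlap_as_long_as_gene_rejected_before_sampling(self):
        tpl = GenomeTemplate(features=(
            _pcg("g1", 10),
            _trna("t1", "GAA", length=69, intergenic=-69),
        ))
        with pytest.raises(TemplateError, match="overlap|start"):
            mc.generate_mitogenome(tpl, seed=0)

    def test_stop_type_inconsistent_with_length_rejected(self):
        bad = TemplateFeature(name="g", category="PCG", length=30,
                              start_codon="ATG", stop_type="T--")
        with pytest.raises(TemplateError, match="mod 3"):
            GenomeTemplate(features=(bad,)).validate()

    def test_non_atn_start_rejected(self):
        bad = TemplateFeature(name="g", category="PCG", length=30,
                              start_codon="GTG", stop_type="TAA")
        with pytest.raises(TemplateError, match="ATN"):
            GenomeTemplate(features=(bad,)).validate()


class TestRandomizedTemplates:
    @pytest.mark.parametrize("seed", range(25))
    def test_characterize_of_generate_equals_plan(self, seed):
        rng = np.random.default_rng(1000 + seed)
        feats = []
        for i in range(int(rng.integers(3, 8))):
            gap = int(rng.integers(0, 30))
            kind = rng.choice(["PCG", "tRNA", "rRNA"])
            if kind == "PCG":
                stop = str(rng.choice(["TAA", "TAG", "AGA", "AGG",
                                       "T--", "TA-"]))
                start = str(rng.choice(["ATG", "ATA", "ATT", "ATC"]))
                strand = str(rng.choice(["H", "L"]))
                feats.append(_pcg(f"f{i}", int(rng.integers(10, 80)),
                                  stop=stop, start=start, intergenic=gap,
                                  strand=strand))
            elif kind == "tRNA":
                feats.append(_trna(f"f{i}", str(rng.choice(ANTICODONS)),
                                   length=int(rng.integers(62, 76)),
                                   intergenic=gap,
                                   strand=str(rng.choice(["H", "L"]))))
            else:
                feats.append(TemplateFeature(
                    name=f"f{i}", category="rRNA",
                    length=int(rng.integers(100, 400)), intergenic=gap))
        tpl = GenomeTemplate(features=tuple(feats))
        genome, _ = mc.generate_mitogenome(tpl, seed=seed)
        rows = mc.build_characterization_table(genome)
        for row, tf in zip(rows, tpl.features):
            assert row.length_bp == tf.length
            if tf.category == "PCG":
                assert row.start_codon == tf.start_codon
                assert row.stop_codon == tf.stop_type


class TestCompositionTargets:
    def test_spacer_composition_within_tolerance_at_5kb(self):
        # one large spacer so the sampled composition is measurable
        tpl = GenomeTemplate(features=(
            _trna("t1", "GAA"),
            _trna("t2", "UAC", intergenic=6000),
        ))
        genome, _ = mc.generate_mitogenome(tpl, seed=3)
        spacer = genome.sequence[69 : 69 + 6000]
        counts = collections.Counter(spacer)
        n = sum(counts[b] for b in "ACGT")
        for base, target in zip("ACGT", DEFAULT_COMPOSITION["spacer"]):
            assert abs(100 * counts[base] / n - 100 * target) < 1.5


class TestGenerateTrna:
    def test_anticodon_at_loop_center(self):
        seq, truth = mc.generate_trna("GAA", length=70, seed=6)
        arm = truth.anticodon_arm
        start = arm.loop_start + 2
        assert seq[start - 1 : start + 2] == "GAA"

    def test_deterministic_per_seed(self):
        a, _ = mc.generate_trna("UGC", length=68, seed=5)
        b, _ = mc.generate_trna("UGC", length=68, seed=5)
        c, _ = mc.generate_trna("UGC", length=68, seed=6)
        assert a == b and a != c

    def test_dhu_less_always_folds_degenerate(self):
        # guarantee holds for the anticodon-constrained fold
        for seed in range(5):
            seq, _ = mc.generate_trna("GCU", length=59, dhu_present=False,
                                      seed=seed)
            assert not mc.fold_cloverleaf(seq, anticodon="GCU").dhu_present

    @pytest.mark.parametrize("seed", range(20))
    def test_fold_recovers_construction_or_better(self, seed):
        dhu = seed % 2 == 0
        length = 69 if dhu else 61
        seq, truth = mc.generate_trna("UUC", length=length, dhu_present=dhu,
                                      seed=seed)
        cl = mc.fold_cloverleaf(seq, anticodon="UUC")
        assert cl.dhu_present == dhu
        assert cl.score >= truth.score

    def test_impossible_geometry_rejected(self):
        with pytest.raises(TemplateError, match="geometry"):
            mc.generate_trna("GAA", length=40)


class TestEvolveSequences:
    def test_zero_branch_lengths_keep_root_sequence(self):
        tree = mc.PhyloTree.from_newick("(A:0,B:0,C:0);")
        root = "ACGTACGTAC" * 10
        tips = mc.evolve_sequences(root, tree, mc.PhyloModel(), seed=1)
        assert all(s == root for s in tips.values())

    def test_jc_expected_divergence_within_3_se(self):
        t = 0.1
        n = 100_000
        tree = mc.PhyloTree.from_newick(f"(A:{t},B:0);")
        rng = np.random.default_rng(0)
        root = "".join(rng.choice(list("ACGT"), size=n))
        tips = mc.evolve_sequences(root, tree, mc.PhyloModel(), seed=2)
        p_obs = np.mean([a != b for a, b in zip(tips["A"], tips["B"])])
        p_exp = 0.75 * (1 - np.exp(-4 * t / 3))
        se = np.sqrt(p_exp * (1 - p_exp) / n)
        assert abs(p_obs - p_exp) < 3 * se

    def test_long_branch_converges_to_stationary_frequencies(self):
        freqs = (0.4, 0.3, 0.2, 0.1)
        model = mc.PhyloModel(freqs=freqs)
        tree = mc.PhyloTree.from_newick("(A:25,B:0,C:0);")
        root = "G" * 50_000  # far from stationarity
        tips = mc.evolve_sequences(root, tree, model, seed=7)
        counts = collections.Counter(tips["A"])
        for base, f in zip("ACGT", freqs):
            assert abs(counts[base] / 50_000 - f) < 0.01

    def test_determinism(self):
        tree = mc.PhyloTree.from_newick("(A:0.2,B:0.1,C:0.3);")
        root = "ACGT" * 100
        a = mc.evolve_sequences(root, tree, mc.PhyloModel(alpha=0.5), seed=9)
        b = mc.evolve_sequences(root, tree, mc.PhyloModel(alpha=0.5), seed=9)
        assert a == b
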