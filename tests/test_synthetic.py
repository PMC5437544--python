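import numpy as np
import pytest

from cladefill.gene_filter import build_hint_regions, hint_fscore, write_hints
from cladefill.genome_io import extract_sequences, parse_gtf, read_fasta
from cladefill.hit_scoring import HmmHit
from cladefill.skewt import SkewTParams
from cladefill.synthetic import (
    CladeSpec,
    MockGenePredictor,
    PredictorNoise,
    generate_clade,
    generate_score_samples,
    write_clade,
)


class TestGenerateClade:
    def test_determinism(self):
        spec = CladeSpec(n_species=3, n_families=5, n_hidden=2, seed=7)
        a, b = generate_clade(spec), generate_clade(spec)
        assert a.genomes == b.genomes
        assert {s: sorted(ann.genes) for s, ann in a.annotations.items()} == {
            s: sorted(ann.genes) for s, ann in b.annotations.items()
        }
        assert [g.gene_id for g in a.hidden_genes] == [g.gene_id for g in b.hidden_genes]

    def test_zero_mutation_rate_gives_identical_family_members(self):
        clade = generate_clade(
            CladeSpec(n_species=3, n_families=4, n_hidden=1, mutation_rate=0.0, seed=3)
        )
        for og in clade.orthogroups_full.groups.values():
            proteins = {
                clade.full_annotations[sp].genes[g].protein for sp, g in og.members
            }
            assert len(proteins) == 1

    def test_hidden_genes_absent_from_annotation_present_in_genome(self, small_clade):
        target = small_clade.target_species
        for gene in small_clade.hidden_genes:
            assert gene.gene_id not in small_clade.annotations[target].genes
            assert gene.gene_id in small_clade.full_annotations[target].genes
            contig = small_clade.genomes[target][gene.seq_id]
            assert gene.cds[-1].end <= len(contig)

    def test_hidden_genes_are_discoverable_by_construction(self, small_clade):
        from cladefill.orthogroups import discoverable_genes

        membership = small_clade.orthogroups_full.membership_index()
        target = small_clade.target_species
        for gene in small_clade.hidden_genes:
            og_id = membership[(target, gene.gene_id)]
            og = small_clade.orthogroups_full.groups[og_id]
            assert og.species_set() - {target}, "hidden gene family must span species"

    def test_annotated_genes_translate_cleanly(self, small_clade):
        for sp, ann in small_clade.full_annotations.items():
            for gene in ann:
                assert gene.protein
                assert "*" not in gene.protein
                assert not gene.internal_stop

    def test_intron_mode_produces_multi_interval_genes(self):
        clade = generate_clade(
            CladeSpec(n_species=2, n_families=3, n_hidden=0, max_introns=2, seed=5)
        )
        n_multi = sum(
            len(g.cds) > 1 for ann in clade.full_annotations.values() for g in ann
        )
        assert n_multi > 0

    def test_outputs_roundtrip_through_parsers_without_warnings(
        self, tmp_path, small_clade, caplog
    ):
        write_clade(small_clade, tmp_path)
        with caplog.at_level("WARNING", logger="cladefill"):
            for sp in small_clade.species:
                genome = read_fasta(tmp_path / f"{sp}.genome.fa")
                ann = parse_gtf(tmp_path / f"{sp}.gtf", sp)
                extracted = extract_sequences(ann, genome)
                for gene in extracted:
                    original = small_clade.annotations[sp].genes[gene.gene_id]
                    assert gene.protein == original.protein
        assert not caplog.records


class TestScoreSamples:
    good = SkewTParams(1.2, 0.3, 2.0, 8.0)
    bad = SkewTParams(0.3, 0.2, 2.0, 8.0)

    def test_empty_when_zero_requested(self):
        g, b = generate_score_samples(self.good, self.bad, 0, 10, seed=1)
        assert g.size == 0 and b.size == 10

    def test_same_seed_identical(self):
        a = generate_score_samples(self.good, self.bad, 100, 100, seed=5)
        b = generate_score_samples(self.good, self.bad, 100, 100, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_sample_mean_within_three_standard_errors(self):
        g, _ = generate_score_samples(self.good, self.bad, 10_000, 0, seed=11)
        se = np.sqrt(self.good.var() / g.size)
        assert abs(g.mean() - self.good.mean()) < 3 * se


class TestMockPredictor:
    def hints_for(self, clade, genes, tmp_path):
        hits = [HmmHit("OG", g.span, 100.0) for g in genes]
        path = tmp_path / "hints.gff"
        write_hints(hits, path)
        return path

    def test_zero_noise_reproduces_truth_models(self, tmp_path, small_clade):
        target = small_clade.target_species
        truth = small_clade.full_annotations[target]
        hints = self.hints_for(small_clade, small_clade.hidden_genes, tmp_path)
        predictor = MockGenePredictor(truth)
        predicted = predictor.predict(target, small_clade.genomes[target], hints)
        assert len(predicted) == len(small_clade.hidden_genes)
        predicted_cds = sorted(tuple(g.cds) for g in predicted)
        truth_cds = sorted(tuple(g.cds) for g in small_clade.hidden_genes)
        assert predicted_cds == truth_cds

    def test_split_noise_yields_two_abutting_halves(self, tmp_path, small_clade):
        target = small_clade.target_species
        truth = small_clade.full_annotations[target]
        one = small_clade.hidden_genes[:1]
        hints = self.hints_for(small_clade, one, tmp_path)
        predictor = MockGenePredictor(truth, PredictorNoise(split=True))
        predicted = list(predictor.predict(target, small_clade.genomes[target], hints))
        assert len(predicted) == 2
        a, b = sorted(predicted, key=lambda g: g.cds[0].start)
        assert a.cds[-1].end == b.cds[0].start

    def test_jitter_keeps_long_genes_above_threshold(self, tmp_path, small_clade):
        target = small_clade.target_species
        truth = small_clade.full_annotations[target]
        long_genes = [g for g in truth if g.cds_length >= 900][:3]
        assert long_genes
        hints_path = self.hints_for(small_clade, long_genes, tmp_path)
        hits = [HmmHit("OG", g.span, 100.0) for g in long_genes]
        predictor = MockGenePredictor(truth, PredictorNoise(jitter=30, seed=2))
        predicted = predictor.predict(target, small_clade.genomes[target], hints_path)
        hfs = []
        for gene in predicted:
            for reg in build_hint_regions(hits, gene):
                hfs.append(hint_fscore(reg, gene).hf)
        assert hfs
        assert all(0.8 <= h < 1.0 for h in hfs)

    def test_unknown_contig_in_hints_is_error(self, tmp_path, small_clade):
        target = small_clade.target_species
        hints = tmp_path / "bad.gff"
        hints.write_text("ghost_chr\tx\texonpart\t1\t50\t1\t+\t.\tgrp=OG;src=M\n")
        predictor = MockGenePredictor(small_clade.full_annotations[target])
        with pytest.raises(ValueError, match="ghost_chr"):
            predictor.predict(target, small_clade.genomes[target], hints)
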