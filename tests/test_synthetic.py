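import filecmp
import warnings
from collections import Counter

import numpy as np
import pytest

from editome.io import read_gene_models, read_genome, read_repeats, read_variants
from editome.model import EditingSite, MismatchClass, SampleSupport
from editome.synthetic import (
    SyntheticConfig,
    SyntheticTruth,
    TruthRecord,
    evaluate_recovery,
    generate_reference,
    plant_variants,
    read_truth,
    write_study,
)

SMALL = SyntheticConfig(seed=5, genome_len=120_000, n_genes=10, n_repeats=30,
                        n_edit_sites=25, n_subthreshold_edits=8,
                        n_error_snvs=40, n_known_snps=60, n_private_snps=10)


@pytest.fixture(scope="module")
def study():
    reference = generate_reference(SMALL)
    samples, truth = plant_variants(reference, SMALL)
    return reference, samples, truth


class TestDeterminism:
    def test_same_seed_twice_is_byte_identical(self, tmp_path, study):
        reference, samples, truth = study
        ref2 = generate_reference(SMALL)
        samples2, truth2 = plant_variants(ref2, SMALL)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_study(reference, samples, truth, str(d1))
        p2 = write_study(ref2, samples2, truth2, str(d2))
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_different_seed_differs(self, study):
        reference, _, _ = study
        other = generate_reference(SyntheticConfig(
            **{**SMALL.__dict__, "seed": 6}))
        assert other.assembly.contigs != reference.assembly.contigs


class TestRoundTrips:
    def test_emitted_files_reload_cleanly(self, tmp_path, study, recwarn):
        reference, samples, truth = study
        paths = write_study(reference, samples, truth, str(tmp_path))
        genome = read_genome(paths["genome"])
        assert genome.contigs == reference.assembly.contigs
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            models = read_gene_models(paths["genes"])
        assert len(models) == len(reference.gene_models)
        for mine, parsed in zip(
                sorted(reference.gene_models.genes, key=lambda g: g.id),
                sorted(models.genes, key=lambda g: g.id)):
            assert mine.span == parsed.span and mine.strand == parsed.strand
            assert mine.biotype == parsed.biotype
            assert mine.transcripts[0].exons == parsed.transcripts[0].exons
            assert [c[:2] for c in mine.transcripts[0].cds] == \
                [c[:2] for c in parsed.transcripts[0].cds]
        repeats = read_repeats(paths["repeats"])
        assert len(repeats) == len(reference.repeats)
        for rep in repeats.repeats:
            assert 1 <= rep.start <= rep.end <= genome.length(rep.contig)
        assert read_truth(paths["truth"]).records == truth.records

    def test_vcf_round_trip_preserves_depths(self, tmp_path, study):
        reference, samples, truth = study
        paths = write_study(reference, samples, truth, str(tmp_path))
        key = sorted(samples)[0]
        import os
        vcf = os.path.join(str(tmp_path), "samples", f"{key[0]}_{key[1]}.vcf")
        parsed = read_variants(vcf, key[0], key[1])
        original = samples[key]
        assert len(parsed) == len(original)
        for a, b in zip(parsed, original):
            assert (a.pos, a.ref, a.alt, a.total_depth, a.alt_depth,
                    a.genotype) == (b.pos, b.ref, b.alt, b.total_depth,
                                    b.alt_depth, b.genotype)
            assert a.annotations["HRun"] == b.annotations["HRun"]


class TestTruthInvariants:
    def test_positions_unique_and_classes_expected(self, study):
        _, _, truth = study
        counts = Counter(r.klass for r in truth.records)
        assert counts["edit"] == SMALL.n_edit_sites
        assert counts["subthreshold_edit"] == SMALL.n_subthreshold_edits
        assert counts["error"] == SMALL.n_error_snvs
        assert counts["known_snp"] == SMALL.n_known_snps
        assert counts["private_snp"] == SMALL.n_private_snps

    def test_every_edit_is_a_to_g_on_its_transcribed_strand(self, study):
        reference, _, truth = study
        for rec in truth.of_class("edit"):
            base = reference.assembly.base(rec.contig, rec.pos)
            assert (rec.ref, rec.alt) in {("A", "G"), ("T", "C")}
            assert base == rec.ref
            genes = reference.gene_models.genes_at(rec.contig, rec.pos)
            strands = {g.strand for g in genes}
            if rec.ref == "T":          # minus-strand A on transcribed strand
                assert strands == {"-"}

    def test_edits_recur_in_at_least_two_individuals(self, study):
        _, _, truth = study
        for rec in truth.of_class("edit"):
            assert len(rec.individuals) >= 2

    def test_errors_and_private_snps_are_single_individual(self, study):
        _, _, truth = study
        for rec in truth.of_class("error") + truth.of_class("private_snp"):
            assert len(rec.individuals) == 1

    def test_cluster_members_span_within_double_window(self, study):
        _, _, truth = study
        by_cluster = {}
        for rec in truth.of_class("edit"):
            if rec.cluster_id:
                by_cluster.setdefault(rec.cluster_id, []).append(rec.pos)
        assert by_cluster, "expected at least one planted cluster"
        for positions in by_cluster.values():
            positions.sort()
            assert all(b - a <= 100 for a, b in zip(positions, positions[1:]))

    def test_known_snps_in_every_individual_and_catalogue(self, study):
        reference, samples, truth = study
        catalogue = {p for (_c, p, _r, _a) in reference.known_snps}
        for rec in truth.of_class("known_snp")[:20]:
            assert rec.pos in catalogue
            seen = {ind for (ind, _t), obs in samples.items()
                    for o in obs if o.pos == rec.pos}
            assert seen == set(SMALL.individuals)
        for rec in truth.of_class("private_snp"):
            assert rec.pos not in catalogue

    def test_binomial_sampling_tracks_true_ratio(self, study):
        _, samples, truth = study
        pooled = {}
        for obs_list in samples.values():
            for o in obs_list:
                pooled.setdefault(o.pos, []).append((o.alt_depth, o.total_depth))
        for rec in truth.of_class("edit"):
            depths = pooled.get(rec.pos, [])
            if sum(d for _a, d in depths) < 200:
                continue
            observed = sum(a for a, _d in depths) / sum(d for _a, d in depths)
            assert observed == pytest.approx(rec.true_ratio, abs=0.15)


class TestRecovery:
    def site(self, pos):
        return EditingSite(contig="chr1", pos=pos, ref="A", alt="G",
                           mismatch=MismatchClass("A>G", "+", "gene"),
                           supports=[SampleSupport("b", "t", 0.3, 9, 30)])

    def truth(self):
        recs = [TruthRecord("chr1", p, "edit", "A", "G", 0.3, ("b1", "b2"),
                            ("liver",)) for p in (10, 20, 30)]
        recs.append(TruthRecord("chr1", 40, "error", "C", "T", 0.1, ("b1",),
                                ("liver",)))
        return SyntheticTruth(records=recs)

    def test_perfect_calls(self):
        report = evaluate_recovery([self.site(p) for p in (10, 20, 30)],
                                   self.truth())
        assert report.precision == report.recall == 1.0

    def test_empty_calls_na_precision(self):
        report = evaluate_recovery([], self.truth())
        assert report.precision is None and report.recall == 0.0

    def test_confusion_matrix_brute_force(self):
        calls = [self.site(p) for p in (10, 40, 99)]
        report = evaluate_recovery(calls, self.truth())
        assert (report.tp, report.fp, report.fn) == (1, 2, 2)
        assert report.fp_by_category == {"error": 1, "none": 1}
        assert report.precision == pytest.approx(1 / 3)
        assert report.recall == pytest.approx(1 / 3)
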