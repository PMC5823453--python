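import math

import numpy as np
import pytest
from Bio import Align

from editome.align import smith_waterman
from editome.config import ThresholdConfig
from editome.model import (
    EditingSite,
    GenomeAssembly,
    MismatchClass,
    SampleSupport,
    revcomp,
)
from editome.motif import (
    StrandResolutionError,
    extract_flanks,
    neighbor_pfm,
)
from editome.validation import (
    ValidationProfile,
    hits_from_tabular,
    karlin_altschul_lambda,
    match_reference,
)

CFG = ThresholdConfig()


def a_site(pos, strand="+", contig="c1"):
    ref, alt = ("A", "G")
    return EditingSite(contig=contig, pos=pos, ref=ref, alt=alt,
                       mismatch=MismatchClass("A>G", strand, "gene"),
                       supports=[SampleSupport("bull1", "liver", 0.3, 9, 30)])


class TestFlanks:
    def test_plus_strand_window(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("CGT"), size=400))
        seq = seq[:200] + "A" + seq[201:]
        genome = GenomeAssembly({"c1": seq})
        window = extract_flanks(a_site(201), genome, flank=50)
        assert len(window.seq) == 101 and window.center == 50
        assert window.seq == seq[150:251]
        assert not window.clipped

    def test_minus_strand_reverse_complemented(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACG"), size=400))
        seq = seq[:200] + "T" + seq[201:]      # genomic T = transcribed A on −
        genome = GenomeAssembly({"c1": seq})
        window = extract_flanks(a_site(201, strand="-"), genome, flank=50)
        assert window.seq == revcomp(seq[150:251])
        assert window.seq[window.center] == "A"

    def test_clipped_near_contig_start(self):
        genome = GenomeAssembly({"c1": "C" * 19 + "A" + "C" * 400})
        window = extract_flanks(a_site(20), genome, flank=50)
        assert window.clipped and len(window.seq) == 70

    def test_center_not_a_is_an_error(self):
        genome = GenomeAssembly({"c1": "C" * 401})
        with pytest.raises(StrandResolutionError):
            extract_flanks(a_site(201), genome, flank=50)


class TestPFM:
    def test_forced_tag_context(self):
        seq = ("G" * 50 + "TAG" + "G" * 50) * 2
        genome = GenomeAssembly({"c1": seq})
        sites = [a_site(52), a_site(52 + 103)]
        pfm = neighbor_pfm(sites, genome, CFG)
        assert pfm.base_fraction(0, "A") == 1.0
        assert pfm.base_fraction(-1, "T") == 1.0
        assert pfm.base_fraction(+1, "G") == 1.0
        assert pfm.column_total(0) == 2

    def test_uniform_contexts_have_near_zero_information(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=30_000))
        positions = [i + 1 for i, b in enumerate(seq) if b == "A"][200:1200]
        genome = GenomeAssembly({"c1": seq})
        pfm = neighbor_pfm([a_site(p) for p in positions], genome, CFG)
        ic = pfm.information_content()
        assert ic.loc[0] == pytest.approx(2.0)        # pure A at center
        nonzero = [ic.loc[p] for p in pfm.positions if p != 0]
        assert max(nonzero) < 0.02

    def test_column_sums_conserved_with_clipping(self):
        seq = list("C" * 306)
        seq[5] = seq[199] = "A"          # sites at 1-based 6 and 200
        genome = GenomeAssembly({"c1": "".join(seq)})
        pfm = neighbor_pfm([a_site(6), a_site(200)], genome, CFG)
        # left-clipped site misses columns −10..−6
        assert pfm.column_total(-10) == 1
        assert pfm.column_total(0) == 2


class TestSmithWaterman:
    def oracle(self):
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 1
        aligner.mismatch_score = -2
        aligner.open_gap_score = -7
        aligner.extend_gap_score = -2
        return aligner

    def test_scores_match_biopython_on_random_pairs(self):
        rng = np.random.default_rng(11)
        aligner = self.oracle()
        for _ in range(40):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 80))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 120))))
            assert smith_waterman(a, b).score == pytest.approx(aligner.score(a, b))

    def test_perfect_match_statistics(self):
        aln = smith_waterman("ACGTACGTAC", "TTACGTACGTACTT")
        assert aln.score == 10 and aln.identity == 1.0 and aln.columns == 10


class TestMatchReference:
    def make_flank(self, rng):
        return "".join(rng.choice(list("ACGT"), size=101))

    def test_verbatim_flank_counted(self):
        rng = np.random.default_rng(13)
        flank = self.make_flank(rng)
        refs = [self.make_flank(rng) for _ in range(5)] + [flank]
        hits = match_reference([flank], refs, ValidationProfile.est(CFG))
        assert hits[0].n_hits == 1
        assert hits[0].best_identity == 1.0
        assert hits[0].best_alnlen == 101

    def test_reverse_complement_reference_found(self):
        rng = np.random.default_rng(17)
        flank = self.make_flank(rng)
        hits = match_reference([flank], [revcomp(flank)],
                               ValidationProfile.est(CFG))
        assert hits[0].n_hits == 1

    def test_low_identity_rejected_under_conservation_profile(self):
        rng = np.random.default_rng(19)
        flank = self.make_flank(rng)
        diverged = list(flank)
        for i in rng.choice(101, size=20, replace=False):   # ~80% identity
            diverged[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[diverged[i]]
        diverged = "".join(diverged)
        cons = match_reference([flank], [diverged],
                               ValidationProfile.conservation(CFG))
        assert cons[0].n_hits == 0

    def test_order_invariance_and_threshold_monotonicity(self):
        rng = np.random.default_rng(23)
        flank = self.make_flank(rng)
        near = list(flank)
        for i in rng.choice(101, size=8, replace=False):
            near[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[near[i]]
        refs = [self.make_flank(rng), "".join(near), flank]
        profile = ValidationProfile.conservation(CFG)
        forward = match_reference([flank], refs, profile)
        backward = match_reference([flank], refs[::-1], profile)
        assert forward[0].n_hits == backward[0].n_hits
        looser = ValidationProfile("loose", profile.max_evalue * 100,
                                   0.5, profile.min_alnlen)
        assert match_reference([flank], refs, looser)[0].n_hits >= \
            forward[0].n_hits

    def test_empty_reference_warns_and_zeroes(self):
        hits = match_reference(["A" * 101], [], ValidationProfile.est(CFG))
        assert hits[0].n_hits == 0 and math.isinf(hits[0].best_evalue)

    def test_agrees_with_exhaustive_sw_oracle(self):
        """Support counts equal a from-scratch Biopython scan with the same
        e-value/identity thresholds."""
        rng = np.random.default_rng(29)
        flanks = [self.make_flank(rng) for _ in range(4)]
        refs = []
        for flank in flanks[:2]:
            near = list(flank)
            for i in rng.choice(101, size=6, replace=False):
                near[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[near[i]]
            refs.append("".join(near))
        refs += [self.make_flank(rng) for _ in range(6)]
        profile = ValidationProfile.est(CFG)
        got = match_reference(flanks, refs, profile)

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 1
        aligner.mismatch_score = -2
        aligner.open_gap_score = -7
        aligner.extend_gap_score = -2
        lam = karlin_altschul_lambda()
        db = sum(len(r) for r in refs)
        for flank, stats in zip(flanks, got):
            expected = 0
            for ref in refs:
                score = max(aligner.score(flank, ref),
                            aligner.score(flank, revcomp(ref)))
                e = 0.621 * len(flank) * db * math.exp(-lam * score)
                if e <= profile.max_evalue:
                    expected += 1
            assert stats.n_hits == expected


def test_lambda_solves_the_score_equation():
    lam = karlin_altschul_lambda()
    assert 0.25 * math.exp(lam) + 0.75 * math.exp(-2 * lam) == pytest.approx(1.0)
    assert lam == pytest.approx(1.33, abs=0.01)


def test_tabular_ingest_applies_profile(tmp_path):
    rows = [
        "q1\tr1\t98.0\t101\t2\t0\t1\t101\t1\t101\t1e-40\t180",
        "q1\tr2\t80.0\t101\t20\t0\t1\t101\t1\t101\t1e-10\t90",
        "q2\tr1\t99.0\t40\t1\t0\t1\t40\t1\t40\t1e-12\t70",
    ]
    path = tmp_path / "hits.tsv"
    path.write_text("\n".join(rows) + "\n")
    est = hits_from_tabular(str(path), ValidationProfile("est", 1e-5))
    assert est == {"q1": 2, "q2": 1}
    cons = hits_from_tabular(str(path),
                             ValidationProfile("cons", 1e-3, 0.85, 50))
    assert cons == {"q1": 1}
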