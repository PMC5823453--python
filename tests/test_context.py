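import numpy as np
import pytest
from Bio import Align

from editome.config import ThresholdConfig
from editome.context import (
    SSRInterval,
    bidirectional_overlap,
    find_ssrs,
    flank_uniqueness,
    homopolymer_run,
    in_ssr_zone,
    near_splice_junction,
)
from editome.model import Gene, GeneModelSet, GenomeAssembly, Transcript, revcomp

CFG = ThresholdConfig()


# --- independent brute-force SSR oracle ------------------------------------

def _primitive(motif):
    m = len(motif)
    return not any(m % d == 0 and motif == motif[:d] * (m // d)
                   for d in range(1, m))


def brute_force_ssrs(seq, min_total=6, max_motif=8):
    """Naive O(n²·m) enumeration of maximal perfect tandem repeats."""
    n = len(seq)
    found = set()
    for m in range(1, max_motif + 1):
        for i in range(n - m):
            if any(b not in "ACGT" for b in seq[i:i + m]):
                continue
            # maximal to the left?
            if i >= 1 and i + m - 1 < n and seq[i - 1] == seq[i + m - 1]:
                continue
            j = i + m
            while j < n and seq[j] == seq[j - m] and seq[j] in "ACGT":
                j += 1
            span = j - i
            if span < max(min_total, 2 * m):
                continue
            if not _primitive(seq[i:i + m]):
                continue
            motif = min(seq[i + k:i + m] + seq[i:i + k] for k in range(m))
            found.add((i + 1, j, motif, span // m))
    return found


class TestSSR:
    def test_forced_example(self):
        ssrs = find_ssrs("GGACACACTT", CFG)
        assert len(ssrs) == 1
        s = ssrs[0]
        assert (s.start, s.end, s.motif, s.total_len, s.copies) == (3, 8, "AC", 6, 3)

    def test_homopolymer_run_reported_once_as_single_base(self):
        ssrs = find_ssrs("TTTTTT", CFG)
        assert [(s.motif, s.total_len) for s in ssrs] == [("T", 6)]

    def test_n_never_in_ssr(self):
        assert find_ssrs("AANAAANAAA", CFG) == []

    def test_partial_trailing_copy_extends_span(self):
        s = find_ssrs("GACACACATT", CFG)[0]
        # span ACACACA (7 nt): three full AC copies plus a partial one
        assert (s.start, s.end, s.total_len, s.copies) == (2, 8, 7, 3)

    def test_matches_brute_force_on_random_battery(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            seq = "".join(rng.choice(list("ACGTN"), size=200,
                                     p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            got = {(s.start, s.end, s.motif, s.copies)
                   for s in find_ssrs(seq, CFG)}
            assert got == brute_force_ssrs(seq)


class TestSSRZone:
    SSRS = [SSRInterval("c1", 100, 110, "AC", 5)]

    @pytest.mark.parametrize("pos,expected", [
        (97, True),      # start - 3
        (96, False),
        (105, True),
        (113, True),     # end + 3
        (114, False),
    ])
    def test_offset_boundaries(self, pos, expected):
        assert in_ssr_zone(pos, self.SSRS, CFG) is expected

    def test_monotone_in_offset(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            pos = int(rng.integers(80, 130))
            hit_small = in_ssr_zone(pos, self.SSRS, ThresholdConfig(ssr_offset=2))
            hit_large = in_ssr_zone(pos, self.SSRS, ThresholdConfig(ssr_offset=3))
            assert not hit_small or hit_large


class TestHomopolymer:
    def test_left_run_of_alt_base(self):
        genome = GenomeAssembly({"c1": "TTTTTTAC"})
        assert homopolymer_run(genome, "c1", 7, "T") == 6

    def test_right_run(self):
        genome = GenomeAssembly({"c1": "GCAGGG"})
        assert homopolymer_run(genome, "c1", 3, "G") == 3

    def test_matches_naive_scan_on_random_contexts(self):
        rng = np.random.default_rng(23)
        seq = "".join(rng.choice(list("ACGT"), size=500, p=[0.4, 0.1, 0.1, 0.4]))
        genome = GenomeAssembly({"c1": seq})
        for _ in range(200):
            pos = int(rng.integers(2, 500))
            alt = "ACGT"[int(rng.integers(4))]
            left = right = 0
            i = pos - 2
            while i >= 0 and seq[i] == alt:
                left += 1
                i -= 1
            i = pos
            while i < len(seq) and seq[i] == alt:
                right += 1
                i += 1
            assert homopolymer_run(genome, "c1", pos, alt) == max(left, right)


def _intron_gene():
    return GeneModelSet([Gene(
        id="g", symbol="G", biotype="protein_coding", contig="c1", strand="+",
        transcripts=[Transcript(id="t", exons=[(901, 1000), (1101, 1200)])])])


class TestSpliceJunction:
    @pytest.mark.parametrize("pos,expected", [
        (1003, True),     # 3 bp into the intron (1001..1100)
        (1005, True),     # 5th intronic base
        (1006, False),    # 6 bp inside
        (1096, True),     # 5 bp from the downstream exon
        (1095, False),
        (950, False),     # exonic
    ])
    def test_five_bp_margin(self, pos, expected):
        assert near_splice_junction(_intron_gene(), "c1", pos, CFG) is expected


class TestBidirectional:
    def test_cross_strand_only(self, gene_fixture):
        assert bidirectional_overlap(gene_fixture, "c2", 700) is True
        assert bidirectional_overlap(gene_fixture, "c2", 200) is False
        assert bidirectional_overlap(gene_fixture, "c1", 1500) is False

    def test_two_same_strand_genes_not_bidirectional(self):
        a = Gene(id="a", symbol="A", biotype="protein_coding", contig="c1",
                 strand="+", transcripts=[Transcript(id="ta", exons=[(100, 500)])])
        b = Gene(id="b", symbol="B", biotype="protein_coding", contig="c1",
                 strand="+", transcripts=[Transcript(id="tb", exons=[(300, 700)])])
        assert bidirectional_overlap(GeneModelSet([a, b]), "c1", 400) is False


# --- flank uniqueness -------------------------------------------------------

def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate(rng, seq, n_subs):
    out = list(seq)
    for i in rng.choice(len(seq), size=n_subs, replace=False):
        out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
    return "".join(out)


def sw_oracle_hits(window, genome, min_identity=0.9, min_cov=0.9):
    """Count distinct qualifying loci with Biopython's local aligner by
    iterative best-hit masking (independent of the package's seeded scan)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    hits = 0
    for name, seq in genome.contigs.items():
        for target in (seq, revcomp(seq)):
            work = target
            for _ in range(6):
                try:
                    aln = aligner.align(window, work)[0]
                except (IndexError, ValueError):
                    break
                cols = matches = 0
                for (qs, qe), (ts, te) in zip(*aln.aligned):
                    cols += qe - qs
                    matches += sum(a == b for a, b in
                                   zip(window[qs:qe], work[ts:te]))
                # count gap columns between aligned blocks
                qblocks, tblocks = aln.aligned
                for i in range(1, len(qblocks)):
                    cols += max(qblocks[i][0] - qblocks[i - 1][1],
                                tblocks[i][0] - tblocks[i - 1][1])
                if cols < min_cov * len(window) or matches / cols < min_identity:
                    break
                hits += 1
                t0, t1 = tblocks[0][0], tblocks[-1][1]
                work = work[:t0] + "N" * (t1 - t0) + work[t1:]
    return hits


class TestFlankUniqueness:
    def test_verbatim_duplicate_is_non_unique(self):
        rng = np.random.default_rng(31)
        seq = list(_random_seq(rng, 40_000))
        window = seq[9950:10051]
        seq[29949:30050] = window
        genome = GenomeAssembly({"c1": "".join(seq)})
        assert not flank_uniqueness(genome, "c1", 10_000, CFG)

    def test_random_window_is_unique(self):
        rng = np.random.default_rng(37)
        genome = GenomeAssembly({"c1": _random_seq(rng, 50_000)})
        res = flank_uniqueness(genome, "c1", 25_000, CFG)
        assert res.unique and res.n_hits == 1

    def test_95pct_copy_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(41)
        seq = list(_random_seq(rng, 40_000))
        window = "".join(seq[9950:10051])
        seq[29949:30050] = list(_mutate(rng, window, 5))     # ~95% identity
        genome = GenomeAssembly({"c1": "".join(seq)})
        result = flank_uniqueness(genome, "c1", 10_000, CFG)
        oracle = sw_oracle_hits(window, genome)
        assert result.n_hits == oracle == 2
        assert not result.unique

    def test_revcomp_genome_invariance(self):
        rng = np.random.default_rng(43)
        seq = _random_seq(rng, 30_000)
        genome = GenomeAssembly({"c1": seq})
        flipped = GenomeAssembly({"c1": revcomp(seq)})
        pos = 12_345
        mirrored = len(seq) - pos + 1
        assert flank_uniqueness(genome, "c1", pos, CFG).unique == \
            flank_uniqueness(flipped, "c1", mirrored, CFG).unique

    def test_all_n_window_is_non_unique(self):
        rng = np.random.default_rng(47)
        seq = _random_seq(rng, 5000)
        seq = seq[:2000] + "N" * 101 + seq[2101:]
        genome = GenomeAssembly({"c1": seq})
        assert not flank_uniqueness(genome, "c1", 2051, CFG)

    def test_clipped_window_flagged(self):
        rng = np.random.default_rng(53)
        genome = GenomeAssembly({"c1": _random_seq(rng, 5000)})
        assert flank_uniqueness(genome, "c1", 20, CFG).clipped
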