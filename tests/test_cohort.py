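import math

import numpy as np
import pytest

from editome.cohort import (
    all_pairwise_comparisons,
    benjamini_hochberg,
    compare_editing_ratios,
    expression_editing_correlation,
    mismatch_spectrum,
    recurrence_filter,
    shared_site_counts,
    site_tissue_matrix,
    tissue_specific_sites,
)
from editome.config import ThresholdConfig
from editome.mismatch import classify_mismatch
from editome.model import EditingSite, MismatchClass, SampleSupport

from conftest import make_variant

CFG = ThresholdConfig()
A2I = MismatchClass("A>G", "+", "gene")


def make_site(pos=100, tissues=("liver",), ratios=None, label="A>G",
              individuals=None):
    ratios = ratios or [0.3] * len(tissues)
    individuals = individuals or [f"bull{i % 3 + 1}" for i in range(len(tissues))]
    supports = [SampleSupport(ind, t, r, 10, 30)
                for ind, t, r in zip(individuals, tissues, ratios)]
    return EditingSite(contig="c1", pos=pos, ref=label[0], alt=label[2],
                       mismatch=MismatchClass(label, "+", "gene"),
                       supports=supports)


class TestRecurrence:
    def pair(self, pos, individual, tissue):
        v = make_variant(pos=pos, individual=individual, tissue=tissue)
        return (v, A2I)

    def test_two_individuals_same_tissue_kept(self):
        sites = recurrence_filter([self.pair(100, "bull1", "liver"),
                                   self.pair(100, "bull2", "liver")], CFG)
        assert len(sites) == 1 and sites[0].tissues == {"liver"}

    def test_single_individual_dropped(self):
        assert recurrence_filter([self.pair(100, "bull1", "liver")], CFG) == []

    def test_cross_tissue_recurrence_allowed(self):
        sites = recurrence_filter([self.pair(100, "bull1", "liver"),
                                   self.pair(100, "bull2", "brain")], CFG)
        assert len(sites) == 1 and sites[0].tissues == {"liver", "brain"}

    def test_same_tissue_mode_is_stricter(self):
        cfg = ThresholdConfig(recurrence_same_tissue=True)
        pairs = [self.pair(100, "bull1", "liver"),
                 self.pair(100, "bull2", "brain")]
        assert recurrence_filter(pairs, cfg) == []
        assert len(recurrence_filter(pairs, CFG)) == 1

    def test_unique_keys_and_strand_grouping(self):
        # a genomic T>C on a minus-strand gene groups with its A>G key
        minus = MismatchClass("A>G", "-", "gene")
        pairs = [(make_variant(pos=200, ref="T", alt="C",
                               individual="bull1"), minus),
                 (make_variant(pos=200, ref="T", alt="C",
                               individual="bull2"), minus)]
        sites = recurrence_filter(pairs, CFG)
        assert len(sites) == 1
        assert (sites[0].ref, sites[0].alt) == ("A", "G")
        keys = [s.key for s in sites]
        assert len(keys) == len(set(keys))


class TestTissueLogic:
    def test_specificity_partition(self):
        rng = np.random.default_rng(9)
        tissues = ["brain", "liver", "lung", "kidney"]
        sites = []
        for i in range(200):
            chosen = [t for t in tissues if rng.random() < 0.4] or ["brain"]
            sites.append(make_site(pos=i + 1, tissues=tuple(chosen)))
        specific = tissue_specific_sites(sites)
        n_specific = sum(len(v) for v in specific.values())
        n_multi = sum(1 for s in sites if len(s.tissues) > 1)
        assert n_specific + n_multi == len(sites)
        for tissue, group in specific.items():
            assert all(s.tissues == {tissue} for s in group)

    def test_shared_counts_brute_force(self):
        rng = np.random.default_rng(10)
        tissues = [f"t{i}" for i in range(9)]
        sites = []
        for i in range(150):
            chosen = [t for t in tissues if rng.random() < 0.5] or [tissues[0]]
            sites.append(make_site(pos=i + 1, tissues=tuple(chosen)))
        for k in (1, 2, 5, 9, 10):
            expected = sum(1 for s in sites if len(s.tissues) >= k)
            assert shared_site_counts(sites, k) == expected
        assert shared_site_counts(sites, 1) == len(sites)
        assert shared_site_counts(sites, 10) == 0
        with pytest.raises(ValueError):
            shared_site_counts(sites, 0)


class TestSpectrum:
    def test_headline_fraction(self):
        labels = ["A>G"] * 697 + ["C>T"] * 21 + ["G>A"] * 76
        summary = mismatch_spectrum(labels)
        assert summary.total == 794
        assert summary.a_to_i_fraction == pytest.approx(87.78, abs=0.01)
        assert round(summary.a_to_i_fraction) == 88

    def test_all_a_to_g(self):
        assert mismatch_spectrum(["A>G"] * 10).a_to_i_fraction == 100.0

    def test_counts_match_tabulation_oracle(self):
        rng = np.random.default_rng(11)
        from editome.model import MISMATCH_LABELS
        labels = [MISMATCH_LABELS[i]
                  for i in rng.integers(0, 12, size=1200)]
        summary = mismatch_spectrum(labels)
        for lab in MISMATCH_LABELS:
            assert summary.counts[lab] == labels.count(lab)
        assert sum(summary.percentage(lab) for lab in MISMATCH_LABELS) == \
            pytest.approx(100.0)


class TestStatistics:
    def test_identical_vectors_give_t0_p1(self):
        sites = ([make_site(pos=i, tissues=("a",), ratios=[r])
                  for i, r in enumerate([0.2, 0.3, 0.4], 1)]
                 + [make_site(pos=i + 10, tissues=("b",), ratios=[r])
                    for i, r in enumerate([0.2, 0.3, 0.4], 1)])
        comp = compare_editing_ratios(sites, "a", "b", CFG)
        assert comp.t == pytest.approx(0.0)
        assert comp.p == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        # a=(0.2,0.3,0.4), b=(0.6,0.7,0.8): sp²=0.01, se=0.1·√(2/3),
        # t = −0.4/0.08165 = −4.899, df=4 → p≈0.008065
        sites = ([make_site(pos=i, tissues=("a",), ratios=[r])
                  for i, r in enumerate([0.2, 0.3, 0.4], 1)]
                 + [make_site(pos=i + 10, tissues=("b",), ratios=[r])
                    for i, r in enumerate([0.6, 0.7, 0.8], 1)])
        comp = compare_editing_ratios(sites, "a", "b", CFG)
        assert comp.t == pytest.approx(-4.8990, abs=1e-3)
        assert comp.p == pytest.approx(0.00806, abs=1e-4)

    def test_degenerate_equal_constant_vectors(self):
        sites = ([make_site(pos=1, tissues=("a",), ratios=[0.5]),
                  make_site(pos=2, tissues=("a",), ratios=[0.5]),
                  make_site(pos=3, tissues=("b",), ratios=[0.5]),
                  make_site(pos=4, tissues=("b",), ratios=[0.5])])
        comp = compare_editing_ratios(sites, "a", "b", CFG)
        assert comp.p == 1.0

    def test_bh_step_up_by_hand(self):
        qs = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert qs == pytest.approx([0.04, 0.04, 0.04, 0.04])
        # monotone non-decreasing in sorted-p order, and q >= p
        ps = [0.001, 0.2, 0.04, 0.9, 0.01]
        qs = benjamini_hochberg(ps)
        paired = sorted(zip(ps, qs))
        assert all(q1 <= q2 for (_, q1), (_, q2) in zip(paired, paired[1:]))
        assert all(q >= p for p, q in zip(ps, qs))

    def test_pairwise_fills_q(self):
        rng = np.random.default_rng(12)
        sites = []
        for i in range(60):
            tissues = tuple(t for t in ("a", "b", "c") if rng.random() < 0.8)
            if not tissues:
                continue
            sites.append(make_site(pos=i + 1, tissues=tissues,
                                   ratios=list(rng.uniform(0.1, 0.9,
                                                           len(tissues)))))
        comps = all_pairwise_comparisons(sites, ("a", "b", "c"), CFG)
        assert len(comps) == 3
        assert all(not math.isnan(c.q) for c in comps)


class TestCorrelation:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, _ = expression_editing_correlation(x, [2 * v for v in x])
        assert r == pytest.approx(1.0)
        r, _ = expression_editing_correlation(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_matches_definitional_formula(self):
        rng = np.random.default_rng(14)
        x = rng.uniform(0, 100, size=9)
        y = rng.uniform(0, 50, size=9)
        r, _ = expression_editing_correlation(list(x), list(y))
        expected = (np.mean((x - x.mean()) * (y - y.mean()))
                    / (x.std() * y.std()))
        assert r == pytest.approx(expected)

    def test_too_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            expression_editing_correlation([1, 2], [3, 4])


def test_tissue_matrix_has_na_for_absent():
    sites = [make_site(pos=1, tissues=("a", "b"), ratios=[0.2, 0.4]),
             make_site(pos=2, tissues=("b",), ratios=[0.6])]
    frame = site_tissue_matrix(sites, ["a", "b"])
    assert frame.loc["c1:1", "a"] == pytest.approx(0.2)
    assert np.isnan(frame.loc["c1:2", "a"])
    assert frame.loc["c1:2", "b"] == pytest.approx(0.6)
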