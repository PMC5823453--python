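"""Cross-sample logic: biological-replicate recurrence, tissue assignment
and specificity, mismatch-spectrum summaries, editing-ratio statistics and
ADAR-expression correlation.

The recurrence rule is the pipeline's main defence against private SNPs and
sequencing errors: a candidate must be observed in at least two distinct
individuals (any tissue) to survive, on the premise that genuine editing is
shared within a species while rare SNPs and artefacts are not.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .config import ThresholdConfig, DEFAULT_CONFIG
from .filters import editing_ratio
from .mismatch import classify_mismatch, transcribed_alleles
from .model import (
    EditingSite,
    GeneModelSet,
    MISMATCH_LABELS,
    MismatchClass,
    SampleSupport,
    VariantObservation,
)


def recurrence_filter(candidates: Iterable[tuple[VariantObservation, MismatchClass]],
                      config: ThresholdConfig = DEFAULT_CONFIG,
                      ) -> list[EditingSite]:
    """Group per-sample candidates by transcribed-strand site and keep those
    recurring in >= ``min_individuals`` distinct individuals.

    ``candidates`` pairs each passing observation with its mismatch class.
    With ``recurrence_same_tissue`` set, the individuals must share at least
    one tissue; by default any-tissue recurrence counts.
    """
    groups: dict[tuple, list[tuple[VariantObservation, MismatchClass]]] = defaultdict(list)
    for obs, klass in candidates:
        ref, alt = transcribed_alleles(obs, klass.strand)
        groups[(obs.contig, obs.pos, ref, alt)].append((obs, klass))

    sites: list[EditingSite] = []
    for (contig, pos, ref, alt), members in sorted(groups.items()):
        if config.recurrence_same_tissue:
            by_tissue = defaultdict(set)
            for obs, _ in members:
                by_tissue[obs.tissue].add(obs.individual)
            if max((len(v) for v in by_tissue.values()), default=0) < config.min_individuals:
                continue
        else:
            individuals = {obs.individual for obs, _ in members}
            if len(individuals) < config.min_individuals:
                continue
        supports = [SampleSupport(obs.individual, obs.tissue,
                                  editing_ratio(obs), obs.alt_depth,
                                  obs.total_depth)
                    for obs, _ in members]
        sites.append(EditingSite(contig=contig, pos=pos, ref=ref, alt=alt,
                                 mismatch=members[0][1], supports=supports,
                                 origin="high_confidence"))
    return sites


def tissue_specific_sites(sites: Sequence[EditingSite]) -> dict[str, list[EditingSite]]:
    """Sites supported in exactly one tissue, keyed by that tissue."""
    out: dict[str, list[EditingSite]] = defaultdict(list)
    for site in sites:
        tissues = site.tissues
        if len(tissues) == 1:
            out[next(iter(tissues))].append(site)
    return dict(out)


def shared_site_counts(sites: Sequence[EditingSite], k: int) -> int:
    """Number of sites present in at least ``k`` tissues."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return sum(1 for s in sites if len(s.tissues) >= k)


@dataclass
class SpectrumSummary:
    """Counts of the 12 mismatch classes, overall and (optionally) per tissue."""

    counts: Counter
    per_tissue: dict[str, Counter] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def percentage(self, label: str) -> float:
        return 100.0 * self.counts.get(label, 0) / self.total if self.total else 0.0

    @property
    def a_to_i_fraction(self) -> float:
        """Share of A>G (A-to-I) sites, in percent."""
        return self.percentage("A>G")

    def to_frame(self) -> pd.DataFrame:
        rows = {"all": {lab: self.counts.get(lab, 0) for lab in MISMATCH_LABELS}}
        for tissue, counter in sorted(self.per_tissue.items()):
            rows[tissue] = {lab: counter.get(lab, 0) for lab in MISMATCH_LABELS}
        return pd.DataFrame(rows).T


def mismatch_spectrum(labelled: Iterable, by_tissue: bool = False) -> SpectrumSummary:
    """Tabulate mismatch classes.

    Accepts EditingSite objects, plain label strings, or (label, tissues)
    pairs; per-tissue counts are filled when requested and available.
    """
    counts: Counter = Counter()
    per_tissue: dict[str, Counter] = defaultdict(Counter)
    for item in labelled:
        if isinstance(item, EditingSite):
            label, tissues = item.mismatch.label, item.tissues
        elif isinstance(item, MismatchClass):
            label, tissues = item.label, ()
        elif isinstance(item, str):
            label, tissues = item, ()
        else:
            label, tissues = item
        counts[label] += 1
        if by_tissue:
            for tissue in tissues:
                per_tissue[tissue][label] += 1
    return SpectrumSummary(counts=counts, per_tissue=dict(per_tissue))


def site_tissue_matrix(sites: Sequence[EditingSite],
                       tissues: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Site × tissue matrix of mean editing ratios (NaN where absent)."""
    if tissues is None:
        tissues = sorted({t for s in sites for t in s.tissues})
    index = [f"{s.contig}:{s.pos}" for s in sites]
    data = np.full((len(sites), len(tissues)), np.nan)
    for i, site in enumerate(sites):
        for j, tissue in enumerate(tissues):
            if tissue in site.tissues:
                data[i, j] = site.tissue_ratio(tissue)
    return pd.DataFrame(data, index=index, columns=list(tissues))


@dataclass
class PairwiseComparison:
    tissue_a: str
    tissue_b: str
    t: float
    p: float
    q: float = float("nan")
    n_a: int = 0
    n_b: int = 0


def compare_editing_ratios(sites: Sequence[EditingSite],
                           tissue_a: str, tissue_b: str,
                           config: ThresholdConfig = DEFAULT_CONFIG,
                           ) -> PairwiseComparison:
    """Two-sample t-test on per-site mean editing ratios of two tissues.

    Pooled-variance (classic Student) by default; the Welch variant is a
    config switch. Degenerate inputs (zero variance both sides, equal
    means) get p = 1 by convention.
    """
    a = [s.tissue_ratio(tissue_a) for s in sites if tissue_a in s.tissues]
    b = [s.tissue_ratio(tissue_b) for s in sites if tissue_b in s.tissues]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each tissue needs at least two ratio observations")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        return PairwiseComparison(tissue_a, tissue_b, 0.0, 1.0,
                                  n_a=len(a), n_b=len(b))
    t, p = sp_stats.ttest_ind(a, b, equal_var=not config.welch_t)
    return PairwiseComparison(tissue_a, tissue_b, float(t), float(p),
                              n_a=len(a), n_b=len(b))


def all_pairwise_comparisons(sites: Sequence[EditingSite],
                             tissues: Optional[Sequence[str]] = None,
                             config: ThresholdConfig = DEFAULT_CONFIG,
                             ) -> list[PairwiseComparison]:
    """All tissue-pair t-tests with Benjamini–Hochberg q-values."""
    if tissues is None:
        tissues = sorted({t for s in sites for t in s.tissues})
    comps = []
    for a, b in itertools.combinations(tissues, 2):
        try:
            comps.append(compare_editing_ratios(sites, a, b, config))
        except ValueError:
            continue
    if comps:
        qs = benjamini_hochberg([c.p for c in comps])
        for comp, q in zip(comps, qs):
            comp.q = q
    return comps


def benjamini_hochberg(pvalues: Sequence[float]) -> list[float]:
    """Step-up FDR-adjusted q-values."""
    _, qs, _, _ = multipletests(pvalues, method="fdr_bh")
    return list(qs)


def expression_editing_correlation(expression: Sequence[float],
                                   edit_counts: Sequence[float],
                                   ) -> tuple[float, float]:
    """Pearson correlation between a gene's per-tissue expression (TPM) and
    per-tissue editing counts. Returns (r, two-sided p)."""
    if len(expression) != len(edit_counts):
        raise ValueError("vectors must share their tissue axis")
    if len(expression) < 3:
        raise ValueError("need at least 3 tissue pairs")
    r, p = sp_stats.pearsonr(expression, edit_counts)
    return float(r), float(p)


def per_tissue_site_counts(sites: Sequence[EditingSite]) -> Counter:
    counts: Counter = Counter()
    for site in sites:
        for tissue in site.tissues:
            counts[tissue] += 1
    return counts
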