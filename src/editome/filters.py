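"""The per-sample quality and allele filter cascade, with single-reason
provenance.

Each variant observation receives exactly one verdict whose ``reason`` is
the first failing check in the documented order:

    quality (HRun, DP, MQ, QD, MQRankSum, ReadPosRankSum)
    → allele (multi-allelic, hom-alt, depth, alt reads, ratio bounds)
    → bidirectional transcription
    → SSR zone
    → splice-junction margin
    → flank uniqueness

All inequalities are strict as printed: a run of exactly 5 passes, a depth
of exactly 10 passes, a ratio of exactly 0.10 passes, a ratio of exactly
1.0 fails. Missing GATK annotations pass (recorded as absent) so VCFs from
other callers do not zero the pipeline.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .config import ThresholdConfig, DEFAULT_CONFIG
from .context import StudyContext
from .model import VariantObservation

REASONS = (
    "known_snp", "multi_allelic", "hom_alt", "low_depth", "few_alt_reads",
    "low_ratio", "full_ratio", "hrun", "low_mq", "low_qd", "mqranksum",
    "readposranksum", "bidirectional", "ssr", "splice_junction",
    "non_unique_flank", "none",
)


@dataclass
class FilterVerdict:
    passed: bool
    reason: str
    values_used: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reason not in REASONS:
            raise ValueError(f"unknown reason {self.reason!r}")
        if self.passed != (self.reason == "none"):
            raise ValueError("passed must hold exactly when reason == 'none'")


def _fail(reason: str, values: dict) -> FilterVerdict:
    return FilterVerdict(False, reason, values)


def editing_ratio(variant: VariantObservation) -> float:
    """Fraction of reads carrying the variant allele (alt depth / total)."""
    if variant.total_depth <= 0:
        raise ValueError(f"zero depth at {variant.contig}:{variant.pos}")
    return variant.alt_depth / variant.total_depth


def apply_quality_filters(variant: VariantObservation,
                          config: ThresholdConfig = DEFAULT_CONFIG,
                          ) -> FilterVerdict:
    """GATK-style site-quality gates re-checked from the VCF annotations."""
    ann = variant.annotations
    values = {"DP": variant.total_depth}
    for key in ("HRun", "MQ", "QD", "MQRankSum", "ReadPosRankSum"):
        values[key] = ann.get(key, "absent")

    hrun = ann.get("HRun")
    if hrun is not None and hrun > config.max_hrun:
        return _fail("hrun", values)
    if variant.total_depth < config.min_depth:
        return _fail("low_depth", values)
    mq = ann.get("MQ")
    if mq is not None and mq < config.min_mq:
        return _fail("low_mq", values)
    qd = ann.get("QD")
    if qd is not None and qd < config.min_qd:
        return _fail("low_qd", values)
    mqrs = ann.get("MQRankSum")
    if mqrs is not None and mqrs < config.min_mqranksum:
        return _fail("mqranksum", values)
    rprs = ann.get("ReadPosRankSum")
    if rprs is not None and rprs < config.min_readposranksum:
        return _fail("readposranksum", values)
    return FilterVerdict(True, "none", values)


def apply_allele_filters(variant: VariantObservation,
                         config: ThresholdConfig = DEFAULT_CONFIG,
                         ) -> FilterVerdict:
    """Allele-level rules: single non-reference allele, heterozygous call,
    depth/alt-read floors, and the editing-ratio band [0.10, 1.0)."""
    values = {"DP": variant.total_depth, "alt_depth": variant.alt_depth,
              "genotype": variant.genotype, "n_alts": len(variant.all_alts) or 1}
    if variant.multi_allelic:
        return _fail("multi_allelic", values)
    if variant.genotype == "hom_alt":
        return _fail("hom_alt", values)
    if variant.total_depth < config.min_depth:
        return _fail("low_depth", values)
    if variant.alt_depth < config.min_alt_reads:
        return _fail("few_alt_reads", values)
    ratio = editing_ratio(variant)
    values["ratio"] = ratio
    if ratio < config.min_ratio:
        return _fail("low_ratio", values)
    if ratio >= config.max_ratio_exclusive:
        return _fail("full_ratio", values)
    return FilterVerdict(True, "none", values)


def apply_context_filters(variant: VariantObservation, ctx: StudyContext,
                          ) -> FilterVerdict:
    """Positional checks: bidirectional transcription, SSR zone,
    splice-junction margin, flank uniqueness (in that order)."""
    contig, pos = variant.contig, variant.pos
    values: dict = {}
    if ctx.bidirectional(contig, pos):
        return _fail("bidirectional", values)
    if ctx.in_ssr_zone(contig, pos):
        return _fail("ssr", values)
    if ctx.near_splice(contig, pos):
        return _fail("splice_junction", values)
    if not ctx.flank_unique(contig, pos):
        return _fail("non_unique_flank", values)
    return FilterVerdict(True, "none", values)


@dataclass
class CascadeLedger:
    """Bookkeeping of the cascade: one verdict per input observation."""

    verdicts: list[FilterVerdict]
    reason_counts: Counter = field(default_factory=Counter)

    @property
    def n_input(self) -> int:
        return len(self.verdicts)

    @property
    def n_passed(self) -> int:
        return sum(1 for v in self.verdicts if v.passed)

    def check_books(self) -> bool:
        rejected = sum(c for r, c in self.reason_counts.items() if r != "none")
        return rejected + self.n_passed == self.n_input


def run_cascade(variants: Iterable[VariantObservation], ctx: StudyContext,
                config: Optional[ThresholdConfig] = None) -> CascadeLedger:
    """Apply the full cascade in its deterministic order; each rejected
    observation carries the first failing reason only."""
    config = config if config is not None else ctx.config
    verdicts = []
    counts: Counter = Counter()
    for v in variants:
        verdict = apply_quality_filters(v, config)
        if verdict.passed:
            allele = apply_allele_filters(v, config)
            if allele.passed:
                verdict.values_used.update(allele.values_used)
                ctx_verdict = apply_context_filters(v, ctx)
                if not ctx_verdict.passed:
                    verdict = FilterVerdict(False, ctx_verdict.reason,
                                            verdict.values_used)
            else:
                verdict = FilterVerdict(False, allele.reason,
                                        {**verdict.values_used,
                                         **allele.values_used})
        verdicts.append(verdict)
        counts[verdict.reason] += 1
    return CascadeLedger(verdicts=verdicts, reason_counts=counts)
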