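"""Every numeric cutoff of the discovery pipeline in one validated record.

The defaults are the published operating point of the method: GATK-style
site-quality gates, allele/coverage/ratio rules, the SSR and splice-junction
exclusion zones, the 100 bp cluster window and the ≥2-individual recurrence
rule. All inequalities elsewhere in the package are strict as printed
(e.g. homopolymer runs *longer than* 5 fail, depth *below* 10 fails, a
ratio of exactly 0.10 passes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass(frozen=True)
class ThresholdConfig:
    """Numeric thresholds of the editing-site filter cascade.

    Attributes
    ----------
    min_depth:
        Minimum total read depth at a site (DP); sites with fewer reads fail.
    min_alt_reads:
        Minimum reads supporting the variant allele.
    min_ratio:
        Minimum editing ratio (alt/total); exactly ``min_ratio`` passes.
    max_ratio_exclusive:
        Sites edited in 100% of reads are removed (unrealistic efficiency);
        the ratio must be strictly below this value.
    max_hrun:
        Maximum homopolymer-run length; runs longer than this fail.
    min_mq:
        Minimum RMS mapping quality (MQ).
    min_qd:
        Minimum quality-by-depth (QD).
    min_mqranksum / min_readposranksum:
        Lower bounds on the GATK rank-sum annotations.
    ssr_motif_len_range:
        Motif lengths considered when scanning for simple sequence repeats.
    ssr_min_total_len:
        Minimum total span of a perfect tandem repeat.
    ssr_offset:
        Exclusion margin around an SSR interval, in bases.
    splice_flank:
        Intronic bases adjacent to an exon boundary that are excluded.
    uniq_flank:
        Flank length (each side) used for the uniqueness re-alignment check.
    cluster_window:
        Maximum gap (bp) linking two editing sites into one cluster, and the
        recruitment distance of the extension step.
    gene_flank:
        Distance (bp) within which an intergenic site is associated with a
        gene (strand resolution, upstream/downstream annotation).
    min_individuals:
        Biological-replication requirement: a site must recur in at least
        this many distinct individuals.
    motif_flank:
        Bases each side of the edited A in the neighbor-preference matrix.
    est_evalue:
        E-value cutoff for EST support.
    cons_evalue / cons_min_identity / cons_min_alnlen:
        Cross-species conservation thresholds.
    """

    min_depth: int = 10
    min_alt_reads: int = 3
    min_ratio: float = 0.10
    max_ratio_exclusive: float = 1.0
    max_hrun: int = 5
    min_mq: float = 40.0
    min_qd: float = 2.0
    min_mqranksum: float = -12.5
    min_readposranksum: float = -8.0
    ssr_motif_len_range: tuple[int, int] = (1, 8)
    ssr_min_total_len: int = 6
    ssr_offset: int = 3
    splice_flank: int = 5
    uniq_flank: int = 50
    uniq_min_identity: float = 0.90
    uniq_min_coverage: float = 0.90
    cluster_window: int = 100
    gene_flank: int = 5000
    min_individuals: int = 2
    motif_flank: int = 10
    est_evalue: float = 1e-5
    cons_evalue: float = 1e-3
    cons_min_identity: float = 0.85
    cons_min_alnlen: int = 50
    # behavioural switches (see methods note)
    snp_subtraction_allele_aware: bool = False
    recurrence_same_tissue: bool = False
    transitive_extension: bool = False
    welch_t: bool = False

    def __post_init__(self) -> None:
        positive = (
            "min_depth", "min_alt_reads", "max_hrun", "min_mq", "min_qd",
            "ssr_min_total_len", "ssr_offset", "splice_flank", "uniq_flank",
            "cluster_window", "gene_flank", "min_individuals", "motif_flank",
            "est_evalue", "cons_evalue", "cons_min_alnlen",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.min_ratio < self.max_ratio_exclusive):
            raise ValueError("require 0 <= min_ratio < max_ratio_exclusive")
        lo, hi = self.ssr_motif_len_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid ssr_motif_len_range")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ThresholdConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        kwargs = {}
        for key, value in mapping.items():
            if key == "ssr_motif_len_range" and not isinstance(value, tuple):
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)


DEFAULT_CONFIG = ThresholdConfig()
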