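"""Seeded generator of a complete miniature editing study, plus recovery
scoring.

The generated study mirrors the structure the pipeline assumes: three
individuals sequenced across nine tissues, a genome with intron/exon gene
models on both strands, SINE-like repeats (a fraction as inverted pairs),
clustered A>G editing sites enriched in those repeats with a T(−1)/G(+1)
context bias, germline SNPs shared by all individuals (listed in the
known-SNP catalogue), private single-individual SNPs (deliberately NOT
listed — the pipeline's acknowledged blind spot), and singleton error SNVs
across all twelve mismatch classes.

Read counts are sampled binomially at each site's true editing ratio with
Poisson depth; reads themselves are never simulated (the pipeline consumes
VCFs, not alignments).
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import ThresholdConfig, DEFAULT_CONFIG
from .context import find_ssrs, homopolymer_run, near_splice_junction, \
    bidirectional_overlap
from .io import write_genome, write_repeats_bed
from .model import (
    EditingSite,
    Gene,
    GeneModelSet,
    GenomeAssembly,
    MISMATCH_LABELS,
    RepeatFeature,
    RepeatSet,
    Transcript,
    VariantObservation,
    complement_base,
    revcomp,
)

BASES = "ACGT"

TISSUES = ("brain", "heart", "colon", "lung", "spleen", "kidney",
           "testes", "muscle", "liver")
INDIVIDUALS = ("bull1", "bull2", "bull3")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the synthetic miniature editome."""

    seed: int = 0
    genome_len: int = 1_000_000
    contig: str = "chr1"
    n_genes: int = 30
    n_repeats: int = 200
    repeat_len: int = 150
    inverted_pair_frac: float = 0.30
    repeat_divergence: float = 0.15
    n_edit_sites: int = 120
    frac_in_repeats: float = 0.80
    cluster_geom_p: float = 1 / 3          # geometric cluster sizes, mean 3
    cluster_max_size: int = 8
    ratio_alpha: float = 2.0               # Beta(2, 4) truncated to the band
    ratio_beta: float = 4.0
    ratio_low: float = 0.10
    ratio_high: float = 0.95
    depth_mean: float = 40.0               # Poisson, floored at 10
    depth_floor: int = 10
    p_t_minus1: float = 0.5                # context bias on the transcribed strand
    p_g_plus1: float = 0.5
    n_subthreshold_edits: int = 40         # cluster members below the HC bar
    subthreshold_ratio_low: float = 0.02
    subthreshold_ratio_high: float = 0.30
    n_error_snvs: int = 300
    n_known_snps: int = 400
    n_private_snps: int = 60
    tissues: tuple[str, ...] = TISSUES
    individuals: tuple[str, ...] = INDIVIDUALS
    tissue_presence: float = 0.6

    def __post_init__(self) -> None:
        for name in ("inverted_pair_frac", "frac_in_repeats", "tissue_presence",
                     "p_t_minus1", "p_g_plus1", "repeat_divergence"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a probability")


@dataclass
class TruthRecord:
    contig: str
    pos: int
    klass: str                    # edit | subthreshold_edit | error | known_snp | private_snp
    ref: str                      # genomic strand
    alt: str
    true_ratio: float
    individuals: tuple[str, ...]
    tissues: tuple[str, ...]
    in_repeat: bool = False
    cluster_id: Optional[str] = None


@dataclass
class SyntheticTruth:
    records: list[TruthRecord]

    def __post_init__(self) -> None:
        keys = [(r.contig, r.pos) for r in self.records]
        if len(keys) != len(set(keys)):
            raise ValueError("planted positions must be unique")
        self._by_pos = {(r.contig, r.pos): r for r in self.records}

    def of_class(self, klass: str) -> list[TruthRecord]:
        return [r for r in self.records if r.klass == klass]

    def lookup(self, contig: str, pos: int) -> Optional[TruthRecord]:
        return self._by_pos.get((contig, pos))


@dataclass
class SyntheticReference:
    assembly: GenomeAssembly
    gene_models: GeneModelSet
    repeats: RepeatSet
    known_snps: list[tuple[str, int, str, str]]
    config: SyntheticConfig


# ---------------------------------------------------------------------------
# Reference generation


def _rng(config: SyntheticConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng((config.seed, salt))


def _random_bases(rng: np.random.Generator, n: int,
                  probs=(0.25, 0.25, 0.25, 0.25)) -> np.ndarray:
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=probs)


def generate_reference(config: SyntheticConfig) -> SyntheticReference:
    """Genome + gene models + repeats + known-SNP catalogue, deterministic
    under the config seed."""
    rng = _rng(config, 1)
    n = config.genome_len
    seq = _random_bases(rng, n)

    genes, occupied = _layout_genes(config, rng)
    if not genes:
        raise ValueError("infeasible packing: no genes fit the genome length")

    repeats = _place_repeats(config, rng, seq, genes, occupied)

    genome = GenomeAssembly({config.contig: seq.tobytes().decode("ascii")})
    gene_models = GeneModelSet(genes)

    known = []
    taken: set[int] = set()
    rng_snp = _rng(config, 2)
    while len(known) < config.n_known_snps:
        pos = int(rng_snp.integers(1, n + 1))
        if pos in taken:
            continue
        ref = genome.base(config.contig, pos)
        if ref not in BASES:
            continue
        alt = BASES[int(rng_snp.integers(0, 4))]
        if alt == ref:
            continue
        taken.add(pos)
        known.append((config.contig, pos, ref, alt))
    known.sort(key=lambda r: r[1])
    return SyntheticReference(assembly=genome, gene_models=gene_models,
                              repeats=RepeatSet(repeats), known_snps=known,
                              config=config)


def _layout_genes(config: SyntheticConfig, rng: np.random.Generator,
                  ) -> tuple[list[Gene], list[tuple[int, int]]]:
    """Sequential left-to-right layout; returns genes and exon intervals."""
    n_pseudo = max(1, config.n_genes // 10)
    n_antisense = 2 if config.n_genes >= 10 else 0
    n_coding = config.n_genes - n_pseudo - n_antisense

    genes: list[Gene] = []
    exon_zones: list[tuple[int, int]] = []
    cursor = int(rng.integers(2000, 6000))
    host_introns: list[tuple[int, int, str]] = []   # for antisense overlaps

    for gi in range(n_coding + n_pseudo):
        pseudo = gi >= n_coding
        strand = "+" if rng.random() < 0.5 else "-"
        if pseudo:
            length = int(rng.integers(400, 900))
            end = cursor + length - 1
            if end > config.genome_len - 2000:
                raise ValueError("infeasible packing: genome too short")
            tx = Transcript(id=f"tx_ps{gi:02d}", exons=[(cursor, end)])
            genes.append(Gene(id=f"gene{gi:02d}", symbol=f"PSG{gi:02d}",
                              biotype="pseudogene", contig=config.contig,
                              strand=strand, transcripts=[tx]))
            exon_zones.append((cursor, end))
            cursor = end + int(rng.integers(3000, 9000))
            continue
        n_exons = int(rng.integers(4, 9))
        exons = []
        pos = cursor
        for e in range(n_exons):
            elen = int(rng.integers(150, 400))
            exons.append((pos, pos + elen - 1))
            pos += elen
            if e < n_exons - 1:
                pos += int(rng.integers(600, 2000))
        gene_end = exons[-1][1]
        if gene_end > config.genome_len - 2000:
            raise ValueError("infeasible packing: genome too short for genes")
        tx = _build_coding_transcript(f"tx{gi:02d}", exons, strand, rng)
        genes.append(Gene(id=f"gene{gi:02d}", symbol=f"GENE{gi:02d}",
                          biotype="protein_coding", contig=config.contig,
                          strand=strand, transcripts=[tx]))
        exon_zones.extend(exons)
        introns = tx.introns()
        if introns:
            s, e = introns[len(introns) // 2]
            host_introns.append((s, e, strand))
        cursor = gene_end + int(rng.integers(3000, 9000))

    # antisense partners overlapping a host intron → bidirectional zones
    for ai in range(n_antisense):
        if ai >= len(host_introns):
            break
        s, e, host_strand = host_introns[ai * 3 % len(host_introns)]
        if e - s < 500:
            continue
        a_start = s + 50
        a_end = min(e - 50, a_start + 800)
        strand = "-" if host_strand == "+" else "+"
        tx = Transcript(id=f"tx_as{ai}", exons=[(a_start, a_end)])
        genes.append(Gene(id=f"geneAS{ai}", symbol=f"ASG{ai}",
                          biotype="other", contig=config.contig,
                          strand=strand, transcripts=[tx]))
        exon_zones.append((a_start, a_end))
    return genes, sorted(exon_zones)


def _build_coding_transcript(tx_id: str, exons: list[tuple[int, int]],
                             strand: str, rng: np.random.Generator) -> Transcript:
    total = sum(e - s + 1 for s, e in exons)
    u5 = int(rng.integers(100, 200))
    u3 = int(rng.integers(150, 300))
    cds_len = total - u5 - u3
    cds_len -= cds_len % 3
    u3 = total - u5 - cds_len
    # walk transcript in 5'→3' order assigning UTR5 | CDS | UTR3
    order = exons if strand == "+" else exons[::-1]
    utr5, cds_iv, utr3 = [], [], []
    consumed = 0
    for s, e in order:
        elen = e - s + 1
        # positions within transcript: [consumed, consumed+elen)
        t0, t1 = consumed, consumed + elen
        for kind, k0, k1 in (("u5", 0, u5), ("cds", u5, u5 + cds_len),
                             ("u3", u5 + cds_len, total)):
            lo, hi = max(t0, k0), min(t1, k1)
            if lo >= hi:
                continue
            if strand == "+":
                gs, ge = s + (lo - t0), s + (hi - t0) - 1
            else:
                ge, gs = e - (lo - t0), e - (hi - t0) + 1
            if kind == "u5":
                utr5.append((gs, ge))
            elif kind == "u3":
                utr3.append((gs, ge))
            else:
                cds_iv.append((gs, ge))
        consumed += elen
    cds_iv.sort()
    # phase per GFF convention, in translation order
    frames: dict[tuple[int, int], int] = {}
    cum = 0
    for iv in (cds_iv if strand == "+" else cds_iv[::-1]):
        frames[iv] = (3 - cum % 3) % 3
        cum += iv[1] - iv[0] + 1
    return Transcript(id=tx_id, exons=sorted(exons),
                      cds=[(s, e, frames[(s, e)]) for s, e in cds_iv],
                      utr5=sorted(utr5), utr3=sorted(utr3))


def _place_repeats(config: SyntheticConfig, rng: np.random.Generator,
                   seq: np.ndarray, genes: list[Gene],
                   exon_zones: list[tuple[int, int]]) -> list[RepeatFeature]:
    """Write diverged copies of SINE/LINE/DNA consensi into the sequence."""
    consensus = {
        "Bov-tA": _random_bases(rng, config.repeat_len, (0.34, 0.14, 0.22, 0.30)),
        "Bov-A2": _random_bases(rng, config.repeat_len, (0.32, 0.16, 0.22, 0.30)),
        "L1-BT": _random_bases(rng, 400, (0.30, 0.20, 0.20, 0.30)),
        "Charlie": _random_bases(rng, 200, (0.28, 0.22, 0.22, 0.28)),
    }
    family_class = {"Bov-tA": "SINE", "Bov-A2": "SINE",
                    "L1-BT": "LINE", "Charlie": "DNA"}
    n_sine = int(config.n_repeats * 0.85)
    plan = (["Bov-tA"] * int(n_sine * 0.75)
            + ["Bov-A2"] * (n_sine - int(n_sine * 0.75)))
    rest = config.n_repeats - n_sine
    plan += ["L1-BT"] * (rest * 2 // 3) + ["Charlie"] * (rest - rest * 2 // 3)

    blocked = list(exon_zones)

    def free(start: int, end: int) -> bool:
        if start < 100 or end > config.genome_len - 100:
            return False
        return all(end < s - 10 or start > e + 10 for s, e in blocked)

    repeats: list[RepeatFeature] = []
    placed = 0
    i = 0
    attempts = 0
    while i < len(plan) and attempts < 50_000:
        attempts += 1
        family = plan[i]
        cons = consensus[family]
        rlen = cons.size
        start0 = int(rng.integers(100, config.genome_len - rlen - 700))
        end0 = start0 + rlen - 1
        if not free(start0, end0):
            continue
        paired = (family_class[family] == "SINE"
                  and rng.random() < config.inverted_pair_frac)
        copy = _diverge(cons, config.repeat_divergence, rng)
        seq[start0:start0 + rlen] = copy
        repeats.append(RepeatFeature(config.contig, start0 + 1, end0 + 1, "+",
                                     family_class[family], family))
        blocked.append((start0, end0))
        i += 1
        if paired and i < len(plan):
            gap = int(rng.integers(100, 400))
            p_start = end0 + 1 + gap
            p_end = p_start + rlen - 1
            if free(p_start, p_end):
                copy2 = _diverge(cons, config.repeat_divergence, rng)
                rc = np.frombuffer(
                    revcomp(copy2.tobytes().decode("ascii")).encode("ascii"),
                    dtype=np.uint8)
                seq[p_start:p_start + rlen] = rc
                repeats.append(RepeatFeature(config.contig, p_start + 1,
                                             p_end + 1, "-",
                                             family_class[family], family))
                blocked.append((p_start, p_end))
                i += 1
    return repeats


def _diverge(consensus: np.ndarray, rate: float,
             rng: np.random.Generator) -> np.ndarray:
    copy = consensus.copy()
    hits = np.nonzero(rng.random(copy.size) < rate)[0]
    subs = _random_bases(rng, hits.size)
    for idx, b in zip(hits, subs):
        if copy[idx] == b:
            b = ord(BASES[(BASES.index(chr(b)) + 1) % 4])
        copy[idx] = b
    return copy


# ---------------------------------------------------------------------------
# Variant planting


def plant_variants(reference: SyntheticReference,
                   config: Optional[SyntheticConfig] = None,
                   ) -> tuple[dict[tuple[str, str], list[VariantObservation]],
                              SyntheticTruth]:
    """Per-sample observations plus the planted-site ledger."""
    config = config or reference.config
    rng = _rng(config, 3)
    genome = reference.assembly
    genes = reference.gene_models
    contig = config.contig

    thresholds = ThresholdConfig()
    ssr_zones = _ssr_zone_array(genome, contig, thresholds)
    known_positions = {p for (_c, p, _r, _a) in reference.known_snps}
    taken: set[int] = set(known_positions)

    samples: dict[tuple[str, str], list[VariantObservation]] = {
        (ind, tis): [] for ind in config.individuals for tis in config.tissues}
    truth_records: list[TruthRecord] = []

    # --- edits -------------------------------------------------------------
    edit_sites, sub_sites = _choose_edit_sites(reference, config, rng,
                                               ssr_zones, taken)
    for cluster_id, pos, strand, in_repeat in edit_sites:
        ratio = _truncated_beta(rng, config)
        n_ind = 2 if rng.random() < 0.5 else min(3, len(config.individuals))
        carriers = tuple(sorted(str(x) for x in rng.choice(
            config.individuals, size=n_ind, replace=False)))
        present = tuple(t for t in config.tissues
                        if rng.random() < config.tissue_presence)
        if not present:
            present = (config.tissues[int(rng.integers(len(config.tissues)))],)
        ref_base = genome.base(contig, pos)            # A or T
        alt_base = "G" if strand == "+" else "C"
        for ind in carriers:
            for tissue in present:
                depth = _depth(rng, config)
                alt = int(rng.binomial(depth, ratio))
                if alt == 0:
                    continue
                samples[(ind, tissue)].append(_obs(
                    genome, contig, pos, ref_base, alt_base, depth, alt,
                    "het", ind, tissue, rng))
        truth_records.append(TruthRecord(
            contig=contig, pos=pos, klass="edit", ref=ref_base, alt=alt_base,
            true_ratio=ratio, individuals=carriers, tissues=present,
            in_repeat=in_repeat, cluster_id=cluster_id))

    # --- sub-threshold cluster members -------------------------------------
    # Edited adenosines below the per-sample bar (single individual, low
    # ratio): invisible to the high-confidence cascade, recoverable only by
    # the 100 bp extension around their cluster mates.
    for cluster_id, pos, strand, in_repeat in sub_sites:
        ratio = _truncated_band(rng, config, config.subthreshold_ratio_low,
                                config.subthreshold_ratio_high)
        ind = config.individuals[int(rng.integers(len(config.individuals)))]
        present = tuple(t for t in config.tissues
                        if rng.random() < config.tissue_presence) \
            or (config.tissues[0],)
        ref_base = genome.base(contig, pos)
        alt_base = "G" if strand == "+" else "C"
        for tissue in present:
            depth = _depth(rng, config)
            alt = int(rng.binomial(depth, ratio))
            if alt == 0:
                continue
            samples[(ind, tissue)].append(_obs(
                genome, contig, pos, ref_base, alt_base, depth, alt, "het",
                ind, tissue, rng))
        truth_records.append(TruthRecord(
            contig=contig, pos=pos, klass="subthreshold_edit", ref=ref_base,
            alt=alt_base, true_ratio=ratio, individuals=(ind,),
            tissues=present, in_repeat=in_repeat, cluster_id=cluster_id))

    # --- error SNVs --------------------------------------------------------
    rng_err = _rng(config, 4)
    planted = 0
    while planted < config.n_error_snvs:
        label = MISMATCH_LABELS[int(rng_err.integers(len(MISMATCH_LABELS)))]
        ref_base, alt_base = label[0], label[2]
        pos = int(rng_err.integers(100, config.genome_len - 100))
        if pos in taken or genome.base(contig, pos) != ref_base:
            continue
        taken.add(pos)
        ind = config.individuals[int(rng_err.integers(len(config.individuals)))]
        tissue = config.tissues[int(rng_err.integers(len(config.tissues)))]
        depth = _depth(rng_err, config)
        alt = int(rng_err.integers(1, 5))
        samples[(ind, tissue)].append(_obs(
            genome, contig, pos, ref_base, alt_base, depth, alt, "het",
            ind, tissue, rng_err))
        truth_records.append(TruthRecord(
            contig=contig, pos=pos, klass="error", ref=ref_base, alt=alt_base,
            true_ratio=round(alt / depth, 4), individuals=(ind,),
            tissues=(tissue,)))
        planted += 1

    # --- germline SNPs (known catalogue) -----------------------------------
    rng_snp = _rng(config, 5)
    for (c, pos, ref_base, alt_base) in reference.known_snps:
        hom = rng_snp.random() < 0.3
        for ind in config.individuals:
            for tissue in config.tissues:
                depth = _depth(rng_snp, config)
                if hom:
                    alt = depth
                    gt = "hom_alt"
                else:
                    alt = int(rng_snp.binomial(depth, 0.5))
                    gt = "het"
                if alt == 0:
                    continue
                samples[(ind, tissue)].append(_obs(
                    genome, c, pos, ref_base, alt_base, depth, alt, gt,
                    ind, tissue, rng_snp))
        truth_records.append(TruthRecord(
            contig=c, pos=pos, klass="known_snp", ref=ref_base, alt=alt_base,
            true_ratio=1.0 if hom else 0.5, individuals=config.individuals,
            tissues=config.tissues))

    # --- private SNPs (single individual, absent from the catalogue) -------
    rng_priv = _rng(config, 6)
    planted = 0
    while planted < config.n_private_snps:
        pos = int(rng_priv.integers(100, config.genome_len - 100))
        ref_base = genome.base(contig, pos)
        if pos in taken or ref_base not in BASES:
            continue
        taken.add(pos)
        alt_base = BASES[int(rng_priv.integers(0, 4))]
        if alt_base == ref_base:
            continue
        ind = config.individuals[int(rng_priv.integers(len(config.individuals)))]
        for tissue in config.tissues:
            depth = _depth(rng_priv, config)
            alt = int(rng_priv.binomial(depth, 0.5))
            if alt == 0:
                continue
            samples[(ind, tissue)].append(_obs(
                genome, contig, pos, ref_base, alt_base, depth, alt, "het",
                ind, tissue, rng_priv))
        truth_records.append(TruthRecord(
            contig=contig, pos=pos, klass="private_snp", ref=ref_base,
            alt=alt_base, true_ratio=0.5, individuals=(ind,),
            tissues=config.tissues))
        planted += 1

    for obs_list in samples.values():
        obs_list.sort(key=lambda o: o.pos)
    return samples, SyntheticTruth(records=truth_records)


def _obs(genome: GenomeAssembly, contig: str, pos: int, ref: str, alt: str,
         depth: int, alt_depth: int, gt: str, ind: str, tissue: str,
         rng: np.random.Generator) -> VariantObservation:
    annotations = {
        "HRun": float(homopolymer_run(genome, contig, pos, alt)),
        "MQ": float(np.round(55 + 5 * rng.random(), 2)),
        "QD": float(np.round(10 + 20 * rng.random(), 2)),
        "MQRankSum": float(np.round(rng.normal(0, 1), 3)),
        "ReadPosRankSum": float(np.round(rng.normal(0, 1), 3)),
    }
    return VariantObservation(
        contig=contig, pos=pos, ref=ref, alt=alt, total_depth=depth,
        alt_depth=min(alt_depth, depth), genotype=gt, individual=ind,
        tissue=tissue, annotations=annotations)


def _depth(rng: np.random.Generator, config: SyntheticConfig) -> int:
    return max(config.depth_floor, int(rng.poisson(config.depth_mean)))


def _truncated_beta(rng: np.random.Generator, config: SyntheticConfig) -> float:
    return _truncated_band(rng, config, config.ratio_low, config.ratio_high)


def _truncated_band(rng: np.random.Generator, config: SyntheticConfig,
                    low: float, high: float) -> float:
    while True:
        x = float(rng.beta(config.ratio_alpha, config.ratio_beta))
        if low <= x <= high:
            return float(np.round(x, 4))


def _ssr_zone_array(genome: GenomeAssembly, contig: str,
                    config: ThresholdConfig) -> np.ndarray:
    zones = np.zeros(genome.length(contig) + 2, dtype=bool)
    for ssr in find_ssrs(genome.contigs[contig], config, contig=contig):
        lo = max(1, ssr.start - config.ssr_offset)
        hi = min(genome.length(contig), ssr.end + config.ssr_offset)
        zones[lo:hi + 1] = True
    return zones


def _choose_edit_sites(reference: SyntheticReference, config: SyntheticConfig,
                       rng: np.random.Generator, ssr_zones: np.ndarray,
                       taken: set[int],
                       ) -> tuple[list[tuple[str, int, str, bool]],
                                  list[tuple[str, int, str, bool]]]:
    """Pick clustered plantable positions: (cluster_id, pos, strand, in_repeat).

    Returns the main edit set and a second set of sub-threshold cluster
    members placed 10–90 bp from a chosen main-edit position."""
    genome = reference.assembly
    genes = reference.gene_models
    contig = config.contig
    thresholds = ThresholdConfig()

    # hosts: repeats inside gene spans, and non-repeat genic intervals
    genic_repeats = []
    for rep in reference.repeats.repeats:
        hosts = genes.genes_at(contig, rep.start)
        if hosts and len({g.strand for g in hosts}) == 1:
            genic_repeats.append((rep.start, rep.end, hosts[0].strand, True))
    intron_hosts = []
    for gene in genes.genes:
        if gene.biotype != "protein_coding":
            continue
        for tx in gene.transcripts:
            for s, e in tx.introns():
                if e - s > 300:
                    intron_hosts.append((s, e, gene.strand, False))
            for s, e in tx.utr3:
                if e - s > 60:
                    intron_hosts.append((s, e, gene.strand, False))
    if not genic_repeats or not intron_hosts:
        raise ValueError("infeasible study: no plantable host regions")

    def plantable(pos: int, strand: str) -> bool:
        if pos in taken or not (100 < pos < config.genome_len - 100):
            return False
        base = genome.base(contig, pos)
        if base != ("A" if strand == "+" else "T"):
            return False
        if ssr_zones[pos]:
            return False
        alt_genomic = "G" if strand == "+" else "C"
        if homopolymer_run(genome, contig, pos, alt_genomic) > thresholds.max_hrun:
            return False
        if bidirectional_overlap(genes, contig, pos):
            return False
        if near_splice_junction(genes, contig, pos, thresholds):
            return False
        return True

    def context_ok(pos: int, strand: str, want_t: bool, want_g: bool) -> bool:
        if strand == "+":
            left, right = genome.base(contig, pos - 1), genome.base(contig, pos + 1)
        else:
            left = complement_base(genome.base(contig, pos + 1))
            right = complement_base(genome.base(contig, pos - 1))
        if want_t and left != "T":
            return False
        if want_g and right != "G":
            return False
        return True

    sites: list[tuple[str, int, str, bool]] = []
    cluster_serial = 0
    guard = 0
    while len(sites) < config.n_edit_sites and guard < 20_000:
        guard += 1
        size = min(int(rng.geometric(config.cluster_geom_p)),
                   config.cluster_max_size,
                   config.n_edit_sites - len(sites))
        in_repeat = rng.random() < config.frac_in_repeats
        hosts = genic_repeats if in_repeat else intron_hosts
        s, e, strand, _ = hosts[int(rng.integers(len(hosts)))]
        candidates = [p for p in range(s, e + 1) if plantable(p, strand)]
        if not candidates:
            continue
        cluster_serial += 1
        cid = f"truth_cl{cluster_serial:03d}" if size > 1 else None
        start_idx = int(rng.integers(len(candidates)))
        chosen = [candidates[start_idx]]
        want_t = rng.random() < config.p_t_minus1
        want_g = rng.random() < config.p_g_plus1
        if not context_ok(chosen[0], strand, want_t, want_g):
            biased = [p for p in candidates if context_ok(p, strand, want_t, want_g)]
            if biased:
                chosen = [biased[int(rng.integers(len(biased)))]]
        while len(chosen) < size:
            lo, hi = chosen[-1] + 10, chosen[-1] + 90
            nxt = [p for p in candidates if lo <= p <= hi and p not in chosen]
            if not nxt:
                break
            want_t = rng.random() < config.p_t_minus1
            want_g = rng.random() < config.p_g_plus1
            biased = [p for p in nxt if context_ok(p, strand, want_t, want_g)]
            pool = biased if biased else nxt
            chosen.append(pool[int(rng.integers(len(pool)))])
        for pos in chosen:
            taken.add(pos)
            sites.append((cid, pos, strand, in_repeat))
    if len(sites) < config.n_edit_sites:
        raise ValueError("could not place the requested number of edit sites")

    sub_sites: list[tuple[str, int, str, bool]] = []
    guard = 0
    while len(sub_sites) < config.n_subthreshold_edits and guard < 20_000:
        guard += 1
        cid, anchor, strand, in_repeat = sites[int(rng.integers(len(sites)))]
        lo, hi = anchor - 90, anchor + 90
        nearby = [p for p in range(lo, hi + 1)
                  if abs(p - anchor) >= 10 and plantable(p, strand)]
        if not nearby:
            continue
        pos = nearby[int(rng.integers(len(nearby)))]
        taken.add(pos)
        sub_sites.append((cid, pos, strand, in_repeat))
    return sites, sub_sites


# ---------------------------------------------------------------------------
# Emission and recovery scoring


def write_study(reference: SyntheticReference,
                samples: dict[tuple[str, str], list[VariantObservation]],
                truth: SyntheticTruth, outdir: str) -> dict[str, str]:
    """Emit genome.fa, genes.gff3, repeats.bed, known_snps.vcf, per-sample
    VCFs, meta.tsv and truth.tsv; returns the path map."""
    os.makedirs(os.path.join(outdir, "samples"), exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "genes": os.path.join(outdir, "genes.gff3"),
        "repeats": os.path.join(outdir, "repeats.bed"),
        "known_snps": os.path.join(outdir, "known_snps.vcf"),
        "meta": os.path.join(outdir, "meta.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_genome(reference.assembly, paths["genome"])
    _write_gff3(reference.gene_models, paths["genes"])
    write_repeats_bed(reference.repeats, paths["repeats"])
    _write_vcf(paths["known_snps"], reference.assembly,
               [(c, p, r, a, None) for (c, p, r, a) in reference.known_snps])
    with open(paths["meta"], "w") as fh:
        fh.write("individual_id\ttissue\tvcf_path\n")
        for (ind, tissue), observations in sorted(samples.items()):
            rel = os.path.join("samples", f"{ind}_{tissue}.vcf")
            fh.write(f"{ind}\t{tissue}\t{rel}\n")
            _write_vcf(os.path.join(outdir, rel), reference.assembly,
                       [(o.contig, o.pos, o.ref, o.alt, o) for o in observations])
    with open(paths["truth"], "w") as fh:
        fh.write("contig\tpos\tclass\tref\talt\ttrue_ratio\tindividuals\t"
                 "tissues\tin_repeat\tcluster_id\n")
        for r in truth.records:
            fh.write("\t".join([
                r.contig, str(r.pos), r.klass, r.ref, r.alt,
                f"{r.true_ratio:.4f}", ",".join(r.individuals),
                ",".join(r.tissues), str(int(r.in_repeat)),
                r.cluster_id or ".",
            ]) + "\n")
    return paths


def read_truth(path: str) -> SyntheticTruth:
    records = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            (contig, pos, klass, ref, alt, ratio, inds, tissues, in_rep,
             cid) = line.rstrip("\n").split("\t")
            records.append(TruthRecord(
                contig=contig, pos=int(pos), klass=klass, ref=ref, alt=alt,
                true_ratio=float(ratio), individuals=tuple(inds.split(",")),
                tissues=tuple(tissues.split(",")),
                in_repeat=bool(int(in_rep)),
                cluster_id=None if cid == "." else cid))
    return SyntheticTruth(records=records)


def _write_vcf(path: str, genome: GenomeAssembly, records) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in genome.contigs:
            fh.write(f"##contig=<ID={name},length={genome.length(name)}>\n")
        for key, vtype in (("HRun", "Integer"), ("MQ", "Float"), ("QD", "Float"),
                           ("MQRankSum", "Float"), ("ReadPosRankSum", "Float")):
            fh.write(f'##INFO=<ID={key},Number=1,Type={vtype},Description="{key}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for contig, pos, ref, alt, obs in sorted(records, key=lambda r: (r[0], r[1])):
            if obs is None:
                fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t0/1\n")
                continue
            info = ";".join(
                f"{k}={int(v) if k == 'HRun' else v}"
                for k, v in obs.annotations.items())
            gt = {"het": "0/1", "hom_alt": "1/1", "hom_ref": "0/0"}[obs.genotype]
            ad = f"{obs.total_depth - obs.alt_depth},{obs.alt_depth}"
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t{info}\t"
                     f"GT:AD:DP\t{gt}:{ad}:{obs.total_depth}\n")


def _write_gff3(gene_models: GeneModelSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in gene_models.genes:
            gs, ge = gene.span
            gtype = "pseudogene" if gene.biotype == "pseudogene" else "gene"
            fh.write(f"{gene.contig}\t.\t{gtype}\t{gs}\t{ge}\t.\t{gene.strand}"
                     f"\t.\tID={gene.id};Name={gene.symbol};"
                     f"biotype={gene.biotype}\n")
            for tx in gene.transcripts:
                ts, te = tx.span
                ttype = ("pseudogenic_transcript"
                         if gene.biotype == "pseudogene" else "mRNA")
                fh.write(f"{gene.contig}\t.\t{ttype}\t{ts}\t{te}\t.\t"
                         f"{gene.strand}\t.\tID={tx.id};Parent={gene.id}\n")
                for s, e in tx.exons:
                    fh.write(f"{gene.contig}\t.\texon\t{s}\t{e}\t.\t"
                             f"{gene.strand}\t.\tParent={tx.id}\n")
                for s, e, frame in tx.cds:
                    fh.write(f"{gene.contig}\t.\tCDS\t{s}\t{e}\t.\t"
                             f"{gene.strand}\t{frame}\tParent={tx.id}\n")
                for s, e in tx.utr5:
                    fh.write(f"{gene.contig}\t.\tfive_prime_UTR\t{s}\t{e}\t.\t"
                             f"{gene.strand}\t.\tParent={tx.id}\n")
                for s, e in tx.utr3:
                    fh.write(f"{gene.contig}\t.\tthree_prime_UTR\t{s}\t{e}\t.\t"
                             f"{gene.strand}\t.\tParent={tx.id}\n")


@dataclass
class RecoveryReport:
    tp: int
    fp: int
    fn: int
    precision: Optional[float]      # None when no calls were made
    recall: float
    f1: Optional[float]
    fp_by_category: dict = field(default_factory=dict)


def evaluate_recovery(calls: Sequence[EditingSite],
                      truth: SyntheticTruth) -> RecoveryReport:
    """Confusion-matrix scoring of called sites against planted edits.

    A call is a true positive iff its position carries a planted edit; false
    positives are broken down by the truth class at that position (error,
    private_snp, known_snp, or none for unplanted loci).
    """
    edit_positions = {(r.contig, r.pos) for r in truth.of_class("edit")}
    call_positions = {(s.contig, s.pos) for s in calls}
    tp = len(call_positions & edit_positions)
    fn = len(edit_positions - call_positions)
    fp_by: dict[str, int] = defaultdict(int)
    for key in call_positions - edit_positions:
        record = truth.lookup(*key)
        fp_by[record.klass if record else "none"] += 1
    fp = sum(fp_by.values())
    precision = tp / (tp + fp) if call_positions else None
    recall = tp / len(edit_positions) if edit_positions else 0.0
    f1 = None
    if precision is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    return RecoveryReport(tp=tp, fp=fp, fn=fn, precision=precision,
                          recall=recall, f1=f1, fp_by_category=dict(fp_by))
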