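"""End-to-end orchestration: from per-sample VCFs and annotations to the
annotated, cluster-extended editome with tissue statistics.

Stage order follows the discovery pipeline: known-SNP subtraction → quality
filters → allele filters → positional context filters → ≥2-individual
recurrence → strand-aware classification → clustering and 100 bp extension
→ annotation → cohort statistics → neighbor-preference matrix → optional
flank validation. Every stage's input/output counts are recorded in the run
manifest; rejection reasons plus survivors always sum to the stage input.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .annotate import annotate_sites
from .clustering import a_to_i_fraction, detect_clusters, extend_sites
from .cohort import (
    all_pairwise_comparisons,
    mismatch_spectrum,
    per_tissue_site_counts,
    recurrence_filter,
    site_tissue_matrix,
    tissue_specific_sites,
)
from .config import ThresholdConfig, DEFAULT_CONFIG
from .context import StudyContext
from .filters import apply_quality_filters, run_cascade
from .io import (
    read_gene_models,
    read_genome,
    read_known_snps,
    read_repeats,
    read_sample_metadata,
    read_variants,
    subtract_known_snps,
)
from .mismatch import classify_mismatch
from .model import (
    Cluster,
    EditingSite,
    GeneModelSet,
    GenomeAssembly,
    RepeatSet,
    VariantObservation,
)
from .motif import PositionFrequencyMatrix, extract_flanks, neighbor_pfm
from .validation import ValidationProfile, match_reference

log = logging.getLogger("editome")


@dataclass
class StudyInputs:
    genome: GenomeAssembly
    gene_models: GeneModelSet
    repeats: RepeatSet
    known_snps: set
    samples: dict[tuple[str, str], list[VariantObservation]]
    est_reference: Optional[str] = None       # FASTA path for EST support
    config: ThresholdConfig = field(default_factory=ThresholdConfig)


@dataclass
class RunResult:
    high_confidence: list[EditingSite]
    extended: list[EditingSite]
    clusters: list[Cluster]
    singletons: list[EditingSite]
    combined_clusters: list[Cluster]
    combined_singletons: list[EditingSite]
    filter_ledger: pd.DataFrame
    raw_spectrum: "pd.DataFrame | None"
    raw_a_to_i_pct: float
    hc_spectrum: "pd.DataFrame | None"
    hc_a_to_i_pct: float
    extended_a_to_i_pct: float
    tissue_matrix: pd.DataFrame
    pfm: Optional[PositionFrequencyMatrix]
    pairwise: list
    manifest: dict
    validation: Optional[pd.DataFrame] = None

    @property
    def all_sites(self) -> list[EditingSite]:
        return self.high_confidence + self.extended


def run_study(inputs: StudyInputs, validate: bool = True) -> RunResult:
    """Execute every stage on in-memory inputs."""
    config = inputs.config
    t0 = time.time()
    manifest: dict = {
        "version": __version__,
        "config": _jsonable(config.as_dict()),
        "stages": {},
    }

    all_obs = [obs for observations in inputs.samples.values()
               for obs in observations]
    manifest["stages"]["input"] = {"observations": len(all_obs),
                                   "samples": len(inputs.samples)}

    subtracted = subtract_known_snps(
        all_obs, inputs.known_snps,
        allele_aware=config.snp_subtraction_allele_aware)
    manifest["stages"]["known_snp_subtraction"] = {
        "in": len(all_obs), "out": len(subtracted),
        "removed": len(all_obs) - len(subtracted)}

    ctx = StudyContext(inputs.genome, inputs.gene_models, inputs.repeats, config)

    # extension pool: quality filters + SNP subtraction only (pre-cascade)
    pool = [o for o in subtracted if apply_quality_filters(o, config).passed]
    manifest["stages"]["extension_pool"] = {"in": len(subtracted),
                                            "out": len(pool)}

    ledger = run_cascade(subtracted, ctx, config)
    passing = [obs for obs, verdict in zip(subtracted, ledger.verdicts)
               if verdict.passed]
    manifest["stages"]["cascade"] = {
        "in": ledger.n_input, "out": ledger.n_passed,
        "reasons": {r: c for r, c in sorted(ledger.reason_counts.items())
                    if r != "none"}}
    if not ledger.check_books():
        raise AssertionError("cascade bookkeeping violated")
    ledger_frame = pd.DataFrame({
        "contig": [o.contig for o in subtracted],
        "pos": [o.pos for o in subtracted],
        "ref": [o.ref for o in subtracted],
        "alt": [o.alt for o in subtracted],
        "sample": [f"{o.individual}/{o.tissue}" for o in subtracted],
        "verdict": ["pass" if v.passed else "fail" for v in ledger.verdicts],
        "reason": [v.reason for v in ledger.verdicts],
        "values_used": [json.dumps(v.values_used, sort_keys=True)
                        for v in ledger.verdicts],
    })

    # classification (memoised per locus) for passing observations and the
    # raw-pool spectrum
    klass_memo: dict[tuple, object] = {}

    def classify(obs: VariantObservation):
        key = (obs.contig, obs.pos, obs.ref, obs.alt)
        if key not in klass_memo:
            klass_memo[key] = classify_mismatch(obs, inputs.gene_models,
                                                config=config)
        return klass_memo[key]

    raw_unique: dict[tuple, object] = {}
    for obs in subtracted:
        key = (obs.contig, obs.pos, obs.ref, obs.alt)
        if key not in raw_unique:
            klass = classify(obs)
            if klass is not None:
                raw_unique[key] = klass
    raw_summary = mismatch_spectrum(list(raw_unique.values()))
    candidates = [(obs, classify(obs)) for obs in passing]
    candidates = [(o, k) for o, k in candidates if k is not None]

    high_conf = recurrence_filter(candidates, config)
    manifest["stages"]["recurrence"] = {
        "in": len({(o.contig, o.pos) for o, _ in candidates}),
        "out": len(high_conf)}

    hc_a2i = [s for s in high_conf if s.mismatch.is_a_to_i]
    clusters, singletons = detect_clusters(hc_a2i, config)
    extended = extend_sites(high_conf, pool, inputs.gene_models, config)
    combined = high_conf + extended
    combined_clusters, combined_singletons = detect_clusters(
        [s for s in combined if s.mismatch.is_a_to_i], config)
    manifest["stages"]["clustering"] = {
        "hc_a_to_i": len(hc_a2i), "clusters": len(clusters),
        "clustered_sites": sum(len(c) for c in clusters),
        "extended_added": len(extended),
        "combined_clusters": len(combined_clusters)}

    annotate_sites(combined, inputs.gene_models, inputs.genome,
                   inputs.repeats, config)

    hc_summary = mismatch_spectrum(high_conf, by_tissue=True)
    tissues = sorted({t for s in high_conf for t in s.tissues})
    matrix = site_tissue_matrix(high_conf, tissues)
    pairwise = all_pairwise_comparisons(high_conf, tissues, config) \
        if len(tissues) >= 2 else []
    pfm = neighbor_pfm(hc_a2i, inputs.genome, config) if hc_a2i else None

    validation_frame = None
    if validate and inputs.est_reference:
        flanks = [extract_flanks(s, inputs.genome, config.uniq_flank).seq
                  for s in hc_a2i]
        hits = match_reference(flanks, inputs.est_reference,
                               ValidationProfile.est(config))
        validation_frame = pd.DataFrame({
            "site": [f"{s.contig}:{s.pos}" for s in hc_a2i],
            "est_hits": [h.n_hits for h in hits],
            "best_evalue": [h.best_evalue for h in hits]})

    manifest["stages"]["summary"] = {
        "high_confidence": len(high_conf),
        "hc_a_to_i_pct": round(hc_summary.a_to_i_fraction, 2),
        "raw_a_to_i_pct": round(raw_summary.a_to_i_fraction, 2),
        "extended_a_to_i_pct": round(a_to_i_fraction(extended), 2),
        "total_a_to_i": len([s for s in combined if s.mismatch.is_a_to_i]),
        "tissue_specific": {t: len(v) for t, v in
                            sorted(tissue_specific_sites(high_conf).items())},
        "per_tissue": dict(sorted(per_tissue_site_counts(high_conf).items())),
    }
    manifest["runtime_s"] = round(time.time() - t0, 2)

    return RunResult(
        filter_ledger=ledger_frame,
        high_confidence=high_conf, extended=extended, clusters=clusters,
        singletons=singletons, combined_clusters=combined_clusters,
        combined_singletons=combined_singletons,
        raw_spectrum=raw_summary.to_frame(), raw_a_to_i_pct=raw_summary.a_to_i_fraction,
        hc_spectrum=hc_summary.to_frame(), hc_a_to_i_pct=hc_summary.a_to_i_fraction,
        extended_a_to_i_pct=a_to_i_fraction(extended),
        tissue_matrix=matrix, pfm=pfm, pairwise=pairwise, manifest=manifest,
        validation=validation_frame)


# ---------------------------------------------------------------------------
# File-level driver


def load_inputs(genome_path: str, genes_path: str, repeats_path: str,
                known_snps_path: str, meta_path: str,
                est_reference: Optional[str] = None,
                config: ThresholdConfig = DEFAULT_CONFIG) -> StudyInputs:
    genome = read_genome(genome_path)
    gene_models = read_gene_models(genes_path)
    repeats = read_repeats(repeats_path)
    known = read_known_snps(known_snps_path)
    samples: dict[tuple[str, str], list[VariantObservation]] = {}
    for rec in read_sample_metadata(meta_path):
        samples[(rec.individual, rec.tissue)] = read_variants(
            rec.vcf_path, rec.individual, rec.tissue)
    return StudyInputs(genome=genome, gene_models=gene_models,
                       repeats=repeats, known_snps=known, samples=samples,
                       est_reference=est_reference, config=config)


def run_pipeline(genome_path: str, genes_path: str, repeats_path: str,
                 known_snps_path: str, meta_path: str, outdir: str,
                 est_reference: Optional[str] = None,
                 config: ThresholdConfig = DEFAULT_CONFIG,
                 validate: bool = True) -> RunResult:
    """Load files, run every stage and emit the TSV reports + manifest."""
    inputs = load_inputs(genome_path, genes_path, repeats_path,
                         known_snps_path, meta_path, est_reference, config)
    result = run_study(inputs, validate=validate)
    result.manifest["inputs"] = {
        os.path.basename(p): _digest(p)
        for p in (genome_path, genes_path, repeats_path, known_snps_path,
                  meta_path) if os.path.exists(p)}
    write_reports(result, outdir)
    return result


def write_reports(result: RunResult, outdir: str) -> dict[str, str]:
    os.makedirs(outdir, exist_ok=True)
    paths = {name: os.path.join(outdir, f"{name}.tsv")
             for name in ("sites", "clusters", "spectrum", "tissue_matrix",
                          "pfm", "pairwise")}
    paths["manifest"] = os.path.join(outdir, "manifest.json")

    rows = []
    for site in result.all_sites:
        ann = site.annotation
        rows.append({
            "contig": site.contig, "pos": site.pos, "ref": site.ref,
            "alt": site.alt, "mismatch": site.mismatch.label,
            "strand": site.mismatch.strand,
            "strand_source": site.mismatch.strand_source,
            "origin": site.origin,
            "n_individuals": len(site.individuals),
            "tissues": ",".join(sorted(site.tissues)),
            "mean_ratio": round(site.mean_ratio(), 4),
            "region": ann.region, "gene": ann.gene_symbol or ".",
            "consequence": ann.consequence or ".",
            "aa_change": ann.aa_change or ".",
            "repeat_class": ann.repeat_class or ".",
            "repeat_family": ann.repeat_family or ".",
            "cluster_id": site.cluster_id or ".",
        })
    pd.DataFrame(rows).sort_values(["contig", "pos"]).to_csv(
        paths["sites"], sep="\t", index=False)

    cluster_rows = [{
        "cluster_id": c.id, "contig": c.contig, "span_start": c.span[0],
        "span_end": c.span[1], "n_sites": len(c),
        "members": ",".join(str(s.pos) for s in c.sites)}
        for c in result.combined_clusters]
    pd.DataFrame(cluster_rows).to_csv(paths["clusters"], sep="\t", index=False)

    if result.hc_spectrum is not None:
        result.hc_spectrum.to_csv(paths["spectrum"], sep="\t",
                                  index_label="tissue")
    result.tissue_matrix.to_csv(paths["tissue_matrix"], sep="\t",
                                index_label="site", na_rep="NA")
    if result.pfm is not None:
        result.pfm.to_tsv(paths["pfm"])
    pd.DataFrame([{
        "tissue_a": c.tissue_a, "tissue_b": c.tissue_b, "t": c.t,
        "p": c.p, "q": c.q} for c in result.pairwise]).to_csv(
        paths["pairwise"], sep="\t", index=False)
    if result.validation is not None:
        paths["validation"] = os.path.join(outdir, "validation.tsv")
        result.validation.to_csv(paths["validation"], sep="\t", index=False)
    paths["filter_ledger"] = os.path.join(outdir, "filter_ledger.tsv")
    result.filter_ledger.to_csv(paths["filter_ledger"], sep="\t", index=False)
    with open(paths["manifest"], "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    paths["run_log"] = os.path.join(outdir, "run.log")
    with open(paths["run_log"], "w") as fh:
        for stage, counts in result.manifest["stages"].items():
            fh.write(f"{stage}\t{json.dumps(counts, sort_keys=True)}\n")
        fh.write(f"runtime_s\t{result.manifest.get('runtime_s', 'NA')}\n")
    return paths


def read_threshold_file(path: str) -> ThresholdConfig:
    """key=value threshold file mirroring ThresholdConfig names."""
    mapping: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if not line:
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if raw.lower() in ("true", "false"):
                value: object = raw.lower() == "true"
            elif "," in raw:
                value = tuple(int(x) for x in raw.split(","))
            else:
                try:
                    value = int(raw)
                except ValueError:
                    value = float(raw)
            mapping[key] = value
    return ThresholdConfig.from_mapping(mapping)


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
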