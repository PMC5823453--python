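"""End-to-end walkthrough: simulate a miniature study, then discover its editome.

Generates a 200 kb genome with gene models, SINE-like repeats and planted
clustered A>G editing sites across 3 individuals × 9 tissues, runs the full
filter cascade + recurrence + clustering pipeline on the emitted VCFs, and
scores the calls against the planted truth.
"""

import json
import os
import tempfile

from editome.pipeline import run_pipeline
from editome.synthetic import (
    SyntheticConfig,
    evaluate_recovery,
    generate_reference,
    plant_variants,
    read_truth,
    write_study,
)

config = SyntheticConfig(seed=42, genome_len=200_000, n_genes=12,
                         n_repeats=50, n_edit_sites=40,
                         n_subthreshold_edits=15, n_error_snvs=80,
                         n_known_snps=100, n_private_snps=20)

with tempfile.TemporaryDirectory() as workdir:
    reference = generate_reference(config)
    samples, truth = plant_variants(reference, config)
    paths = write_study(reference, samples, truth, workdir)
    result = run_pipeline(paths["genome"], paths["genes"], paths["repeats"],
                          paths["known_snps"], paths["meta"],
                          os.path.join(workdir, "out"))
    report = evaluate_recovery(result.high_confidence,
                               read_truth(paths["truth"]))

print("stage counts:", json.dumps(result.manifest["stages"]["cascade"]))
print(f"high-confidence sites: {len(result.high_confidence)} "
      f"({result.hc_a_to_i_pct:.1f}% A-to-I; raw pool was "
      f"{result.raw_a_to_i_pct:.1f}%)")
print(f"clusters: {len(result.clusters)} holding "
      f"{sum(len(c) for c in result.clusters)} sites; extension recruited "
      f"{len(result.extended)} SNVs ({result.extended_a_to_i_pct:.0f}% A>G)")
print(f"recovery vs truth: precision={report.precision:.2f} "
      f"recall={report.recall:.2f} (error-SNV leakage: "
      f"{report.fp_by_category.get('error', 0)})")
print("-> the cascade plus the two-individual recurrence rule removes the "
      "planted sequencing errors and private SNPs while keeping the edits, "
      "and the 100 bp extension pulls in the sub-threshold cluster members.")
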