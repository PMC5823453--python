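"""Tissue-level statistics: editing-ratio contrasts, FDR, ADAR correlation.

Constructs a toy cohort of sites with tissue-structured editing ratios,
runs the pairwise pooled t-tests with Benjamini-Hochberg correction, and
correlates per-tissue editing counts with a toy deaminase expression vector.
"""

import numpy as np

from editome.cohort import (
    all_pairwise_comparisons,
    expression_editing_correlation,
    per_tissue_site_counts,
    shared_site_counts,
    tissue_specific_sites,
)
from editome.config import ThresholdConfig
from editome.model import EditingSite, MismatchClass, SampleSupport

config = ThresholdConfig()
rng = np.random.default_rng(15)
tissues = ["brain", "liver", "kidney", "lung"]
shift = {"brain": 0.18, "liver": 0.01, "kidney": 0.0, "lung": 0.0}

sites = []
for i in range(120):
    present = [t for t in tissues if rng.random() < 0.55] or ["brain"]
    supports = [SampleSupport(f"bull{rng.integers(1, 4)}", t,
                              float(np.clip(0.35 + shift[t]
                                            + rng.normal(0, 0.08), 0.1, 0.95)),
                              9, 30) for t in present]
    sites.append(EditingSite(contig="chr1", pos=1000 + i * 7, ref="A",
                             alt="G",
                             mismatch=MismatchClass("A>G", "+", "gene"),
                             supports=supports))

print("per-tissue site counts:", dict(per_tissue_site_counts(sites)))
print("tissue-specific sites:",
      {t: len(v) for t, v in tissue_specific_sites(sites).items()})
print("sites shared by >=3 tissues:", shared_site_counts(sites, 3))

print("\npairwise pooled t-tests (BH-corrected):")
for comp in all_pairwise_comparisons(sites, tissues, config):
    flag = "*" if comp.q < 0.05 else " "
    print(f"  {comp.tissue_a:>6} vs {comp.tissue_b:<6} t={comp.t:+6.2f} "
          f"p={comp.p:.2e} q={comp.q:.2e}{flag}")
print("-> brain's elevated mean ratio survives the FDR correction; the "
      "near-identical pairs do not.")

counts = per_tissue_site_counts(sites)
editing = [counts[t] for t in tissues]
adar_tpm = [60.0, 25.0, 18.0, 22.0]     # deaminase expression, brain-high
r, p = expression_editing_correlation(adar_tpm, editing)
print(f"\nADAR-style expression vs editing counts: Pearson r={r:.2f} "
      f"(p={p:.2f}) across {len(tissues)} tissues")
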