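"""Neighbor-preference matrix and flank validation on a toy editome.

Plants edited adenosines with the ADAR-like T(-1)/G(+1) context bias in a
random genome, builds the ±10 bp position frequency matrix, and checks the
101-nt flanks against a small EST-like reference set.
"""

import numpy as np

from editome.config import ThresholdConfig
from editome.model import EditingSite, GenomeAssembly, MismatchClass, \
    SampleSupport
from editome.motif import extract_flanks, neighbor_pfm
from editome.validation import ValidationProfile, match_reference

config = ThresholdConfig()
rng = np.random.default_rng(8)

seq = list("".join(rng.choice(list("ACGT"), size=50_000)))
positions = []
cursor = 500
while len(positions) < 60 and cursor < 49_500:
    seq[cursor - 1] = "A"
    if rng.random() < 0.8:
        seq[cursor - 2] = "T"     # 5' neighbour biased toward T
    if rng.random() < 0.8:
        seq[cursor] = "G"         # 3' neighbour biased toward G
    positions.append(cursor)
    cursor += int(rng.integers(300, 900))
genome = GenomeAssembly({"chr1": "".join(seq)})

sites = [EditingSite(contig="chr1", pos=p, ref="A", alt="G",
                     mismatch=MismatchClass("A>G", "+", "gene"),
                     supports=[SampleSupport("b1", "brain", 0.3, 9, 30)])
         for p in positions]

pfm = neighbor_pfm(sites, genome, config)
print(f"sites: {len(sites)};  G fraction at -1: "
      f"{pfm.base_fraction(-1, 'G'):.2f}   G fraction at +1: "
      f"{pfm.base_fraction(+1, 'G'):.2f}   background G: ~0.25")
ic = pfm.information_content()
print(f"information content (bits): pos -1 {ic.loc[-1]:.2f}, "
      f"pos 0 {ic.loc[0]:.2f}, pos +1 {ic.loc[+1]:.2f}, "
      f"pos +5 {ic.loc[5]:.2f}")
print("-> the edited A is fixed (2 bits); the immediate neighbours carry the "
      "planted T/G preference; distal positions are near 0 bits.\n")

flanks = [extract_flanks(s, genome, flank=50).seq for s in sites[:10]]
reference = flanks[:4] + ["".join(rng.choice(list('ACGT'), size=150))
                          for _ in range(10)]
hits = match_reference(flanks, reference, ValidationProfile.est(config))
supported = sum(1 for h in hits if h.n_hits > 0)
print(f"EST-style support: {supported}/10 flanks matched the reference set "
      f"at E<=1e-5 (4 were planted verbatim, so 4 are expected)")
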