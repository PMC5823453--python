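# editome

Discovery of adenosine-to-inosine (A-to-I) RNA editing sites from RNA-Seq
variant calls alone — no matched DNA required.

ADAR enzymes deaminate adenosines in double-stranded RNA; the resulting
inosine is read as guanosine, so an edited position appears as an A>G
mismatch between transcriptome reads and the reference genome. Separating
these sites from germline SNPs, sequencing errors and mapping artefacts
using only RNA-Seq is a filtering problem. `editome` implements a stringent
multi-filter strategy for strand-specific cohorts (several individuals,
several tissues) and the downstream characterisation of the resulting
editome: hyper-editing clusters, repeat enrichment, coding consequences,
neighbor-sequence preferences and flank-based validation.

The package is aimed at researchers analysing editing in organisms without
dense SNP catalogues (livestock, non-model vertebrates), where RNA-only
discovery with biological-replicate support is the practical route.

## Method

Starting from per-sample VCFs (HaplotypeCaller-style, with `AD`/`DP` and
GATK site annotations), each observation passes through, in order:

1. **Known-SNP subtraction** — any site present in the SNP catalogue is
   dropped (position-based by default).
2. **Site-quality gates** — fails iff HRun > 5, DP < 10, MQ < 40, QD < 2,
   MQRankSum < −12.5 or ReadPosRankSum < −8 (all strict, re-checked from
   the VCF annotations).
3. **Allele rules** — a single non-reference allele, heterozygous call,
   DP ≥ 10 with ≥ 3 supporting reads, and editing ratio
   φ = AD_alt / DP in **[0.10, 1.0)** — a site edited in 100% of reads is
   treated as a homozygous variant, not editing.
4. **Positional context** — removed if in a bidirectionally transcribed
   region (sense/antisense gene pair), within ±3 bp of a simple sequence
   repeat (perfect tandem repeats, motif 1–8 nt, span ≥ 6), within 5 bp of
   an intron/exon boundary, or if its 101-bp flank aligns to more than one
   genomic locus at ≥ 90% identity over ≥ 90% of the window (paralogs,
   recent repeats).
5. **Recurrence** — a surviving site must be observed in ≥ 2 distinct
   individuals; singleton artefacts and private SNPs fail here.

Surviving sites are strand-resolved from the gene annotation (a genomic
T>C inside a minus-strand gene is A>G on the transcript), clustered by
single linkage at ≤ 100 bp gaps, and the clusters are **extended**: any SNV
that survived stages 1–2 and lies within 100 bp of a high-confidence A>G
site is recruited (single pass). The editome is then annotated (region
precedence CDS > UTR > intron > pseudogene > up/downstream ≤ 5 kb >
intergenic; codon-level consequences; RepeatMasker-style repeat overlap)
and summarised: 12-class mismatch spectra, per-tissue counts and
specificity, pooled-variance t-tests with Benjamini–Hochberg FDR on
editing ratios, a ±10 bp position frequency matrix around the edited A,
and Smith–Waterman flank matching against EST / known-editome sets with
Karlin–Altschul e-values (EST profile E ≤ 1e−5; conservation profile
E ≤ 1e−3, identity ≥ 0.85, alignment ≥ 50 nt).

A first-class synthetic module generates a complete miniature study —
genome, gene models, diverged SINE-like repeats (30% inverted pairs),
clustered edits with the ADAR T(−1)/G(+1) context bias, germline/private
SNPs and error SNVs, 3 individuals × 9 tissues — with a planted-truth
ledger for precision/recall scoring.

## Worked example

```bash
python examples/simulate_and_discover.py
```

prints (seed 42, 200 kb study):

```
stage counts: {"in": 834, "out": 700, "reasons": {"few_alt_reads": 56, "low_ratio": 49, "ssr": 29}}
high-confidence sites: 40 (100.0% A-to-I; raw pool was 42.2%)
clusters: 8 holding 37 sites; extension recruited 16 SNVs (94% A>G)
recovery vs truth: precision=1.00 recall=1.00 (error-SNV leakage: 0)
```

Reading this: of 834 post-subtraction observations, the cascade rejects
each failing observation with exactly one reason; the recurrence rule then
collapses the survivors to 40 sites, all A-to-I even though only 42% of the
raw pool was — the enrichment of the canonical class through the filters is
itself a quality read-out. The 100 bp extension recruits the planted
sub-threshold cluster members (94% of recruits are A>G), and every planted
sequencing error is excluded.

Other narrated examples: `filter_cascade_walkthrough.py` (one rejection
reason per rule), `cluster_extension.py` (gap-linkage and single-pass
recruitment), `motif_and_validation.py` (PFM and EST-style support),
`tissue_statistics.py` (t-tests, FDR, expression correlation).

A thin CLI wraps the same library calls:

```bash
editome simulate --seed 1 -o study/
editome run -g study/genome.fa -a study/genes.gff3 -r study/repeats.bed \
            -k study/known_snps.vcf -m study/meta.tsv -o out/
editome evaluate --calls out/sites.tsv --truth study/truth.tsv
```

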