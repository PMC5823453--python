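# Methods

## The discovery model

RNA-only editing discovery treats every called SNV as a candidate and asks
whether the evidence pattern is more consistent with ADAR activity than
with the alternatives. The filters encode the alternatives explicitly:

| alternative explanation | filter that addresses it |
|---|---|
| known germline SNP | subtraction against the SNP catalogue |
| unknown shared SNP | heterozygosity + the [0.10, 1.0) ratio band (a hom-alt or 100%-ratio site behaves like a variant, not editing) |
| sequencing error | ≥ 3 supporting reads, ≥ 10% of reads, recurrence in ≥ 2 individuals |
| mapping error near repeats/paralogs | flank self-uniqueness, SSR exclusion zone, homopolymer gate |
| splice-alignment artefact | 5 bp intronic margin at exon boundaries |
| antisense ambiguity | bidirectional-transcription removal |

Recurrence is the pivotal assumption: genuine editing is a property of the
species' transcriptome and recurs across unrelated individuals, whereas
rare SNPs and artefacts are private. The deliberate blind spot is a
*shared* unknown SNP — het in two or more individuals at intermediate
allele balance — which is indistinguishable from editing without DNA. The
synthetic module plants private SNPs in one individual only for exactly
this reason; a stress preset with shared unknown SNPs would measure the
blind spot rather than the pipeline.

All numeric cutoffs live in `ThresholdConfig`. Every inequality is strict
as stated (HRun of exactly 5 passes, depth of exactly 10 passes, ratio of
exactly 0.10 passes, ratio 1.0 fails). Missing GATK annotations pass and
are recorded as absent, so VCFs from other callers do not silently zero
the run.

Each rejected observation carries exactly one reason — the first failing
check in the order quality → allele → bidirectional → SSR →
splice-junction → flank-uniqueness — so stage counts always reconcile:
rejections plus survivors equal the stage input, which the pipeline
asserts on every run.

## Strand resolution

VCFs carry no read orientation, so the transcribed strand is taken from
the annotation: an overlapping gene wins; otherwise a gene within 5 kb;
sites flanked by genes on both strands, or by none, keep the genomic
plus-strand label with `strand_source="unknown"`. Sites *covered* by genes
on both strands are removed outright (bidirectional filter). Minus-strand
labels complement both alleles, which is what turns a genomic T>C into
A>G. The twelve labels are closed under complement, so no information is
lost by the convention.

## SSR semantics

The microsatellite finder reports every maximal perfect tandem repeat with
motif length 1–8 and total span ≥ 6 (and at least two full copies). The
reported motif is the lexicographically minimal rotation; non-primitive
units are suppressed, so a poly-A run is reported once as motif `A` and
never again as `AA`. Partial trailing copies extend the span but not the
copy count. A site is SSR-biased if it falls within ±3 bp of any such
interval. These are the stated bounds of the original tool being
emulated; its undocumented tie-breaks are replaced by the
maximal-primitive-repeat semantics above, which a brute-force enumeration
oracle pins down exactly in the tests.

## Flank uniqueness

The 101-bp window (50 bp each side, clipped at contig edges and flagged)
is searched against the whole assembly on both strands with 16-mer exact
seeds grouped by diagonal, each candidate locus verified by affine-gap
Smith–Waterman (match +1, mismatch −2, gap open 5, extend 2). The site is
unique iff exactly one locus — the self-hit — reaches ≥ 90% identity over
≥ 90% of the window. An all-N window is conservatively non-unique. Seeded
search shares the standard limitation of seed-and-extend tools: a
duplicate at exactly the 90% boundary with adversarially even mismatch
spacing can lack a 16-mer seed and be missed; at the divergence levels of
real repeat families (≥ 10%, clustered) this is immaterial, and the tests
compare against an exhaustive local-alignment oracle on ≤ 100 kb genomes.
For genome-scale work an external aligner's PSL output can be ingested
instead (`unique_from_psl`).

## Clusters and extension

"Two or more sites within a 100 bp window" is read as gap-linkage: sites
chain while consecutive gaps are ≤ 100 bp (inclusive), so a cluster's span
may exceed 100 bp. The alternative span-bounded reading would arbitrarily
split long hyper-edited runs, which is the phenomenon of interest.

Extension recruits, from the pool of SNVs that survived only quality
filtering and SNP subtraction, any SNV within 100 bp of a high-confidence
A>G site. Recruitment is anchored on the initial candidates and is
single-pass — recruits do not themselves recruit — because iterated
closure would let a chain of marginal SNVs walk arbitrarily far from the
evidence; a `transitive_extension` switch exists for comparison. Recruits
keep their own mismatch class and no allele filters are re-applied, so the
A>G share of the added set remains an honest read-out of its quality.

## Statistics

Tissue contrasts use the classic pooled-variance two-sample t-test on
per-site mean editing ratios (a site's per-tissue ratio is the mean over
that tissue's supporting samples), with Benjamini–Hochberg correction
across all tissue pairs and significance at q < 0.05; Welch's variant is a
config switch. Degenerate contrasts (zero variance both sides, equal
means) are assigned p = 1. Expression–editing association is a Pearson
correlation over tissues (n ≥ 3 enforced).

Flank validation aligns each 101-nt flank against every reference record
(both orientations) with the same Smith–Waterman scheme; significance is
Karlin–Altschul, E = K·m·n·e^(−λS) with the database-size n. λ is solved
numerically from Σpᵢe^(λsᵢ) = 1 under uniform composition (≈ 1.33 for
+1/−2); K uses the standard tabulated ungapped value 0.621 for this
scheme. Replicating a full search engine's edge-effect and composition
corrections is a non-goal: at 101-nt queries the identity/length
thresholds dominate the decision, and a BLAST outfmt-6 ingest is provided
for real-scale searches.

The neighbor-preference matrix counts bases at −10..+10 around the edited
A on the transcribed strand; information content is 2 − H (Shannon, bits)
with no small-sample correction; clipped sites contribute only the
columns they cover.

## Annotation choices

Region precedence is CDS > UTR5/UTR3 > intron > pseudogene > upstream >
downstream > intergenic, with upstream/downstream strand-aware within
5 kb. When transcripts disagree, the highest-precedence region wins; no
canonical-transcript selection is attempted. Consequences are computed
only for transcripts whose CDS length is divisible by 3 (others are
flagged incomplete at parse time); the codon is rebuilt on the coding
strand from the CDS intervals, the edited base substituted, and both amino
acids reported (`Asn→Asp` style). Stop gain/loss are reported for
completeness of the genetic code. Repeat overlap reports the single
overlapping feature, longest interval first, ties by coordinate.

## The synthetic study

The generator emulates the structure the method assumes: one 1 Mb contig;
30 genes (intron/exon/CDS/UTR on both strands, a tenth as pseudogenes,
two antisense overlaps creating genuine bidirectional zones); 200 repeat
copies (SINE-like 150 bp consensus at 15% per-copy divergence — far enough
that 101-bp flanks stay unique — 30% as inverted pairs, plus LINE- and
DNA-class minorities); 120 clustered A>G edits (cluster sizes geometric
with mean 3 capped at 8, gaps 10–90 bp, 80% inside genic repeats, T(−1)
and G(+1) context biases at probability 0.5 each, ratios Beta(2,4)
truncated to [0.10, 0.95], present in 2–3 individuals and each tissue with
probability 0.6); 40 sub-threshold cluster members (single individual,
ratios truncated to [0.02, 0.30]) that only the extension step can
recover; 300 singleton error SNVs uniform over the 12 classes; 400
catalogued germline SNPs present in all individuals; 60 private SNPs
deliberately absent from the catalogue. Read support is binomial at the
site's true ratio with Poisson(40) depth floored at 10; reads themselves
are never simulated, matching a pipeline that consumes VCFs.

What passing on this study shows: the cascade's bookkeeping, strand logic,
recurrence, clustering and extension behave as specified under realistic
count noise. What it cannot show: robustness to alignment artefacts,
coverage heterogeneity between samples, allele-specific expression, or
shared unknown SNPs — none of which exist in the generator. Sample sizes
(3 individuals × 9 tissues) mirror the cohort structure the method was
designed around; the 1 Mb genome keeps a full run in tens of seconds while
leaving every filter with genuine work to do.

## Numerical and degenerate-input conventions

Coordinates are 1-based inclusive internally (VCF-native); BED is
converted at the reading boundary. Zero-depth ratios are an error, not 0.
Multi-allelic records are retained at parse time and rejected by the
cascade with the `multi_allelic` reason, so the ledger shows the method's
stated rationale rather than a silent parser drop. Known-SNP subtraction
is position-based (an allele-aware switch exists) since a catalogued SNP
at a site makes it untrustworthy regardless of allele. All randomness
flows through a single seed; equal seeds give byte-identical studies and
reports.

## Known limitations

RNA-only discovery cannot see DNA: shared unknown SNPs are reported as
editing. Sites more than 5 kb from any annotated gene cannot be
strand-resolved and are labelled on the plus strand, flagged unknown.
Recall is bounded by the ratio band — genuinely low-ratio editing
(< 10% of reads) is excluded by design and only partially recovered via
cluster extension. The e-value machinery is an ungapped approximation; use
the tabular ingest when exact search-engine statistics matter.
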