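import numpy as np
import pytest

from editome.model import (
    Gene,
    GeneModelSet,
    GenomeAssembly,
    Transcript,
    VariantObservation,
)


def make_variant(contig="c1", pos=100, ref="A", alt="G", dp=40, ad=12,
                 gt="het", individual="bull1", tissue="liver",
                 annotations=None, multi=False, alts=None):
    return VariantObservation(
        contig=contig, pos=pos, ref=ref, alt=alt, total_depth=dp,
        alt_depth=ad, genotype=gt, individual=individual, tissue=tissue,
        annotations=annotations or {}, multi_allelic=multi,
        all_alts=tuple(alts) if alts else (alt,))


@pytest.fixture
def random_genome():
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    return GenomeAssembly({"c1": seq})


@pytest.fixture
def gene_fixture():
    """Two coding genes (one per strand), a pseudogene, and an antisense
    pair creating a bidirectional zone."""
    plus = Gene(
        id="gplus", symbol="GPLUS", biotype="protein_coding", contig="c1",
        strand="+",
        transcripts=[Transcript(
            id="tplus",
            exons=[(1001, 1200), (2001, 2200), (3001, 3300)],
            utr5=[(1001, 1100)],
            cds=[(1101, 1200, 0), (2001, 2200, 0), (3001, 3100, 0)],
            utr3=[(3101, 3300)])])
    minus = Gene(
        id="gminus", symbol="GMINUS", biotype="protein_coding", contig="c1",
        strand="-",
        transcripts=[Transcript(
            id="tminus",
            exons=[(5001, 5300), (6001, 6200)],
            utr3=[(5001, 5100)],
            cds=[(5101, 5300, 0), (6001, 6100, 0)],
            utr5=[(6101, 6200)])])
    pseudo = Gene(
        id="gpseudo", symbol="PSG1", biotype="pseudogene", contig="c1",
        strand="+",
        transcripts=[Transcript(id="tpseudo", exons=[(8001, 8600)])])
    sense = Gene(
        id="gsense", symbol="SENSE", biotype="protein_coding", contig="c2",
        strand="+",
        transcripts=[Transcript(id="tsense", exons=[(100, 900)])])
    anti = Gene(
        id="ganti", symbol="ANTI", biotype="other", contig="c2", strand="-",
        transcripts=[Transcript(id="tanti", exons=[(500, 1400)])])
    return GeneModelSet([plus, minus, pseudo, sense, anti])


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A written small synthetic study plus its end-to-end pipeline result."""
    from editome.pipeline import run_pipeline
    from editome.synthetic import (
        SyntheticConfig, generate_reference, plant_variants, write_study)

    cfg = SyntheticConfig(seed=11, genome_len=200_000, n_genes=12,
                          n_repeats=50, n_edit_sites=40,
                          n_subthreshold_edits=15, n_error_snvs=80,
                          n_known_snps=100, n_private_snps=20)
    reference = generate_reference(cfg)
    samples, truth = plant_variants(reference, cfg)
    outdir = tmp_path_factory.mktemp("study")
    paths = write_study(reference, samples, truth, str(outdir))
    result = run_pipeline(paths["genome"], paths["genes"], paths["repeats"],
                          paths["known_snps"], paths["meta"],
                          str(outdir / "out"))
    return {"config": cfg, "reference": reference, "samples": samples,
            "truth": truth, "paths": paths, "result": result,
            "outdir": str(outdir)}
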