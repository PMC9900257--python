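import numpy as np
import pytest
from Bio.Seq import Seq

from varscape.fixtures import FixtureSpec, make_bundle
from varscape.genemodel import (
    GenomicInterval,
    TranscriptModel,
    extract_cds,
    load_gene_model,
    select_canonical,
)

SEED = 11

TINY_CDS = "ATGTGGTAA"          # M W *  (two CDS pieces: ATGTG + GTAA)


def _write_fasta(path, name, seq, width=60):
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")


def make_tiny_transcript(tmpdir, strand):
    """Two-exon toy gene carrying the CDS ATGTG|GTAA, either strand.

    Returns (TranscriptModel, fasta_path).  The minus-strand twin carries
    the reverse complement at the mirrored layout so both encode MW*.
    """
    rng = np.random.default_rng(42)
    pad = "".join(rng.choice(list("ACGT"), size=10))
    intron = "GTACAG"
    transcript_dir = "ATGTG" + intron + "GTAA"      # t-coords 1..15
    if strand == "+":
        contig = pad + transcript_dir + pad
        exons = [GenomicInterval("chrT", 11, 15, "+"),
                 GenomicInterval("chrT", 22, 25, "+")]
    else:
        contig = pad + str(Seq(transcript_dir).reverse_complement()) + pad
        # t 1..5 -> g 21..25 ; t 12..15 -> g 11..14
        exons = [GenomicInterval("chrT", 21, 25, "-"),
                 GenomicInterval("chrT", 11, 14, "-")]
    fasta = str(tmpdir / f"tiny_{'plus' if strand == '+' else 'minus'}.fa")
    _write_fasta(fasta, "chrT", contig)
    t = TranscriptModel(
        transcript_id="TINY1", gene_symbol="TINY",
        exons=exons, cds=list(exons))
    return t, fasta


@pytest.fixture(scope="session")
def tiny_plus(tmp_path_factory):
    return make_tiny_transcript(tmp_path_factory.mktemp("tiny_p"), "+")


@pytest.fixture(scope="session")
def tiny_minus(tmp_path_factory):
    return make_tiny_transcript(tmp_path_factory.mktemp("tiny_m"), "-")


@pytest.fixture(scope="session")
def spec_plus():
    return FixtureSpec(seed=SEED)


@pytest.fixture(scope="session")
def bundle_plus(tmp_path_factory, spec_plus):
    outdir = tmp_path_factory.mktemp("bundle_plus")
    return make_bundle(spec_plus, outdir)


@pytest.fixture(scope="session")
def spec_minus():
    return FixtureSpec(seed=SEED, strand="-")


@pytest.fixture(scope="session")
def bundle_minus(tmp_path_factory, spec_minus):
    outdir = tmp_path_factory.mktemp("bundle_minus")
    return make_bundle(spec_minus, outdir)


def _canonical(bundle, symbol="GENE1"):
    models = load_gene_model(
        bundle["gff3"], bundle["fasta"], symbol,
        mane_tsv=bundle["mane"], appris_tsv=bundle["appris"])
    t = select_canonical(models)
    return models, t, extract_cds(t, bundle["fasta"])


@pytest.fixture(scope="session")
def gene_plus(bundle_plus):
    """(all transcripts, canonical transcript, coding sequence), plus strand."""
    return _canonical(bundle_plus)


@pytest.fixture(scope="session")
def gene_minus(bundle_minus):
    return _canonical(bundle_minus)
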