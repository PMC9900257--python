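"""Synthetic input bundles with planted, recoverable structure.

Everything the pipeline consumes can be generated here: a gene model
(GFF3 + FASTA + MANE/APPRIS label TSVs, with decoy transcripts so
canonical selection is exercised), a bgzip+tabix per-SNV score table with
a planted spatial signal, ClinVar-like and allele-count tables with a
planted pathogenic hotspot and benign background, a protein-feature TSV
and a score-registry TSV.  A single seed makes every file byte-reproducible,
and the planted structure (hotspot location, signal shape, pathogenic-vs-
benign score offset) is recoverable by the downstream analysis, which is
what the end-to-end tests check.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pysam
from Bio.Seq import Seq

from . import genemodel, variantsim
from .genemodel import TranscriptModel, extract_cds, load_gene_model, select_canonical

SENSE_CODONS = sorted(c for c, aa in variantsim.CODON_TO_AA.items() if aa != "*")

SCORE_COLUMNS = ("REVEL_score", "CADD_phred", "SIFT_score")
CANONICAL_ID = "TX001"
DECOY_IDS = ("TX002", "TX003")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic gene / score / variant generator.

    Defaults describe a mid-sized disease gene: a 412-residue protein
    (1239-nt CDS over 4 exons), a pathogenic hotspot spanning amino acids
    260-280 (30 P/LP variants), 30 B/LB variants elsewhere, a quadratic
    positional score signal with sd-0.05 noise, and a +0.4 score offset of
    pathogenic over background.
    """

    gene_symbol: str = "GENE1"
    chrom: str = "chrS"
    n_exons: int = 4
    cds_length: int = 1239
    strand: str = "+"
    intron_lengths: tuple[int, ...] = (220, 160, 310)
    utr5: int = 30
    utr3: int = 30
    hotspot: tuple[int, int, int] = (270, 10, 30)   # center AA, half-width, n P/LP
    n_benign: int = 30
    score_signal: str = "quadratic"   # constant|linear|quadratic|bimodal
    noise_sd: float = 0.05
    group_effect: float = 0.4         # pathogenic-vs-background score offset
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cds_length % 3 != 0:
            raise ValueError("cds_length must be a multiple of 3")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if len(self.intron_lengths) != self.n_exons - 1:
            raise ValueError("need n_exons-1 intron lengths")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        center, hw, _ = self.hotspot
        if not 1 <= center - hw < center + hw <= self.protein_length:
            raise ValueError("hotspot outside protein")

    @property
    def protein_length(self) -> int:
        return self.cds_length // 3 - 1


def signal_value(spec: FixtureSpec, aa_pos) -> np.ndarray:
    """Planted positional score signal, values within [0.1, 0.9]."""
    L = spec.protein_length
    p = np.asarray(aa_pos, dtype=float)
    u = (p - (L + 1) / 2) / ((L - 1) / 2)          # [-1, 1]
    if spec.score_signal == "constant":
        return np.full_like(p, 0.5)
    if spec.score_signal == "linear":
        return 0.5 + 0.3 * u
    if spec.score_signal == "quadratic":
        return 0.2 + 0.6 * u ** 2
    if spec.score_signal == "bimodal":
        return 0.25 + 0.55 * (
            np.exp(-((p - 0.25 * L) / (0.08 * L)) ** 2)
            + np.exp(-((p - 0.75 * L) / (0.08 * L)) ** 2))
    raise ValueError(f"unknown score_signal {spec.score_signal!r}")


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _split_cds(spec: FixtureSpec, rng) -> list[int]:
    """Deliberately codon-unaligned exon chunk sizes of the CDS."""
    n = spec.n_exons
    base = spec.cds_length // n
    sizes = [base] * n
    sizes[-1] += spec.cds_length - base * n
    for i in range(n - 1):                      # jitter splits off codon phase
        shift = int(rng.integers(-7, 8))
        if sizes[i] + shift >= 30 and sizes[i + 1] - shift >= 30:
            sizes[i] += shift
            sizes[i + 1] -= shift
    if min(sizes) < 30:
        raise ValueError("exon chunks shorter than CDS allows")
    return sizes


def _write_fasta(path, name: str, seq: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")


def make_gene(spec: FixtureSpec, outdir) -> dict[str, str]:
    """Write GFF3 + FASTA + MANE/APPRIS TSVs for a synthetic gene.

    The canonical transcript carries the full CDS and a MANE label; two
    decoy transcripts share the exon structure with 3'-trimmed CDS and
    APPRIS labels (principal2, alternative1) so canonical selection has
    real work to do.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    coding = ["ATG"]
    coding += list(rng.choice(SENSE_CODONS, size=spec.cds_length // 3 - 2))
    coding.append("TAA")
    cds_seq = "".join(coding)

    chunks = _split_cds(spec, rng)
    gene_parts = [_random_seq(rng, spec.utr5)]
    t_exons: list[tuple[int, int]] = []
    t_cds: list[tuple[int, int]] = []
    t = spec.utr5                     # bases laid down so far
    cds_off = 0
    for i, c in enumerate(chunks):
        exon_start = t + 1 if i > 0 else 1
        gene_parts.append(cds_seq[cds_off: cds_off + c])
        t_cds.append((t + 1, t + c))
        t += c
        cds_off += c
        if i < len(chunks) - 1:
            t_exons.append((exon_start, t))
            ilen = spec.intron_lengths[i]
            intron = "GT" + _random_seq(rng, ilen - 4) + "AG"
            gene_parts.append(intron)
            t += ilen
        else:
            gene_parts.append(_random_seq(rng, spec.utr3))
            t += spec.utr3
            t_exons.append((exon_start, t))
    gene_seq = "".join(gene_parts)
    N = len(gene_seq)
    offset = 1000
    contig = _random_seq(rng, offset) + gene_seq + _random_seq(rng, 500)

    if spec.strand == "-":
        contig = (contig[:offset] + str(Seq(gene_seq).reverse_complement())
                  + contig[offset + N:])

        def g(iv):
            t1, t2 = iv
            return (offset + N - t2 + 1, offset + N - t1 + 1)
    else:
        def g(iv):
            return (offset + iv[0], offset + iv[1])

    fasta_path = os.path.join(outdir, "genome.fa")
    _write_fasta(fasta_path, spec.chrom, contig)

    # decoy CDS sets: trim codons from the 3' end (t-space end of last chunk)
    def trimmed_cds(trim: int):
        out = list(t_cds)
        s, e = out[-1]
        out[-1] = (s, e - trim)
        return out

    transcripts = [
        (CANONICAL_ID, t_cds),
        (DECOY_IDS[0], trimmed_cds(9)),
        (DECOY_IDS[1], trimmed_cds(18)),
    ]

    gene_g = (min(g(iv)[0] for iv in t_exons), max(g(iv)[1] for iv in t_exons))
    gff3_path = os.path.join(outdir, "gene.gff3")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write("\t".join([
            spec.chrom, "varscape", "gene", str(gene_g[0]), str(gene_g[1]),
            ".", spec.strand, ".",
            f"ID=gene:{spec.gene_symbol};Name={spec.gene_symbol}"]) + "\n")
        for tid, cds_ivs in transcripts:
            fh.write("\t".join([
                spec.chrom, "varscape", "mRNA", str(gene_g[0]),
                str(gene_g[1]), ".", spec.strand, ".",
                f"ID={tid};Parent=gene:{spec.gene_symbol}"]) + "\n")
            for j, iv in enumerate(t_exons, 1):
                s, e = g(iv)
                fh.write("\t".join([
                    spec.chrom, "varscape", "exon", str(s), str(e), ".",
                    spec.strand, ".",
                    f"ID={tid}.exon{j};Parent={tid}"]) + "\n")
            for j, iv in enumerate(cds_ivs, 1):
                s, e = g(iv)
                fh.write("\t".join([
                    spec.chrom, "varscape", "CDS", str(s), str(e), ".",
                    spec.strand, "0",
                    f"ID={tid}.cds{j};Parent={tid}"]) + "\n")

    mane_path = os.path.join(outdir, "mane.tsv")
    with open(mane_path, "w") as fh:
        fh.write(f"{CANONICAL_ID}\tMANE_Select\n")
    appris_path = os.path.join(outdir, "appris.tsv")
    with open(appris_path, "w") as fh:
        fh.write(f"{CANONICAL_ID}\tprincipal1\n")
        fh.write(f"{DECOY_IDS[0]}\tprincipal2\n")
        fh.write(f"{DECOY_IDS[1]}\talternative1\n")

    return {"gff3": gff3_path, "fasta": fasta_path,
            "mane": mane_path, "appris": appris_path}


def _load_canonical(spec: FixtureSpec, gene_files) -> tuple[TranscriptModel, genemodel.CodingSequence]:
    models = load_gene_model(
        gene_files["gff3"], gene_files["fasta"], spec.gene_symbol,
        mane_tsv=gene_files["mane"], appris_tsv=gene_files["appris"])
    t = select_canonical(models)
    return t, extract_cds(t, gene_files["fasta"])


def _plan_variants(spec: FixtureSpec, variants):
    """Deterministically pick the planted P/LP and B/LB missense variants.

    Shared by :func:`make_scores` and :func:`make_variants` so the score
    offset and the ClinVar labels always agree without passing state.
    """
    rng = np.random.default_rng(spec.seed + 104729)
    center, hw, n_path = spec.hotspot
    missense = [v for v in variants if v.consequence == "missense"]
    in_hot = [v for v in missense if center - hw <= v.codon_index <= center + hw]
    out_hot = [v for v in missense if not center - hw <= v.codon_index <= center + hw]
    if len(in_hot) < n_path:
        raise ValueError(
            f"hotspot holds only {len(in_hot)} missense SNVs, "
            f"need {n_path}")
    if len(out_hot) < spec.n_benign:
        raise ValueError("not enough missense SNVs outside the hotspot")
    path_idx = rng.choice(len(in_hot), size=n_path, replace=False)
    ben_idx = rng.choice(len(out_hot), size=spec.n_benign, replace=False)
    pathogenic = [in_hot[i] for i in sorted(path_idx)]
    benign = [out_hot[i] for i in sorted(ben_idx)]
    return pathogenic, benign


def make_scores(spec: FixtureSpec, gene_files, outdir=None) -> str:
    """Write the bgzip+tabix per-SNV score table.

    One row per enumerated SNV of the canonical CDS; missense rows carry
    ``signal(aa_pos) + N(0, sd)`` clipped to [0, 1] (planted pathogenic
    variants shifted by ``group_effect``), other consequences are missing.
    About ``missing_rate`` of score cells are masked with '.'.  A share of
    rows uses two ';'-separated per-transcript slots (decoy first) so slot
    resolution is exercised.
    """
    outdir = outdir or os.path.dirname(gene_files["gff3"])
    t, cds = _load_canonical(spec, gene_files)
    variants = variantsim.enumerate_all_snvs(cds, t, initiator_aware=False)
    pathogenic, _ = _plan_variants(spec, variants)
    path_keys = {v.key for v in pathogenic}

    rng = np.random.default_rng(spec.seed + 7919)
    rows = []
    for v in variants:
        if v.consequence == "missense":
            value = float(signal_value(spec, v.codon_index))
            if v.key in path_keys:
                value += spec.group_effect
            value += rng.normal(0, spec.noise_sd)
            value = float(np.clip(value, 0.0, 1.0))
            revel = round(value, 4)
            cadd = round(min(99.0, value * 40.0), 2)
            sift = round(1.0 - value, 4)
            vals = [revel, cadd, sift]
        else:
            vals = [None, None, None]
        cells = []
        two_slot = rng.random() < 0.3
        for val in vals:
            if val is not None and rng.random() < spec.missing_rate:
                val = None
            if val is None:
                cells.append(".")
            elif two_slot:
                decoy = round(max(0.0, 1.0 - float(val)), 4)
                cells.append(f"{decoy};{val}")
            else:
                cells.append(str(val))
        tx_cell = (f"{DECOY_IDS[0]};{CANONICAL_ID}" if two_slot
                   else CANONICAL_ID)
        rows.append((v.gpos, v.ref_base, v.alt_base,
                     str(v.codon_index), tx_cell, cells))

    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    plain = os.path.join(outdir, "scores.tsv")
    with open(plain, "w") as fh:
        fh.write("#chr\tpos(1-based)\tref\talt\taapos\tEnsembl_transcriptid\t"
                 + "\t".join(SCORE_COLUMNS) + "\n")
        for gpos, ref, alt, aapos, tx, cells in rows:
            fh.write("\t".join(
                [spec.chrom, str(gpos), ref, alt, aapos, tx] + cells) + "\n")
    gz = plain + ".gz"
    pysam.tabix_compress(plain, gz, force=True)
    os.remove(plain)
    pysam.tabix_index(gz, seq_col=0, start_col=1, end_col=1,
                      meta_char="#", force=True)
    return gz


def make_variants(spec: FixtureSpec, gene_files, outdir=None) -> dict[str, str]:
    """Write the ClinVar-like TSV and the exomes/genomes allele-count TSVs.

    P/LP variants cluster in the hotspot and are absent from, or singletons
    in, the population tables; B/LB variants sit elsewhere with allele
    frequencies log-uniform in [1e-5, 1e-2].  A couple of uncertain records
    and one intronic splice record are added for the plots.
    """
    outdir = outdir or os.path.dirname(gene_files["gff3"])
    t, cds = _load_canonical(spec, gene_files)
    variants = variantsim.enumerate_all_snvs(cds, t, initiator_aware=False)
    pathogenic, benign = _plan_variants(spec, variants)
    rng = np.random.default_rng(spec.seed + 15485863)

    clinvar_path = os.path.join(outdir, "clinvar.tsv")
    with open(clinvar_path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tvariant_type\t"
                 "clinical_significance\tphenotype\tprotein_change\n")
        for i, v in enumerate(pathogenic):
            sig = "Pathogenic" if i % 2 == 0 else "Likely pathogenic"
            fh.write("\t".join([
                v.chrom, str(v.gpos), v.ref_base, v.alt_base, "missense",
                sig, "synthetic disorder", v.protein_change]) + "\n")
        for i, v in enumerate(benign):
            sig = "Benign" if i % 2 == 0 else "Likely benign"
            fh.write("\t".join([
                v.chrom, str(v.gpos), v.ref_base, v.alt_base, "missense",
                sig, "not provided", v.protein_change]) + "\n")
        uncertain = [v for v in variants if v.consequence == "missense"][:2]
        for v in uncertain:
            fh.write("\t".join([
                v.chrom, str(v.gpos), v.ref_base, v.alt_base, "missense",
                "Uncertain significance", "not provided",
                v.protein_change]) + "\n")
        # one intronic splice-region record for the transcript plot
        if len(t.exons) > 1:
            e1, e2 = sorted(t.exons, key=lambda iv: iv.start)[:2]
            ipos = e1.end + 2
            fh.write("\t".join([
                t.chrom, str(ipos), "G", "A", "splice",
                "Likely pathogenic", "synthetic disorder", ""]) + "\n")

    an = {"exomes": 250000, "genomes": 150000}
    pop_rows = {"exomes": [], "genomes": []}
    for v in benign:
        af = 10 ** rng.uniform(-5, -2)
        datasets = ["exomes"]
        if rng.random() < 0.5:
            datasets.append("genomes")
        for ds in datasets:
            ac = max(1, int(round(af * an[ds])))
            pop_rows[ds].append((v.chrom, v.gpos, v.ref_base, v.alt_base,
                                 ac, an[ds]))
    for v in pathogenic:
        if rng.random() < 0.3:          # singleton or absent
            pop_rows["exomes"].append(
                (v.chrom, v.gpos, v.ref_base, v.alt_base, 1, an["exomes"]))

    paths = {"clinvar": clinvar_path}
    for ds in ("exomes", "genomes"):
        p = os.path.join(outdir, f"{ds}.tsv")
        with open(p, "w") as fh:
            fh.write("chrom\tpos\tref\talt\tac\tan\n")
            for row in sorted(pop_rows[ds], key=lambda r: r[1]):
                fh.write("\t".join(map(str, row)) + "\n")
        paths[ds] = p
    return paths


def make_features(spec: FixtureSpec, outdir) -> str:
    """Write a UniProt-like protein feature TSV (domains overlap a region)."""
    L = spec.protein_length
    center, hw, _ = spec.hotspot
    path = os.path.join(outdir, "features.tsv")
    with open(path, "w") as fh:
        fh.write("feature_type\tlabel\tstart\tend\n")
        fh.write(f"domain\tN-lobe\t{max(1, L // 8)}\t{L // 3}\n")
        fh.write(f"region\tLinker\t{L // 3 - 10}\t{L // 2}\n")
        fh.write(f"domain\tCatalytic\t{max(1, center - 3 * hw)}"
                 f"\t{min(L, center + 3 * hw)}\n")
    return path


def make_registry(outdir) -> str:
    """Write the registry TSV rows for the fixture's three score columns."""
    path = os.path.join(outdir, "registry.tsv")
    with open(path, "w") as fh:
        fh.write("name\torientation\tcutoff\tmin\tmax\n")
        fh.write("REVEL_score\thigher_damaging\t0.5\t0\t1\n")
        fh.write("CADD_phred\thigher_damaging\t20\t0\t99\n")
        fh.write("SIFT_score\tlower_damaging\t0.05\t0\t1\n")
    return path


def make_bundle(spec: FixtureSpec, outdir) -> dict[str, str]:
    """Generate every synthetic input file the pipeline needs."""
    os.makedirs(outdir, exist_ok=True)
    paths = make_gene(spec, outdir)
    paths["scores"] = make_scores(spec, paths, outdir)
    paths.update(make_variants(spec, paths, outdir))
    paths["features"] = make_features(spec, outdir)
    paths["registry"] = make_registry(outdir)
    return paths
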