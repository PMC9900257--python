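"""Readers for the three external variant-table dialects and group assignment.

Three inputs are consumed as local files: a ClinVar-like summary TSV
(chrom, pos, ref, alt, variant_type, clinical_significance, phenotype,
protein_change), per-dataset allele-count TSVs (chrom, pos, ref, alt, ac,
an), and a bgzip-compressed, tabix-indexed per-SNV score table in the
dbNSFP column dialect (chr, pos(1-based), ref, alt, aapos,
Ensembl_transcriptid, then one column per score; ``.`` marks missing and
``;`` separates per-transcript value lists).
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass, field

import pysam

from .genemodel import GenomicInterval
from .groupstats import GroupedScores
from .variantsim import SimulatedVariant

logger = logging.getLogger(__name__)

SIGNIFICANCE_VOCAB = (
    "pathogenic", "likely_pathogenic", "benign", "likely_benign",
    "uncertain", "conflicting",
)

_SIGNIFICANCE_MAP = {
    "pathogenic": "pathogenic",
    "likely pathogenic": "likely_pathogenic",
    "likely_pathogenic": "likely_pathogenic",
    "pathogenic/likely pathogenic": "likely_pathogenic",
    "pathogenic/likely_pathogenic": "likely_pathogenic",
    "benign": "benign",
    "likely benign": "likely_benign",
    "likely_benign": "likely_benign",
    "benign/likely benign": "likely_benign",
    "benign/likely_benign": "likely_benign",
    "uncertain significance": "uncertain",
    "uncertain_significance": "uncertain",
    "uncertain": "uncertain",
    "conflicting interpretations of pathogenicity": "conflicting",
    "conflicting classifications of pathogenicity": "conflicting",
    "conflicting": "conflicting",
}

PATHOGENIC_GROUP = ("pathogenic", "likely_pathogenic")
BENIGN_GROUP = ("benign", "likely_benign")


@dataclass(frozen=True)
class ClinVarRecord:
    chrom: str
    gpos: int
    ref: str
    alt: str
    variant_type: str
    significance: str
    phenotype: str = ""
    protein_change: str | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.gpos, self.ref, self.alt)

    @property
    def is_pathogenic(self) -> bool:
        return self.significance in PATHOGENIC_GROUP

    @property
    def is_benign(self) -> bool:
        return self.significance in BENIGN_GROUP


@dataclass(frozen=True)
class PopulationCount:
    chrom: str
    gpos: int
    ref: str
    alt: str
    dataset: str            # "exomes" | "genomes"
    ac: int
    an: int

    @property
    def af(self) -> float:
        """Allele frequency, always recomputed as ac/an."""
        return self.ac / self.an

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.gpos, self.ref, self.alt)


@dataclass(frozen=True)
class ScoreMeta:
    """Orientation and published damaging cutoff of one pathogenicity score."""

    name: str
    orientation: str              # "higher_damaging" | "lower_damaging"
    damaging_cutoff: float
    value_range: tuple[float, float] | None = None   # None = unbounded

    def __post_init__(self) -> None:
        if self.orientation not in ("higher_damaging", "lower_damaging"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.value_range is not None:
            lo, hi = self.value_range
            if not lo <= self.damaging_cutoff <= hi:
                raise ValueError(
                    f"{self.name}: cutoff {self.damaging_cutoff} outside "
                    f"range {self.value_range}")

    def is_damaging(self, value: float) -> bool:
        if self.orientation == "higher_damaging":
            return value >= self.damaging_cutoff
        return value <= self.damaging_cutoff


@dataclass
class ScoreRecord:
    chrom: str
    gpos: int
    ref: str
    alt: str
    aa_pos: int | None
    values: dict[str, float | None] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.gpos, self.ref, self.alt)


def _meta(name, orientation, cutoff, rng=None):
    return ScoreMeta(name, orientation, cutoff, rng)


#: Registry of the 43 per-SNV pathogenicity/conservation score columns of
#: the dbNSFP v4.3a dialect, each with orientation and its commonly used
#: damaging cutoff.  Unknown columns can be registered at run time.
DEFAULT_SCORE_REGISTRY: dict[str, ScoreMeta] = {m.name: m for m in [
    _meta("SIFT_score", "lower_damaging", 0.05, (0, 1)),
    _meta("SIFT4G_score", "lower_damaging", 0.05, (0, 1)),
    _meta("Polyphen2_HDIV_score", "higher_damaging", 0.453, (0, 1)),
    _meta("Polyphen2_HVAR_score", "higher_damaging", 0.447, (0, 1)),
    _meta("LRT_score", "lower_damaging", 0.001, (0, 1)),
    _meta("MutationTaster_score", "higher_damaging", 0.5, (0, 1)),
    _meta("MutationAssessor_score", "higher_damaging", 1.935),
    _meta("FATHMM_score", "lower_damaging", -1.5),
    _meta("PROVEAN_score", "lower_damaging", -2.5),
    _meta("VEST4_score", "higher_damaging", 0.5, (0, 1)),
    _meta("MetaSVM_score", "higher_damaging", 0.0),
    _meta("MetaLR_score", "higher_damaging", 0.5, (0, 1)),
    _meta("MetaRNN_score", "higher_damaging", 0.5, (0, 1)),
    _meta("M-CAP_score", "higher_damaging", 0.025, (0, 1)),
    _meta("REVEL_score", "higher_damaging", 0.5, (0, 1)),
    _meta("MutPred_score", "higher_damaging", 0.611, (0, 1)),
    _meta("MVP_score", "higher_damaging", 0.7, (0, 1)),
    _meta("MPC_score", "higher_damaging", 2.0),
    _meta("PrimateAI_score", "higher_damaging", 0.803, (0, 1)),
    _meta("DEOGEN2_score", "higher_damaging", 0.5, (0, 1)),
    _meta("BayesDel_addAF_score", "higher_damaging", 0.0692655),
    _meta("BayesDel_noAF_score", "higher_damaging", -0.0570105),
    _meta("ClinPred_score", "higher_damaging", 0.5, (0, 1)),
    _meta("LIST-S2_score", "higher_damaging", 0.85, (0, 1)),
    _meta("VARITY_R_score", "higher_damaging", 0.5, (0, 1)),
    _meta("VARITY_ER_score", "higher_damaging", 0.5, (0, 1)),
    _meta("VARITY_R_LOO_score", "higher_damaging", 0.5, (0, 1)),
    _meta("VARITY_ER_LOO_score", "higher_damaging", 0.5, (0, 1)),
    _meta("CADD_raw", "higher_damaging", 2.0),
    _meta("CADD_phred", "higher_damaging", 20.0, (0, 99)),
    _meta("DANN_score", "higher_damaging", 0.96, (0, 1)),
    _meta("fathmm-MKL_coding_score", "higher_damaging", 0.5, (0, 1)),
    _meta("fathmm-XF_coding_score", "higher_damaging", 0.5, (0, 1)),
    _meta("Eigen-raw_coding", "higher_damaging", 0.0),
    _meta("Eigen-PC-raw_coding", "higher_damaging", 0.0),
    _meta("GenoCanyon_score", "higher_damaging", 0.5, (0, 1)),
    _meta("integrated_fitCons_score", "higher_damaging", 0.7, (0, 1)),
    _meta("LINSIGHT", "higher_damaging", 0.8, (0, 1)),
    _meta("GERP++_RS", "higher_damaging", 4.4),
    _meta("phyloP100way_vertebrate", "higher_damaging", 7.52),
    _meta("phyloP30way_mammalian", "higher_damaging", 1.0),
    _meta("phastCons100way_vertebrate", "higher_damaging", 0.5, (0, 1)),
    _meta("SiPhy_29way_logOdds", "higher_damaging", 12.17),
]}


def load_score_registry(path=None) -> dict[str, ScoreMeta]:
    """Built-in registry, optionally extended/overridden from a TSV
    (columns: name, orientation, cutoff, min, max; min/max '.' = unbounded)."""
    registry = dict(DEFAULT_SCORE_REGISTRY)
    if path is None:
        return registry
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rng = None
            if row.get("min", ".") != "." and row.get("max", ".") != ".":
                rng = (float(row["min"]), float(row["max"]))
            registry[row["name"]] = ScoreMeta(
                row["name"], row["orientation"], float(row["cutoff"]), rng)
    return registry


def normalize_significance(raw: str) -> str:
    """Map a free-form clinical significance string to the closed vocabulary.

    Unrecognized strings fall back to ``uncertain`` with a logged warning.
    """
    key = raw.strip().lower()
    for candidate in (key, key.replace("_", " ")):
        if candidate in _SIGNIFICANCE_MAP:
            return _SIGNIFICANCE_MAP[candidate]
    logger.warning("unknown clinical significance %r -> uncertain", raw)
    return "uncertain"


def read_clinvar(
    tsv_path, transcript_span: GenomicInterval | None = None
) -> list[ClinVarRecord]:
    """Read a ClinVar-like summary TSV, dropping records outside the span."""
    records: list[ClinVarRecord] = []
    with open(tsv_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            chrom, pos = row["chrom"], int(row["pos"])
            if transcript_span is not None and not (
                    chrom == transcript_span.chrom
                    and transcript_span.contains(pos)):
                continue
            records.append(ClinVarRecord(
                chrom=chrom, gpos=pos, ref=row["ref"], alt=row["alt"],
                variant_type=row.get("variant_type", "other"),
                significance=normalize_significance(
                    row["clinical_significance"]),
                phenotype=row.get("phenotype", ""),
                protein_change=row.get("protein_change") or None,
            ))
    return records


def read_population_counts(tsv_path, dataset_tag: str) -> list[PopulationCount]:
    """Read an allele-count TSV; af is recomputed, ac=0 and an=0 rows dropped."""
    if dataset_tag not in ("exomes", "genomes"):
        raise ValueError(f"dataset_tag must be exomes|genomes, got {dataset_tag!r}")
    out: list[PopulationCount] = []
    with open(tsv_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            ac, an = int(row["ac"]), int(row["an"])
            if an == 0:
                logger.warning("dropping %s:%s with an=0", row["chrom"], row["pos"])
                continue
            if ac == 0:
                continue
            out.append(PopulationCount(
                chrom=row["chrom"], gpos=int(row["pos"]), ref=row["ref"],
                alt=row["alt"], dataset=dataset_tag, ac=ac, an=an))
    return out


def _resolve_cell(cell: str, tx_cell: str, transcript_id: str | None) -> float | None:
    """Resolve a possibly per-transcript ';'-separated score cell.

    The slot whose transcript id matches wins; otherwise the first numeric
    entry is used; ``.`` means missing.
    """
    if cell in (".", "", None):
        return None
    parts = cell.split(";")
    if len(parts) > 1 and transcript_id:
        tx_parts = tx_cell.split(";") if tx_cell else []
        if transcript_id in tx_parts:
            slot = tx_parts.index(transcript_id)
            if slot < len(parts) and parts[slot] not in (".", ""):
                return float(parts[slot])
    for p in parts:
        if p not in (".", ""):
            return float(p)
    return None


def query_scores(
    indexed_tsv_path,
    region: GenomicInterval,
    score_names: list[str],
    transcript_id: str | None = None,
) -> list[ScoreRecord]:
    """Region query against a bgzip+tabix per-SNV score table.

    Raises ``FileNotFoundError`` naming the expected ``.tbi`` index when it
    is absent.  Header columns are taken from the table's ``#``-prefixed
    header line.
    """
    index = str(indexed_tsv_path) + ".tbi"
    if not os.path.exists(index):
        raise FileNotFoundError(
            f"tabix index not found: expected {index} next to {indexed_tsv_path}")
    records: list[ScoreRecord] = []
    with pysam.TabixFile(str(indexed_tsv_path)) as tbx:
        header_line = tbx.header[-1]
        columns = header_line.lstrip("#").split("\t")
        idx = {c: i for i, c in enumerate(columns)}
        missing = [s for s in score_names if s not in idx]
        if missing:
            raise KeyError(f"score column(s) not in table: {missing}")
        try:
            rows = tbx.fetch(region.chrom, region.start - 1, region.end)
        except ValueError:
            return []
        for line in rows:
            f = line.split("\t")
            tx_cell = f[idx["Ensembl_transcriptid"]] if "Ensembl_transcriptid" in idx else ""
            aapos_raw = f[idx["aapos"]] if "aapos" in idx else "."
            aa_pos = _resolve_cell(aapos_raw, tx_cell, transcript_id)
            values = {
                s: _resolve_cell(f[idx[s]], tx_cell, transcript_id)
                for s in score_names
            }
            records.append(ScoreRecord(
                chrom=f[idx["chr"]], gpos=int(f[idx["pos(1-based)"]]),
                ref=f[idx["ref"]], alt=f[idx["alt"]],
                aa_pos=int(aa_pos) if aa_pos is not None else None,
                values=values,
            ))
    return records


def assign_groups(
    simulated: list[SimulatedVariant],
    clinvar: list[ClinVarRecord],
    pop: list[PopulationCount],
    scores: list[ScoreRecord],
    score_name: str,
    include_start_lost: bool = False,
) -> GroupedScores:
    """Partition one score's values into the four analysis groups.

    Membership is non-exclusive: the in-silico group holds every simulated
    variant with a score, and the same variant may also sit in the ClinVar
    and/or population groups.  Missing score values are dropped everywhere.
    """
    value_by_key = {}
    for rec in scores:
        v = rec.values.get(score_name)
        if v is not None:
            value_by_key[rec.key] = v

    gs = GroupedScores(score_name=score_name)

    for v in simulated:
        if v.consequence == "start_lost" and not include_start_lost:
            continue
        val = value_by_key.get(v.key)
        if val is not None:
            gs.groups["InSilico"].append(val)

    seen_pop = set()
    for p in pop:
        if p.key in seen_pop:    # same variant in both datasets: one value
            continue
        seen_pop.add(p.key)
        val = value_by_key.get(p.key)
        if val is not None:
            gs.groups["gnomAD"].append(val)

    for c in clinvar:
        val = value_by_key.get(c.key)
        if val is None:
            continue
        if c.is_pathogenic:
            gs.groups["ClinVar_pathogenic"].append(val)
        elif c.is_benign:
            gs.groups["ClinVar_benign"].append(val)

    for g in ("ClinVar_pathogenic", "ClinVar_benign"):
        if not gs.groups[g]:
            logger.warning("group %s is empty for %s", g, score_name)
    return gs
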