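"""Exhaustive simulation of all possible coding SNVs and their consequences.

Every base of a CDS can mutate into three alternate bases, so a CDS of
length L yields exactly 3L single-nucleotide variants.  Each variant is
classified at the protein level (synonymous / missense / nonsense /
stop_lost / start_lost) from the standard genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .genemodel import CodingSequence, TranscriptModel

BASES = "ACGT"

_standard = CodonTable.unambiguous_dna_by_id[1]
#: codon -> one-letter amino acid or '*', standard genetic code
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
CODON_TO_AA.update({c: "*" for c in _standard.stop_codons})

CONSEQUENCES = ("synonymous", "missense", "nonsense", "stop_lost", "start_lost")


@dataclass(frozen=True)
class SimulatedVariant:
    """One enumerated SNV with codon context and protein consequence.

    ``ref_base``/``alt_base`` are on the genomic strand (the join key used
    by external variant/score tables); ``ref_codon``/``alt_codon`` on the
    coding strand.
    """

    chrom: str
    gpos: int
    ref_base: str
    alt_base: str
    cds_pos: int
    codon_index: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    consequence: str

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.gpos, self.ref_base, self.alt_base)

    @property
    def protein_change(self) -> str:
        return to_protein_notation(self)


def translate_codon(codon: str) -> str:
    """Translate one codon with the standard genetic code ('*' for stop)."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"not an unambiguous DNA codon: {codon!r}")
    return CODON_TO_AA[codon]


def classify_consequence(
    ref_aa: str, alt_aa: str, codon_index: int, is_initiator: bool = False
) -> str:
    """Protein-level consequence class of a single amino-acid change.

    Stop-retaining changes count as synonymous; any change in the initiator
    codon is start_lost when ``is_initiator`` is set (translation loss, not
    a substitution).
    """
    if ref_aa == alt_aa:
        return "synonymous"
    if is_initiator:
        return "start_lost"
    if alt_aa == "*":
        return "nonsense"
    if ref_aa == "*":
        return "stop_lost"
    return "missense"


def enumerate_all_snvs(
    cds: CodingSequence,
    t: TranscriptModel | None = None,
    initiator_aware: bool = True,
) -> list[SimulatedVariant]:
    """Enumerate the 3 x len(cds) possible SNVs of a coding sequence.

    Order is deterministic: ascending CDS position, then alternate base
    A<C<G<T on the coding strand.  ``initiator_aware=False`` classifies
    first-codon changes like any other substitution (as precomputed score
    tables list them).
    """
    chrom = t.chrom if t is not None else "cds"
    strand = t.strand if t is not None else "+"
    seq = cds.seq.upper()
    out: list[SimulatedVariant] = []
    for i, ref in enumerate(seq):
        cds_pos = i + 1
        codon_index = (cds_pos + 2) // 3
        offset = i % 3
        codon_start = i - offset
        ref_codon = seq[codon_start: codon_start + 3]
        gpos = cds.genomic_positions[i]
        for alt in BASES:
            if alt == ref:
                continue
            alt_codon = ref_codon[:offset] + alt + ref_codon[offset + 1:]
            ref_aa = CODON_TO_AA[ref_codon]
            alt_aa = CODON_TO_AA[alt_codon]
            consequence = classify_consequence(
                ref_aa, alt_aa, codon_index,
                is_initiator=initiator_aware and codon_index == 1,
            )
            if strand == "+":
                g_ref, g_alt = ref, alt
            else:
                g_ref = str(Seq(ref).complement())
                g_alt = str(Seq(alt).complement())
            out.append(SimulatedVariant(
                chrom=chrom, gpos=gpos, ref_base=g_ref, alt_base=g_alt,
                cds_pos=cds_pos, codon_index=codon_index,
                ref_codon=ref_codon, alt_codon=alt_codon,
                ref_aa=ref_aa, alt_aa=alt_aa, consequence=consequence,
            ))
    return out


def to_protein_notation(v: SimulatedVariant, three_letter: bool = False) -> str:
    """HGVS-like protein notation, e.g. ``p.W2C``, ``p.Trp2Ter``, ``p.W2=``."""
    def aa(x: str) -> str:
        if not three_letter:
            return x
        return "Ter" if x == "*" else seq3(x)

    if v.consequence == "synonymous":
        return f"p.{aa(v.ref_aa)}{v.codon_index}="
    return f"p.{aa(v.ref_aa)}{v.codon_index}{aa(v.alt_aa)}"


#: Column layout of the exported in-silico variant table; the
#: (chrom,pos,ref,alt) key matches the score-table dialect.
VARIANT_TABLE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "cds_pos", "codon_index",
    "ref_codon", "alt_codon", "aa_ref", "aa_alt", "consequence",
    "protein_change",
]


def variants_to_frame(variants: list[SimulatedVariant]) -> pd.DataFrame:
    """Tabulate simulated variants with the documented export columns."""
    rows = [
        (v.chrom, v.gpos, v.ref_base, v.alt_base, v.cds_pos, v.codon_index,
         v.ref_codon, v.alt_codon, v.ref_aa, v.alt_aa, v.consequence,
         v.protein_change)
        for v in variants
    ]
    return pd.DataFrame(rows, columns=VARIANT_TABLE_COLUMNS)
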