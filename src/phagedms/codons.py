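"""Codon tables and small DNA helpers.

The preferred-codon policy used for saturation-library design is based on
approximate *E. coli* K-12 codon usage (fraction of each codon among the
codons for its amino acid). Only the rank order matters for design: the
top-ranked codon encodes each programmed substitution, and the next-ranked
codon for the wild-type residue provides synonymous (silent) controls.
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGT")

#: codon -> (amino acid, usage fraction within that amino acid), E. coli K-12.
CODON_USAGE_ECOLI: dict[str, tuple[str, float]] = {
    "GCG": ("A", 0.36), "GCC": ("A", 0.27), "GCA": ("A", 0.21), "GCT": ("A", 0.16),
    "CGC": ("R", 0.40), "CGT": ("R", 0.38), "CGG": ("R", 0.10), "CGA": ("R", 0.06),
    "AGA": ("R", 0.04), "AGG": ("R", 0.02),
    "AAC": ("N", 0.55), "AAT": ("N", 0.45),
    "GAT": ("D", 0.63), "GAC": ("D", 0.37),
    "TGC": ("C", 0.56), "TGT": ("C", 0.44),
    "CAG": ("Q", 0.65), "CAA": ("Q", 0.35),
    "GAA": ("E", 0.69), "GAG": ("E", 0.31),
    "GGC": ("G", 0.41), "GGT": ("G", 0.34), "GGG": ("G", 0.15), "GGA": ("G", 0.11),
    "CAT": ("H", 0.57), "CAC": ("H", 0.43),
    "ATT": ("I", 0.51), "ATC": ("I", 0.42), "ATA": ("I", 0.07),
    "CTG": ("L", 0.50), "TTA": ("L", 0.13), "TTG": ("L", 0.13),
    "CTT": ("L", 0.10), "CTC": ("L", 0.10), "CTA": ("L", 0.04),
    "AAA": ("K", 0.77), "AAG": ("K", 0.23),
    "ATG": ("M", 1.00),
    "TTT": ("F", 0.57), "TTC": ("F", 0.43),
    "CCG": ("P", 0.52), "CCA": ("P", 0.19), "CCT": ("P", 0.16), "CCC": ("P", 0.12),
    "AGC": ("S", 0.28), "TCT": ("S", 0.15), "TCC": ("S", 0.15), "TCG": ("S", 0.15),
    "AGT": ("S", 0.15), "TCA": ("S", 0.12),
    "ACC": ("T", 0.44), "ACG": ("T", 0.27), "ACT": ("T", 0.17), "ACA": ("T", 0.13),
    "TGG": ("W", 1.00),
    "TAT": ("Y", 0.57), "TAC": ("Y", 0.43),
    "GTG": ("V", 0.37), "GTT": ("V", 0.26), "GTC": ("V", 0.20), "GTA": ("V", 0.15),
    "TAA": ("*", 0.64), "TGA": ("*", 0.29), "TAG": ("*", 0.07),
}

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: amino acid -> codons sorted by decreasing E. coli usage (deterministic).
CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, (_aa, _frac) in sorted(
    CODON_USAGE_ECOLI.items(), key=lambda kv: (-kv[1][1], kv[0])
):
    CODONS_BY_AA.setdefault(_aa, []).append(_codon)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def preferred_codon(aa: str) -> str:
    """Most-used E. coli codon for amino acid ``aa`` (or ``*``)."""
    return CODONS_BY_AA[aa][0]


def synonymous_codons(codon: str) -> list[str]:
    """Alternative codons encoding the same residue, by decreasing usage."""
    aa = CODON_USAGE_ECOLI[codon][0]
    return [c for c in CODONS_BY_AA[aa] if c != codon]


def translate_codon(codon: str) -> str:
    if codon in _STANDARD.stop_codons:
        return "*"
    return _STANDARD.forward_table[codon]


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
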