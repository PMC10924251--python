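"""Protein targets, codon/amino-acid variants, and saturation-library design.

A saturation-mutagenesis library programs every single amino-acid
substitution across a mutagenized window of the target protein, one codon
per substitution by default, plus optional synonymous (silent) codon
variants that later serve as the measurement null for neutrality calls.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .codons import AMINO_ACIDS, CODONS_BY_AA, DNA_ALPHABET, preferred_codon

#: Sentinel amino-acid effect for codon variants that leave the protein unchanged.
SYNONYMOUS = "SYNONYMOUS"

_NAME_RE = re.compile(r"^([A-Z*])(\d+)([A-Z*])$")


class VariantError(ValueError):
    """Invalid sequence, window, or variant-name input."""


def translate(dna: str) -> str:
    """Translate coding DNA with the standard genetic code; stops become ``*``.

    Raises :class:`VariantError` for a non-triplet length or characters
    outside A/C/G/T.
    """
    dna = dna.upper()
    if len(dna) % 3 != 0:
        raise VariantError(f"coding sequence length {len(dna)} is not a multiple of 3")
    bad = set(dna) - DNA_ALPHABET
    if bad:
        raise VariantError(f"non-ACGT characters in coding sequence: {sorted(bad)}")
    return str(Seq(dna).translate())


@dataclass(frozen=True)
class ProteinTarget:
    """A coding sequence to be mutagenized over a residue window.

    Residue numbering is 1-based with position 1 the initiator Met.
    """

    name: str
    dna_seq: str
    mut_start: int
    mut_end: int
    aa_seq: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "dna_seq", self.dna_seq.upper())
        aa = translate(self.dna_seq)
        if not self.dna_seq.startswith("ATG"):
            raise VariantError(f"{self.name}: coding sequence must start with ATG")
        if "*" in aa:
            raise VariantError(f"{self.name}: internal stop codon in coding sequence")
        object.__setattr__(self, "aa_seq", aa)
        if not (1 <= self.mut_start <= self.mut_end <= len(aa)):
            raise VariantError(
                f"{self.name}: window {self.mut_start}-{self.mut_end} outside "
                f"protein of length {len(aa)}"
            )

    def codon(self, position: int) -> str:
        """Codon at 1-based residue ``position``."""
        return self.dna_seq[3 * (position - 1) : 3 * position]

    @property
    def window_positions(self) -> range:
        return range(self.mut_start, self.mut_end + 1)


@dataclass(frozen=True)
class AminoAcidVariant:
    """A single substitution named in the wild type/position/mutant style, e.g. D86H."""

    position: int
    wt_aa: str
    mut_aa: str

    @property
    def name(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    @property
    def is_substitution(self) -> bool:
        return self.mut_aa != self.wt_aa

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


def parse_variant_name(
    name: str, target: ProteinTarget, allow_synonymous: bool = False
) -> AminoAcidVariant:
    """Parse ``"D86H"`` into an :class:`AminoAcidVariant`, validated against ``target``.

    The wild-type residue in the name must match ``target.aa_seq`` at that
    position. A self-substitution such as ``"D86D"`` is rejected unless
    ``allow_synonymous`` admits it as the synonymous sentinel.
    """
    m = _NAME_RE.match(name)
    if not m:
        raise VariantError(f"unparseable variant name {name!r}")
    wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
    if not 1 <= pos <= len(target.aa_seq):
        raise VariantError(f"{name}: position {pos} outside {target.name}")
    found = target.aa_seq[pos - 1]
    if found != wt:
        raise VariantError(f"{name}: expected {found} at {pos}, name claims {wt}")
    if mut == wt and not allow_synonymous:
        raise VariantError(f"{name}: not a substitution (wild-type residue repeated)")
    return AminoAcidVariant(position=pos, wt_aa=wt, mut_aa=mut)


@dataclass(frozen=True)
class CodonVariant:
    """A single-codon change to a target, with its amino-acid-level effect."""

    parent: ProteinTarget
    codon_index: int  # 1-based
    codon: str
    aa_effect: AminoAcidVariant | str  # AminoAcidVariant, SYNONYMOUS, or "wildtype"

    @property
    def full_dna(self) -> str:
        i = 3 * (self.codon_index - 1)
        return self.parent.dna_seq[:i] + self.codon + self.parent.dna_seq[i + 3 :]

    @property
    def klass(self) -> str:
        if self.aa_effect == SYNONYMOUS:
            return "synonymous"
        if self.aa_effect == "wildtype":
            return "wildtype"
        return "missense"

    @property
    def variant_name(self) -> str:
        if self.klass == "missense":
            return self.aa_effect.name
        if self.klass == "synonymous":
            wt = self.parent.aa_seq[self.codon_index - 1]
            return f"{wt}{self.codon_index}{wt}.{self.codon.lower()}"
        return "wildtype"


WILDTYPE_NAME = "wildtype"


class VariantLibrary:
    """A designed variant set with an exact DNA-sequence index.

    Membership and assignment are by full-length variant DNA; the index maps
    each distinct ``full_dna`` back to the generating variant's name.
    """

    def __init__(self, target: ProteinTarget, variants: list[CodonVariant]):
        self.target = target
        self.variants = variants
        self.index: dict[str, str] = {target.dna_seq: WILDTYPE_NAME}
        for v in variants:
            dna = v.full_dna
            if dna in self.index:
                raise VariantError(f"duplicate library sequence for {v.variant_name}")
            self.index[dna] = v.variant_name

    @property
    def names(self) -> list[str]:
        return [WILDTYPE_NAME] + [v.variant_name for v in self.variants]

    @property
    def sequences(self) -> dict[str, str]:
        """variant name -> full-length DNA (wild type included)."""
        return {name: dna for dna, name in self.index.items()}

    def missense_names(self) -> list[str]:
        return [v.variant_name for v in self.variants if v.klass == "missense"]

    def synonymous_names(self) -> list[str]:
        return [v.variant_name for v in self.variants if v.klass == "synonymous"]

    def __len__(self) -> int:
        return len(self.index)

    def manifest(self) -> pd.DataFrame:
        """Library manifest: one row per library member, wild type first."""
        rows = [
            {
                "variant_name": WILDTYPE_NAME,
                "codon_index": 0,
                "codon": "",
                "class": "wildtype",
                "full_dna_sha1": hashlib.sha1(self.target.dna_seq.encode()).hexdigest(),
            }
        ]
        for v in self.variants:
            rows.append(
                {
                    "variant_name": v.variant_name,
                    "codon_index": v.codon_index,
                    "codon": v.codon,
                    "class": v.klass,
                    "full_dna_sha1": hashlib.sha1(v.full_dna.encode()).hexdigest(),
                }
            )
        return pd.DataFrame(rows)


def enumerate_saturation_library(
    target: ProteinTarget,
    synonymous_per_position: int = 1,
    include_stops: bool = False,
) -> VariantLibrary:
    """Enumerate the single-mutant saturation library over the target's window.

    For every position in the mutagenized window and every one of the 19
    non-wild-type amino acids, one codon variant is designed (the most-used
    E. coli codon for the substituting residue). Up to
    ``synonymous_per_position`` silent codon variants of the wild-type
    residue are added per position, taken in decreasing codon-usage order;
    Met and Trp positions have no silent alternative and contribute none.
    Stop-codon variants are excluded unless ``include_stops``.
    """
    variants: list[CodonVariant] = []
    for pos in target.window_positions:
        wt_aa = target.aa_seq[pos - 1]
        wt_codon = target.codon(pos)
        for aa in AMINO_ACIDS:
            if aa == wt_aa:
                continue
            variants.append(
                CodonVariant(
                    parent=target,
                    codon_index=pos,
                    codon=preferred_codon(aa),
                    aa_effect=AminoAcidVariant(pos, wt_aa, aa),
                )
            )
        if include_stops:
            variants.append(
                CodonVariant(
                    parent=target,
                    codon_index=pos,
                    codon=preferred_codon("*"),
                    aa_effect=AminoAcidVariant(pos, wt_aa, "*"),
                )
            )
        n_syn = 0
        for codon in CODONS_BY_AA[wt_aa]:
            if n_syn >= synonymous_per_position:
                break
            if codon == wt_codon:
                continue
            variants.append(
                CodonVariant(
                    parent=target, codon_index=pos, codon=codon, aa_effect=SYNONYMOUS
                )
            )
            n_syn += 1
    return VariantLibrary(target, variants)
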