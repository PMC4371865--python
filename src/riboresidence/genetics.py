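"""Genetic-code lookups shared across the package.

The standard nuclear genetic code is used throughout (S. cerevisiae uses the
standard code for its nuclear genome).  Everything here is derived from
Biopython's codon table rather than hand-typed.
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.Seq import Seq

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: Map of the 61 sense codons to one-letter amino acids.
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)

#: The 61 sense codons in lexicographic order; index into this list is the
#: canonical integer code for a codon.
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: Stop codons of the standard code (TAA, TAG, TGA).
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

#: Integer code (0..60) for each sense codon.
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: Amino acid -> sorted tuple of synonymous codons.
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] = AA_TO_CODONS[_aa] + (_codon,)

#: Amino acids in a fixed (alphabetical) order.
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(AA_TO_CODONS))

_THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}


def aa_three_letter(aa: str) -> str:
    """Three-letter name for a one-letter amino acid code."""
    return _THREE_LETTER[aa]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def gc_count(codon: str) -> int:
    """Number of G or C nucleotides in a codon."""
    return sum(1 for b in codon if b in "GC")


def translate_codons(codons: list[str] | tuple[str, ...]) -> str:
    """Translate a list of codons; stop codons become ``*``."""
    return "".join(CODON_TO_AA.get(c, "*") for c in codons)
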