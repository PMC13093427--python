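"""Vertebrate mitochondrial genetic code helpers.

The translation table itself comes from Biopython (NCBI table 2); this module
derives the lookups the rest of the package needs: codon -> amino acid,
synonymous families grouped *by amino acid* (so Leu and Ser are 6-codon
families spanning two codon boxes), and stop handling (AGA/AGG are stops,
ATA is Met, TGA is Trp).
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

BASES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

_TABLE = unambiguous_dna_by_id[2]  # vertebrate mitochondrial

#: codon -> one-letter amino acid, with '*' for the four stops.
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: amino acid -> tuple of synonymous codons (families defined by amino acid).
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in sorted(CODON_TO_AA):
    AA_TO_CODONS.setdefault(CODON_TO_AA[_codon], tuple())
    AA_TO_CODONS[CODON_TO_AA[_codon]] += (_codon,)

SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in sorted(CODON_TO_AA) if c not in STOP_CODONS
)


def translate_codon(codon: str) -> str:
    """One-letter amino acid for *codon* ('*' for a stop).

    Raises KeyError for codons containing non-ACGT symbols.
    """
    return CODON_TO_AA[codon.upper()]


def is_stop(codon: str) -> bool:
    return codon.upper() in STOP_CODONS


def is_transition(a: str, b: str) -> bool:
    """True when bases *a* and *b* differ within purines or within pyrimidines."""
    if a == b:
        return False
    pair = {a, b}
    return pair <= PURINES or pair <= PYRIMIDINES
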