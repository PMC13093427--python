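"""Codon counting, amino-acid usage and RSCU under the vertebrate mito code.

RSCU (relative synonymous codon usage) for codon *i* in a synonymous family
of size *k* is the observed count divided by the family mean; unbiased usage
gives 1.0 for every codon and family RSCU values sum to *k*.  Families are
grouped by amino acid, so Leu and Ser are 6-codon families (the DnaSP
convention for RSCU-by-amino-acid plots).

Trailing incomplete codons are dropped before counting; codons containing
non-ACGT symbols are skipped and tallied as ambiguous.  Stop-codon families
are excluded from RSCU by default (switchable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .genetic_code import AA_TO_CODONS, CODON_TO_AA

__all__ = ["CodonUsageTable", "count_codons", "rscu", "stop_codon_policy",
           "usage_table"]


@dataclass
class CodonUsageTable:
    counts: dict[str, int]
    aa_counts: dict[str, int]
    ambiguous: int = 0
    rscu: dict[str, float] = field(default_factory=dict)
    include_stops: bool = False

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())


def count_codons(cds_sequences: Iterable[str]) -> CodonUsageTable:
    """Aggregate codon and amino-acid counts over 5'->3' CDS sequences."""
    counts = {c: 0 for c in sorted(CODON_TO_AA)}
    ambiguous = 0
    for seq in cds_sequences:
        s = seq.upper()
        for i in range(0, len(s) - len(s) % 3, 3):
            codon = s[i : i + 3]
            if codon in counts:
                counts[codon] += 1
            else:
                ambiguous += 1
    aa_counts: dict[str, int] = {}
    for codon, n in counts.items():
        aa = CODON_TO_AA[codon]
        aa_counts[aa] = aa_counts.get(aa, 0) + n
    return CodonUsageTable(counts=counts, aa_counts=aa_counts, ambiguous=ambiguous)


def rscu(counts: dict[str, int], include_stops: bool = False) -> dict[str, float]:
    """RSCU per codon: count / (family mean).  Families with zero total map
    to 0 for every member."""
    out: dict[str, float] = {}
    for aa, family in AA_TO_CODONS.items():
        if aa == "*" and not include_stops:
            continue
        total = sum(counts.get(c, 0) for c in family)
        for c in family:
            out[c] = 0.0 if total == 0 else counts.get(c, 0) * len(family) / total
    return out


def stop_codon_policy(table: CodonUsageTable, include_stops: bool) -> CodonUsageTable:
    """Return a table whose RSCU includes or excludes the stop-codon family."""
    return CodonUsageTable(
        counts=dict(table.counts),
        aa_counts=dict(table.aa_counts),
        ambiguous=table.ambiguous,
        rscu=rscu(table.counts, include_stops=include_stops),
        include_stops=include_stops,
    )


def usage_table(table: CodonUsageTable, species: str = "") -> pd.DataFrame:
    """Long-format report: codon, amino acid, count, RSCU (plot-ready)."""
    values = table.rscu or rscu(table.counts, table.include_stops)
    rows = []
    for codon in sorted(table.counts):
        aa = CODON_TO_AA[codon]
        if aa == "*" and not table.include_stops:
            continue
        rows.append({
            "species": species,
            "codon": codon,
            "amino_acid": aa,
            "count": table.counts[codon],
            "rscu": round(values.get(codon, 0.0), 4),
        })
    return pd.DataFrame(rows)
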