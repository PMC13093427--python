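"""Base composition, strand skews, partition fractions, start/stop codons.

Percentages are computed over counted A/C/G/T only (IUPAC ambiguity codes are
excluded from numerator and denominator); strand compositional asymmetry is
measured by AT-skew = (A-T)/(A+T) and GC-skew = (G-C)/(G+C).  Full precision
is kept internally; rounding (percentages to 2 decimals, skews to 3) happens
only in the reporting helpers.

Partition composition is computed on gene sequences in sense (5'->3')
orientation after strand correction, and overlapping genes contribute their
shared bases once per member, so e.g. a PCG-partition length equals the sum
of the member gene lengths.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .genome_model import (
    FeatureType,
    MitogenomeRecord,
    concatenate_partition,
)

__all__ = [
    "CompositionRow",
    "CodonAnnotation",
    "StopClass",
    "base_composition",
    "at_skew",
    "gc_skew",
    "partition_fraction",
    "classify_codons",
    "composition_table",
]


@dataclass(frozen=True)
class CompositionRow:
    partition: str
    length: int
    pctA: float
    pctC: float
    pctG: float
    pctT: float

    @property
    def pctAT(self) -> float:
        return self.pctA + self.pctT

    @property
    def at_skew(self) -> float:
        return at_skew(self.pctA, self.pctT)

    @property
    def gc_skew(self) -> float:
        return gc_skew(self.pctG, self.pctC)


class StopClass(str, Enum):
    COMPLETE = "complete"
    INCOMPLETE = "incomplete"
    NONSTANDARD = "nonstandard"
    UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class CodonAnnotation:
    gene: str | None
    start_codon: str
    stop_codon: str
    stop_class: StopClass


def base_composition(sequence: str, partition: str = "whole") -> CompositionRow:
    """Percentages of A/C/G/T over the counted unambiguous bases.

    ``length`` reports the raw sequence length; ambiguity codes are excluded
    from the percentage denominator.  A sequence with no A/C/G/T at all is an
    error.
    """
    if not sequence:
        raise ValueError("empty sequence")
    counts = Counter(sequence.upper())
    total = sum(counts[b] for b in "ACGT")
    if total == 0:
        raise ValueError("sequence contains no unambiguous A/C/G/T bases")
    return CompositionRow(
        partition=partition,
        length=len(sequence),
        pctA=100.0 * counts["A"] / total,
        pctC=100.0 * counts["C"] / total,
        pctG=100.0 * counts["G"] / total,
        pctT=100.0 * counts["T"] / total,
    )


def at_skew(pctA: float, pctT: float) -> float:
    """(A-T)/(A+T); accepts percentages or raw counts (scale cancels)."""
    if pctA + pctT <= 0:
        raise ValueError("AT-skew undefined: A + T is zero")
    return (pctA - pctT) / (pctA + pctT)


def gc_skew(pctG: float, pctC: float) -> float:
    """(G-C)/(G+C); accepts percentages or raw counts."""
    if pctG + pctC <= 0:
        raise ValueError("GC-skew undefined: G + C is zero")
    return (pctG - pctC) / (pctG + pctC)


def partition_fraction(partition_length: int, genome_length: int) -> float:
    """Percentage of the genome occupied by a partition, truncated to 2
    decimals (the convention the reference tabulations follow: 2673/16943
    reports as 15.77, not 15.78)."""
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    if not 0 < partition_length <= genome_length:
        raise ValueError("partition length must be in (0, genome_length]")
    pct = 100.0 * partition_length / genome_length
    return math.floor(pct * 100 + 1e-9) / 100


def classify_codons(pcg_sequence: str, gene: str | None = None) -> CodonAnnotation:
    """Start/stop codon classification for one PCG in sense orientation.

    The stop is read from the annotation boundary: a length divisible by 3
    ends in a full codon (TAA/TAG complete, AGA/AGG nonstandard); remainder 2
    ending "TA" and remainder 1 ending "T" are incomplete stops completed by
    post-transcriptional polyadenylation; anything else is unclassifiable.
    """
    seq = pcg_sequence.upper()
    if len(seq) < 6:
        raise ValueError("PCG sequence shorter than two codons")
    start = seq[:3]
    rem = len(seq) % 3
    if rem == 0:
        last = seq[-3:]
        if last in ("TAA", "TAG"):
            return CodonAnnotation(gene, start, last, StopClass.COMPLETE)
        if last in ("AGA", "AGG"):
            return CodonAnnotation(gene, start, last, StopClass.NONSTANDARD)
        return CodonAnnotation(gene, start, last, StopClass.UNCLASSIFIABLE)
    if rem == 2 and seq.endswith("TA"):
        return CodonAnnotation(gene, start, "TA-", StopClass.INCOMPLETE)
    if rem == 1 and seq.endswith("T"):
        return CodonAnnotation(gene, start, "T--", StopClass.INCOMPLETE)
    return CodonAnnotation(gene, start, seq[-rem:] + "-" * (3 - rem),
                           StopClass.UNCLASSIFIABLE)


def composition_table(record: MitogenomeRecord, round_output: bool = True) -> pd.DataFrame:
    """Table-2-style report for the whole genome and the PCG/rRNA/tRNA
    partitions (sense-strand gene sequences, overlaps double-counted)."""
    rows = []
    specs = [("whole", record.sequence)]
    for label, ftype in (("PCGs", FeatureType.PCG), ("rRNAs", FeatureType.RRNA),
                         ("tRNAs", FeatureType.TRNA)):
        if any(f.type is ftype for f in record.features):
            specs.append((label, concatenate_partition(record, label)))
    for label, seq in specs:
        c = base_composition(seq, partition=label)
        rows.append({
            "species": record.species,
            "accession": record.accession,
            "partition": label,
            "size": c.length,
            "pctA": round(c.pctA, 2) if round_output else c.pctA,
            "pctC": round(c.pctC, 2) if round_output else c.pctC,
            "pctG": round(c.pctG, 2) if round_output else c.pctG,
            "pctT": round(c.pctT, 2) if round_output else c.pctT,
            "pctAT": round(c.pctAT, 2) if round_output else c.pctAT,
            "at_skew": round(c.at_skew, 3) if round_output else c.at_skew,
            "gc_skew": round(c.gc_skew, 3) if round_output else c.gc_skew,
        })
    return pd.DataFrame(rows)
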