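"""Gene-architecture accounting on annotated circular mitogenomes.

Computes per-gene lengths, signed intergenic distances between adjacent
features (negative = overlap, zero = contiguous, positive = spacer),
overlap/spacer summaries, strand tallies, and an origin-normalized gene-order
signature for between-species comparison.

Adjacency is defined along the single circular sequence regardless of strand,
so overlaps between opposite-strand genes count exactly like same-strand
ones.  The closing adjacency (last feature back to the first) is included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .genome_model import FeatureType, GeneFeature, MitogenomeRecord

__all__ = [
    "SignedGapEntry",
    "ArchitectureSummary",
    "gene_length",
    "signed_gap",
    "gap_entries",
    "summarize_architecture",
    "strand_distribution",
    "gene_order_signature",
    "architecture_table",
]


@dataclass(frozen=True)
class SignedGapEntry:
    prev_gene: str
    next_gene: str
    gap_bp: int


@dataclass(frozen=True)
class ArchitectureSummary:
    n_overlaps: int
    total_overlap_bp: int
    n_spacers: int
    total_spacer_bp: int
    longest_overlap: SignedGapEntry | None
    longest_spacer: SignedGapEntry | None
    n_heavy: int
    n_light: int
    genome_length: int
    total_gene_bp: int


def _features_of(obj) -> list[GeneFeature]:
    return list(obj.features) if isinstance(obj, MitogenomeRecord) else list(obj)


def gene_length(feature: GeneFeature, genome_length: int) -> int:
    """Length in bp; adds *genome_length* when the feature wraps the origin."""
    return feature.length(genome_length)


def signed_gap(prev: GeneFeature, next: GeneFeature, genome_length: int,
               circular: bool = True) -> int:
    """Signed intergenic distance ``next.start - prev.end - 1``.

    Negative values are overlaps.  For the closing adjacency on a circular
    genome the distance is taken modulo the genome, mapped into
    ``(-genome_length/2, genome_length/2]`` so small overlaps across the
    origin stay negative.
    """
    if prev is next or (prev.name == next.name and prev.start == next.start):
        raise ValueError("signed_gap requires two distinct features")
    gap = next.start - prev.end - 1
    if circular:
        gap %= genome_length
        if gap > genome_length // 2:
            gap -= genome_length
    return gap


def gap_entries(record_or_features, genome_length: int | None = None,
                circular: bool = True) -> list[SignedGapEntry]:
    """Signed gaps over all adjacent pairs in genome order (circularly closed).

    For a full circular annotation there are exactly as many entries as
    features.
    """
    if isinstance(record_or_features, MitogenomeRecord):
        genome_length = len(record_or_features)
        circular = record_or_features.circular
    feats = sorted(_features_of(record_or_features), key=lambda f: (f.start, f.end))
    if genome_length is None:
        raise ValueError("genome_length required when passing a bare feature list")
    names = [f.name for f in feats]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names in annotation")
    entries = []
    n = len(feats)
    if n < 2:
        return entries
    for i in range(n if circular else n - 1):
        a, b = feats[i], feats[(i + 1) % n]
        entries.append(SignedGapEntry(a.name, b.name, signed_gap(a, b, genome_length, circular)))
    return entries


def summarize_architecture(record_or_features, genome_length: int | None = None,
                           circular: bool = True) -> ArchitectureSummary:
    """Aggregate signed gaps: overlap/spacer counts, totals, extremes, strands.

    Zero gaps (contiguous genes) count as neither overlap nor spacer.  Ties
    for the longest overlap/spacer resolve to the first in genome order.
    """
    if isinstance(record_or_features, MitogenomeRecord):
        genome_length = len(record_or_features)
        circular = record_or_features.circular
    feats = _features_of(record_or_features)
    entries = gap_entries(feats, genome_length, circular)
    overlaps = [e for e in entries if e.gap_bp < 0]
    spacers = [e for e in entries if e.gap_bp > 0]
    longest_overlap = min(overlaps, key=lambda e: e.gap_bp) if overlaps else None
    longest_spacer = max(spacers, key=lambda e: e.gap_bp) if spacers else None
    genes = [f for f in feats if f.type is not FeatureType.CR]
    return ArchitectureSummary(
        n_overlaps=len(overlaps),
        total_overlap_bp=sum(-e.gap_bp for e in overlaps),
        n_spacers=len(spacers),
        total_spacer_bp=sum(e.gap_bp for e in spacers),
        longest_overlap=longest_overlap,
        longest_spacer=longest_spacer,
        n_heavy=sum(1 for f in genes if f.strand == "H"),
        n_light=sum(1 for f in genes if f.strand == "L"),
        genome_length=genome_length,
        total_gene_bp=sum(f.length(genome_length) for f in feats),
    )


def strand_distribution(record_or_features) -> tuple[int, int, list[str]]:
    """``(n_heavy, n_light, sorted light-strand gene names)`` over the genes
    (control region excluded from the tally)."""
    genes = [f for f in _features_of(record_or_features) if f.type is not FeatureType.CR]
    light = sorted(f.name for f in genes if f.strand == "L")
    return len(genes) - len(light), len(light), light


def gene_order_signature(record_or_features, anchor: str = "trnF") -> tuple[str, ...]:
    """Feature labels in genome order, rotated to start at *anchor* when
    present, for equality comparison between species."""
    feats = sorted(_features_of(record_or_features), key=lambda f: (f.start, f.end))
    names = [f.name for f in feats]
    if anchor in names:
        i = names.index(anchor)
        names = names[i:] + names[:i]
    return tuple(names)


def architecture_table(record_or_features, genome_length: int | None = None,
                       circular: bool = True) -> pd.DataFrame:
    """Table-1-style report: gene, start, end, strand, size, intergenic,
    start/stop codon, anticodon."""
    if isinstance(record_or_features, MitogenomeRecord):
        genome_length = len(record_or_features)
        circular = record_or_features.circular
    feats = sorted(_features_of(record_or_features), key=lambda f: (f.start, f.end))
    gaps = {e.prev_gene: e.gap_bp for e in gap_entries(feats, genome_length, circular)}
    rows = []
    for f in feats:
        rows.append({
            "gene": f.name,
            "start": f.start,
            "end": f.end,
            "strand": f.strand,
            "size": f.length(genome_length),
            "intergenic": gaps.get(f.name, pd.NA),
            "start_codon": f.start_codon or "",
            "stop_codon": f.stop_codon or "",
            "anticodon": f.anticodon or "",
        })
    return pd.DataFrame(rows)
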