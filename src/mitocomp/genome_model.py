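"""Domain model for annotated circular mitogenomes and their file formats.

A :class:`MitogenomeRecord` holds one circular genome (sequence plus an
ordered list of :class:`GeneFeature`).  Coordinates are 1-based inclusive
throughout, matching GenBank; a feature with ``end < start`` spans the
circular origin.  Readers/writers cover single-record GenBank flat files,
FASTA, and a simple tab-separated feature table
(``gene/type/start/end/strand/anticodon`` plus optional codon columns).

Gene names are canonicalized to the 37-name vertebrate mitochondrial
vocabulary (13 PCGs, 12S/16S, 22 tRNAs with trnL1/trnL2 and trnS1/trnS2
disambiguation) plus ``CR`` for the control region, because public deposits
name the same genes in many dialects (COX1, CO1, NAD5, D-loop, ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FeatureType",
    "GeneFeature",
    "MitogenomeRecord",
    "GenomePartition",
    "PARTITION_LABELS",
    "canonical_gene_name",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "read_feature_table",
    "write_feature_table",
    "extract_gene",
    "concatenate_partition",
    "partition_members",
    "reverse_complement",
]


class FeatureType(str, Enum):
    PCG = "PCG"
    RRNA = "rRNA"
    TRNA = "tRNA"
    CR = "CR"


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene (or the control region) on a circular genome."""

    name: str
    type: FeatureType
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive; end < start only when spanning the origin
    strand: str = "H"
    anticodon: str | None = None
    start_codon: str | None = None
    stop_codon: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.name}: start must be >= 1, got {self.start}")
        if self.strand not in ("H", "L"):
            raise ValueError(f"{self.name}: strand must be 'H' or 'L'")
        if self.anticodon is not None and self.type is not FeatureType.TRNA:
            raise ValueError(f"{self.name}: anticodon only valid on tRNA features")

    @property
    def spans_origin(self) -> bool:
        return self.end < self.start

    def length(self, genome_length: int | None = None) -> int:
        """Feature length in bp; *genome_length* is required for wrapping spans."""
        if not self.spans_origin:
            return self.end - self.start + 1
        if genome_length is None:
            raise ValueError(f"{self.name} spans the origin; genome length required")
        return genome_length - self.start + 1 + self.end


@dataclass
class MitogenomeRecord:
    """One annotated (usually circular) mitogenome."""

    accession: str
    species: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        self.sequence = self.sequence.upper()
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        names = [f.name for f in self.features]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate feature names: {sorted(dupes)}")
        L = len(self.sequence)
        for f in self.features:
            if f.end > L or f.start > L:
                raise ValueError(f"{f.name}: coordinates exceed genome length {L}")
            if f.spans_origin and not self.circular:
                raise ValueError(f"{f.name}: origin-spanning span on linear record")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def genes(self) -> list[GeneFeature]:
        """All features except the control region."""
        return [f for f in self.features if f.type is not FeatureType.CR]


@dataclass(frozen=True)
class GenomePartition:
    """A named subset of a record's genes (Table-2-style partitions)."""

    label: str
    members: tuple[str, ...]


PARTITION_LABELS = ("whole", "PCGs", "rRNAs", "tRNAs", "CR")

_PARTITION_TYPE = {
    "PCGs": FeatureType.PCG,
    "rRNAs": FeatureType.RRNA,
    "tRNAs": FeatureType.TRNA,
    "CR": FeatureType.CR,
}


def partition_members(record: MitogenomeRecord, label: str) -> GenomePartition:
    """The partition *label* ('PCGs'/'rRNAs'/'tRNAs'/'CR') for *record*."""
    if label not in _PARTITION_TYPE:
        raise ValueError(f"unknown partition label {label!r}")
    ftype = _PARTITION_TYPE[label]
    return GenomePartition(
        label, tuple(f.name for f in record.features if f.type is ftype)
    )


# ---------------------------------------------------------------------------
# gene-name canonicalization
# ---------------------------------------------------------------------------

_PCG_ALIASES = {
    "COI": ("COI", "COX1", "CO1", "COXI", "MT-CO1", "COX-1", "CYTOCHROME C OXIDASE SUBUNIT 1", "CYTOCHROME C OXIDASE SUBUNIT I"),
    "COII": ("COII", "COX2", "CO2", "COXII", "MT-CO2", "CYTOCHROME C OXIDASE SUBUNIT 2", "CYTOCHROME C OXIDASE SUBUNIT II"),
    "COIII": ("COIII", "COX3", "CO3", "COXIII", "MT-CO3", "CYTOCHROME C OXIDASE SUBUNIT 3", "CYTOCHROME C OXIDASE SUBUNIT III"),
    "ND1": ("ND1", "NAD1", "NADH1", "MT-ND1", "NADH DEHYDROGENASE SUBUNIT 1"),
    "ND2": ("ND2", "NAD2", "NADH2", "MT-ND2", "NADH DEHYDROGENASE SUBUNIT 2"),
    "ND3": ("ND3", "NAD3", "NADH3", "MT-ND3", "NADH DEHYDROGENASE SUBUNIT 3"),
    "ND4": ("ND4", "NAD4", "NADH4", "MT-ND4", "NADH DEHYDROGENASE SUBUNIT 4"),
    "ND4L": ("ND4L", "NAD4L", "NADH4L", "MT-ND4L", "NADH DEHYDROGENASE SUBUNIT 4L"),
    "ND5": ("ND5", "NAD5", "NADH5", "MT-ND5", "NADH DEHYDROGENASE SUBUNIT 5"),
    "ND6": ("ND6", "NAD6", "NADH6", "MT-ND6", "NADH DEHYDROGENASE SUBUNIT 6"),
    "ATP6": ("ATP6", "ATPASE6", "ATPASE 6", "MT-ATP6", "ATP SYNTHASE F0 SUBUNIT 6"),
    "ATP8": ("ATP8", "ATPASE8", "ATPASE 8", "MT-ATP8", "ATP SYNTHASE F0 SUBUNIT 8"),
    "Cytb": ("CYTB", "COB", "CYB", "MT-CYB", "CYTOCHROME B"),
}

_RNA_ALIASES = {
    "12S": ("12S", "12S RRNA", "12S RIBOSOMAL RNA", "RRNS", "S-RRNA", "SMALL SUBUNIT RIBOSOMAL RNA", "MT-RNR1", "RRN12"),
    "16S": ("16S", "16S RRNA", "16S RIBOSOMAL RNA", "RRNL", "L-RRNA", "LARGE SUBUNIT RIBOSOMAL RNA", "MT-RNR2", "RRN16"),
    "CR": ("CR", "D-LOOP", "DLOOP", "CONTROL REGION", "MISC_FEATURE"),
}

# tRNAs: trnX for unambiguous amino acids; the two Leu/Ser isoacceptors are
# distinguished by codon family (L2 = UUR, L1 = CUN, S2 = UCN, S1 = AGY).
_TRNA_BY_AA = {
    "ALA": "trnA", "ARG": "trnR", "ASN": "trnN", "ASP": "trnD", "CYS": "trnC",
    "GLN": "trnQ", "GLU": "trnE", "GLY": "trnG", "HIS": "trnH", "ILE": "trnI",
    "LYS": "trnK", "MET": "trnM", "PHE": "trnF", "PRO": "trnP", "THR": "trnT",
    "TRP": "trnW", "TYR": "trnY", "VAL": "trnV",
}

_ALIAS_TO_CANONICAL: dict[str, str] = {}
for canon, aliases in {**_PCG_ALIASES, **_RNA_ALIASES}.items():
    for a in aliases:
        _ALIAS_TO_CANONICAL[a] = canon
for canon in list(_PCG_ALIASES) + ["12S", "16S", "CR"]:
    _ALIAS_TO_CANONICAL[canon.upper()] = canon
for aa, trn in _TRNA_BY_AA.items():
    _ALIAS_TO_CANONICAL[trn.upper()] = trn
    _ALIAS_TO_CANONICAL[f"TRNA-{aa}"] = trn
    _ALIAS_TO_CANONICAL[f"TRN{trn[-1].upper()}"] = trn
for trn, keys in {
    "trnL1": ("TRNL1", "TRNA-LEU(CUN)", "TRNA-LEU (CUN)", "TRNL(CUN)"),
    "trnL2": ("TRNL2", "TRNA-LEU(UUR)", "TRNA-LEU (UUR)", "TRNL(UUR)"),
    "trnS1": ("TRNS1", "TRNA-SER(AGY)", "TRNA-SER (AGY)", "TRNS(AGY)"),
    "trnS2": ("TRNS2", "TRNA-SER(UCN)", "TRNA-SER (UCN)", "TRNS(UCN)"),
}.items():
    for k in keys:
        _ALIAS_TO_CANONICAL[k] = trn


def canonical_gene_name(raw: str) -> tuple[str, bool]:
    """Map a deposit-style gene name onto the canonical vocabulary.

    Returns ``(name, known)``; when the alias is unknown the raw name is
    returned unchanged with ``known=False`` (callers warn but keep it).
    """
    key = raw.strip().upper().replace("_", "-")
    if key in _ALIAS_TO_CANONICAL:
        return _ALIAS_TO_CANONICAL[key], True
    return raw.strip(), False


# ---------------------------------------------------------------------------
# sequence operations
# ---------------------------------------------------------------------------

def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


def extract_gene(record: MitogenomeRecord, feature: GeneFeature) -> str:
    """The 5'->3' sense sequence of *feature* within *record*.

    Slices ``[start, end]`` inclusive, wrapping through the origin when the
    feature spans it on a circular record; L-strand features are
    reverse-complemented.
    """
    seq = record.sequence
    if feature.spans_origin:
        if not record.circular:
            raise ValueError(f"{feature.name}: end < start on a non-circular record")
        raw = seq[feature.start - 1 :] + seq[: feature.end]
    else:
        raw = seq[feature.start - 1 : feature.end]
    return reverse_complement(raw) if feature.strand == "L" else raw


def concatenate_partition(
    record: MitogenomeRecord,
    partition: GenomePartition | str,
    gene_order: Sequence[str] | None = None,
) -> str:
    """Concatenate the partition's genes, each 5'->3', in *gene_order*.

    Overlapping genes contribute their shared bases once per member, so the
    result length equals the sum of member lengths.  Defaults to the
    record's genome order.
    """
    if isinstance(partition, str):
        partition = partition_members(record, partition)
    missing = [m for m in partition.members if all(f.name != m for f in record.features)]
    if missing:
        raise ValueError(f"partition members absent from record: {missing}")
    order = list(gene_order) if gene_order is not None else list(partition.members)
    absent = [g for g in order if g not in partition.members]
    if absent:
        raise ValueError(f"gene_order entries outside partition: {absent}")
    return "".join(extract_gene(record, record.feature(name)) for name in order)


# ---------------------------------------------------------------------------
# GenBank I/O
# ---------------------------------------------------------------------------

_GB_TYPE = {
    FeatureType.PCG: "CDS",
    FeatureType.RRNA: "rRNA",
    FeatureType.TRNA: "tRNA",
    FeatureType.CR: "D-loop",
}


def _feature_from_seqfeature(sf: SeqFeature, ftype: FeatureType, L: int) -> GeneFeature | None:
    quals = sf.qualifiers
    raw = (quals.get("gene") or quals.get("product") or quals.get("note") or [""])[0]
    if not raw:
        return None
    name, known = canonical_gene_name(raw)
    if not known:
        warnings.warn(f"unmappable gene name {raw!r}; kept verbatim", stacklevel=2)
    strand = "L" if sf.location.strand == -1 else "H"
    loc = sf.location
    if isinstance(loc, CompoundLocation):
        # origin-spanning join(a..L,1..b): represent as end < start
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        start = int(parts[-1].start) + 1
        end = int(parts[0].end)
    else:
        start, end = int(loc.start) + 1, int(loc.end)
    anticodon = None
    if ftype is FeatureType.TRNA:
        for note in quals.get("note", []):
            if note.lower().startswith("anticodon:"):
                anticodon = note.split(":", 1)[1].strip().upper()
        if anticodon is None and "anticodon" in quals:
            raw_ac = quals["anticodon"][0]
            if "seq:" in raw_ac:
                anticodon = raw_ac.split("seq:")[1].strip(") ").upper()
            elif len(raw_ac.strip()) == 3:
                anticodon = raw_ac.strip().upper()
    return GeneFeature(name, ftype, start, end, strand, anticodon)


def read_genbank(path: str | Path) -> MitogenomeRecord:
    """Read a single-record GenBank flat file into a :class:`MitogenomeRecord`.

    CDS features take precedence over co-located ``gene`` features; feature
    names are canonicalized; the circular flag comes from the LOCUS line.
    """
    records = list(SeqIO.parse(str(path), "genbank"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one record, found {len(records)}")
    rec = records[0]
    if len(rec.seq) == 0:
        raise ValueError(f"{path}: record has no sequence")
    L = len(rec.seq)
    feats: dict[str, GeneFeature] = {}
    type_map = {"CDS": FeatureType.PCG, "rRNA": FeatureType.RRNA,
                "tRNA": FeatureType.TRNA, "D-loop": FeatureType.CR}
    for sf in rec.features:
        if sf.type in type_map:
            f = _feature_from_seqfeature(sf, type_map[sf.type], L)
        elif sf.type == "misc_feature" and any(
            "control region" in n.lower() for n in sf.qualifiers.get("note", [])
        ):
            f = _feature_from_seqfeature(sf, FeatureType.CR, L)
            if f is not None:
                f = replace(f, name="CR")
        else:
            continue
        if f is not None:
            feats[f.name] = f
    # plain gene features only fill names not already defined by CDS/rRNA/tRNA
    for sf in rec.features:
        if sf.type != "gene":
            continue
        raw = (sf.qualifiers.get("gene") or [""])[0]
        name, _ = canonical_gene_name(raw)
        if name and name not in feats:
            ftype = FeatureType.PCG
            if name in ("12S", "16S"):
                ftype = FeatureType.RRNA
            elif name.startswith("trn"):
                ftype = FeatureType.TRNA
            elif name == "CR":
                ftype = FeatureType.CR
            f = _feature_from_seqfeature(sf, ftype, L)
            if f is not None:
                feats[f.name] = f
    circular = rec.annotations.get("topology", "") == "circular"
    return MitogenomeRecord(
        accession=rec.id or rec.name,
        species=rec.annotations.get("organism", rec.description or ""),
        sequence=str(rec.seq),
        circular=circular,
        features=list(feats.values()),
    )


def write_genbank(record: MitogenomeRecord, path: str | Path) -> None:
    """Write *record* as a single-record GenBank flat file (round-trippable)."""
    L = len(record.sequence)
    rec = SeqRecord(
        Seq(record.sequence),
        id=record.accession,
        name=record.accession.split(".")[0][:16],
        description=record.species,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
            "organism": record.species,
        },
    )
    for f in record.features:
        strand = -1 if f.strand == "L" else 1
        if f.spans_origin:
            loc = CompoundLocation(
                [SimpleLocation(f.start - 1, L, strand), SimpleLocation(0, f.end, strand)]
            )
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand)
        quals: dict[str, list[str]] = {"gene": [f.name]}
        if f.anticodon:
            quals["note"] = [f"anticodon:{f.anticodon}"]
        rec.features.append(SeqFeature(loc, type=_GB_TYPE[f.type], qualifiers=quals))
    SeqIO.write(rec, str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA and feature-table I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered ``{id: sequence}`` mapping."""
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


_TABLE_COLUMNS = ("gene", "type", "start", "end", "strand", "anticodon")


def read_feature_table(path: str | Path) -> list[GeneFeature]:
    """Read the TSV feature-table dialect (header gene/type/start/end/strand/
    anticodon; optional start_codon/stop_codon columns; '.' for missing)."""
    feats = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _TABLE_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        idx = {c: header.index(c) for c in header}
        for line in fh:
            if not line.strip():
                continue
            row = line.rstrip("\n").split("\t")

            def get(col: str) -> str | None:
                if col not in idx or idx[col] >= len(row):
                    return None
                v = row[idx[col]].strip()
                return None if v in (".", "") else v

            feats.append(
                GeneFeature(
                    name=get("gene"),
                    type=FeatureType(get("type")),
                    start=int(get("start")),
                    end=int(get("end")),
                    strand=get("strand") or "H",
                    anticodon=get("anticodon"),
                    start_codon=get("start_codon"),
                    stop_codon=get("stop_codon"),
                )
            )
    return feats


def write_feature_table(features: Iterable[GeneFeature], path: str | Path) -> None:
    cols = _TABLE_COLUMNS + ("start_codon", "stop_codon")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for f in features:
            row = [f.name, f.type.value, str(f.start), str(f.end), f.strand,
                   f.anticodon or ".", f.start_codon or ".", f.stop_codon or "."]
            fh.write("\t".join(row) + "\n")
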