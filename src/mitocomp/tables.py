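"""Loaders for the printed reference annotations shipped with the package.

Two feature tables give the published gene boundaries of the focal knifefish
mitogenomes (GenBank OR466573, 16,943 bp, and OQ446559, 16,176 bp); a
composition table gives the published per-partition base percentages and
skews for seven Chitala records.  These are inputs for desk-scale
reproduction of the architecture and skew accounting — no sequence download
is required.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files

import pandas as pd

from .genome_model import GeneFeature, read_feature_table

__all__ = ["PrintedAnnotation", "load_printed_features", "load_printed_composition",
           "PRINTED_ACCESSIONS"]

PRINTED_ACCESSIONS = {
    "OR466573": ("Chitala borneensis", 16943),
    "OQ446559": ("Chitala lopis", 16176),
}


@dataclass(frozen=True)
class PrintedAnnotation:
    accession: str
    species: str
    genome_length: int
    features: tuple[GeneFeature, ...]


def _data_path(name: str):
    return files("mitocomp.data").joinpath(name)


def load_printed_features(accession: str) -> PrintedAnnotation:
    """Published feature table for one of the focal accessions.

    Note: the OQ446559 table uses the self-consistent Cytb end (15,542;
    size 1141) rather than the typo-bearing printed end.
    """
    if accession not in PRINTED_ACCESSIONS:
        raise KeyError(f"no printed annotation for {accession!r}")
    species, length = PRINTED_ACCESSIONS[accession]
    feats = read_feature_table(str(_data_path(f"{accession}.features.tsv")))
    return PrintedAnnotation(accession, species, length, tuple(feats))


def load_printed_composition() -> pd.DataFrame:
    """Published per-partition composition rows (percentages and skews)."""
    return pd.read_csv(str(_data_path("chitala_composition.tsv")), sep="\t")
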