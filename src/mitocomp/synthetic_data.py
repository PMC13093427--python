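"""Deterministic synthetic mitogenomes and simulated sequence evolution.

``generate_mitogenome`` builds a fully annotated circular record with the
canonical teleost architecture: the default layout is the published
OR466573 gene map (37 genes + control region, 16,943 bp), so it carries the
10 bp ATP8/ATP6 overlap, the 34 bp trnN-trnC spacer, the light-strand set
{ND6 + 8 tRNAs}, and the published start/stop codon classes (GTG start on
COI, AGG/AGA nonstandard stops, T--/TA- incomplete stops).  The heavy strand
is drawn from skewed base probabilities (defaults tuned to AT% ~ 57 and
GC-skew ~ -0.30), then protein-coding constraints (start codon, stop codon
or incomplete tail, stop-free internal frame in sense orientation) are
imposed by an iterative repair pass that converges to a fixed point; the
same seed always yields a byte-identical record.

``evolve_taxa`` produces a star phylogeny of descendant records under a
kappa-weighted transition bias; within PCGs, nonsynonymous candidate
substitutions are accepted with probability min(1, omega), synonymous ones
always, stop-creating ones never.  No indels are simulated, so per-gene
extraction order doubles as the alignment (``make_alignment``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .genetic_code import PURINES, PYRIMIDINES, is_stop, translate_codon
from .genome_model import (
    FeatureType,
    GeneFeature,
    MitogenomeRecord,
    extract_gene,
    reverse_complement,
)
from .tables import load_printed_features

__all__ = [
    "GeneratorParams",
    "EvolutionParams",
    "default_layout",
    "generate_mitogenome",
    "evolve_sequence",
    "evolve_cds",
    "evolve_taxa",
    "make_alignment",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def default_layout() -> tuple[GeneFeature, ...]:
    """The published OR466573 gene map used as the default template."""
    return load_printed_features("OR466573").features


@dataclass(frozen=True)
class GeneratorParams:
    seed: int = 0
    layout: tuple[GeneFeature, ...] | None = None
    genome_length: int = 16943
    #: heavy-strand base probabilities; defaults give AT% ~ 57.1 and
    #: whole-genome GC-skew ~ -0.30, matching the published composition.
    base_probs: dict[str, float] = field(
        default_factory=lambda: {"A": 0.321, "C": 0.278, "G": 0.151, "T": 0.250}
    )

    def __post_init__(self) -> None:
        total = sum(self.base_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("base_probs must sum to 1")


@dataclass(frozen=True)
class EvolutionParams:
    seed: int = 0
    kappa: float = 4.0  # transition/transversion rate ratio
    omega: float | dict[str, float] = 0.2  # dN/dS acceptance, global or per gene
    branch_lengths: Sequence[float] = (0.05,)  # expected substitutions/site per taxon
    n_taxa: int | None = None

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        omegas = (self.omega.values() if isinstance(self.omega, dict)
                  else [self.omega])
        if any(w < 0 for w in omegas):
            raise ValueError("omega must be non-negative")
        if any(b < 0 for b in self.branch_lengths):
            raise ValueError("branch lengths must be non-negative")


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

class _SenseView:
    """Read/write access to a feature's 5'->3' sense sequence over a mutable
    genome array, handling origin wrap and L-strand complementation."""

    def __init__(self, genome: list[str], feature: GeneFeature):
        L = len(genome)
        if feature.spans_origin:
            idx = list(range(feature.start - 1, L)) + list(range(feature.end))
        else:
            idx = list(range(feature.start - 1, feature.end))
        if feature.strand == "L":
            idx = idx[::-1]
        self._genome = genome
        self._idx = idx
        self._comp = feature.strand == "L"

    def __len__(self) -> int:
        return len(self._idx)

    def get(self, i: int) -> str:
        b = self._genome[self._idx[i]]
        return _COMPLEMENT[b] if self._comp else b

    def set(self, i: int, base: str) -> bool:
        """Write sense base *i*; returns True when the genome changed."""
        b = _COMPLEMENT[base] if self._comp else base
        if self._genome[self._idx[i]] == b:
            return False
        self._genome[self._idx[i]] = b
        return True

    def codon(self, k: int) -> str:
        return self.get(3 * k) + self.get(3 * k + 1) + self.get(3 * k + 2)


def _repair_pcgs(genome: list[str], layout: Sequence[GeneFeature],
                 rng: np.random.Generator, base_probs: dict[str, float],
                 max_passes: int = 30) -> None:
    """Impose start/stop and internal stop-free constraints on every PCG,
    iterating to a fixed point (overlapping genes constrain shared bases)."""
    pcgs = [f for f in layout if f.type is FeatureType.PCG]
    bases = list(base_probs)
    # Escalation bookkeeping: a codon whose 3rd-position fix keeps being
    # overwritten by an overlapping gene's hard-set bases (e.g. the ATP6
    # start codon inside ATP8's frame) is retried at the 2nd, then 1st
    # position until an editable base is found.
    stuck: dict[tuple[str, int], int] = {}
    for _ in range(max_passes):
        changed = False
        for f in pcgs:
            view = _SenseView(genome, f)
            n = len(view)
            n_codons = n // 3
            rem = n % 3
            start = f.start_codon or "ATG"
            for i, b in enumerate(start):
                changed |= view.set(i, b)
            stop = f.stop_codon or ("TAA" if rem == 0 else ("TA-" if rem == 2 else "T--"))
            if rem == 0:
                for i, b in enumerate(stop):
                    changed |= view.set(n - 3 + i, b)
                internal = range(1, n_codons - 1)
            else:
                tail = stop.rstrip("-")
                if len(tail) != rem:
                    raise ValueError(f"{f.name}: stop {stop!r} inconsistent with length {n}")
                for i, b in enumerate(tail):
                    changed |= view.set(n - rem + i, b)
                internal = range(1, n_codons)
            for k in internal:
                codon = view.codon(k)
                if is_stop(codon):
                    level = stuck.get((f.name, k), 0)
                    stuck[(f.name, k)] = level + 1
                    pos = (2, 1, 0)[level % 3]
                    ok = [b for b in bases if b != codon[pos]
                          and not is_stop(codon[:pos] + b + codon[pos + 1:])]
                    w = np.array([base_probs[b] for b in ok])
                    pick = ok[int(rng.choice(len(ok), p=w / w.sum()))]
                    changed |= view.set(3 * k + pos, pick)
        if not changed:
            return
    raise RuntimeError("PCG constraint repair did not converge")


def generate_mitogenome(params: GeneratorParams | None = None,
                        accession: str | None = None,
                        species: str = "Synthetica notopteroides") -> MitogenomeRecord:
    """Generate one annotated circular mitogenome; same seed, same record."""
    params = params or GeneratorParams()
    layout = params.layout or default_layout()
    L = params.genome_length
    for f in layout:
        if not f.spans_origin and f.end > L:
            raise ValueError(f"layout feature {f.name} exceeds genome length {L}")
    rng = np.random.default_rng(params.seed)
    bases = list(params.base_probs)
    probs = np.array([params.base_probs[b] for b in bases])
    genome = [bases[i] for i in rng.choice(len(bases), size=L, p=probs)]
    _repair_pcgs(genome, layout, rng, params.base_probs)
    return MitogenomeRecord(
        accession=accession or f"SYN{params.seed:07d}",
        species=species,
        sequence="".join(genome),
        circular=True,
        features=list(layout),
    )


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def _propose_base(base: str, kappa: float, rng: np.random.Generator) -> str:
    """Mutation target with transition weight kappa against 1 per transversion."""
    ti = next(iter((PURINES if base in PURINES else PYRIMIDINES) - {base}))
    tv = sorted((PYRIMIDINES if base in PURINES else PURINES))
    p_ti = kappa / (kappa + 2.0)
    u = rng.random()
    if u < p_ti:
        return ti
    return tv[0] if u < p_ti + (1.0 - p_ti) / 2.0 else tv[1]


def evolve_sequence(seq: str, branch_length: float, kappa: float,
                    rng: np.random.Generator) -> str:
    """Neutral nucleotide evolution: Poisson(branch_length) substitution
    events per site, each kappa-biased; expected substitutions/site equals
    the branch length."""
    out = list(seq)
    n_events = rng.poisson(branch_length, size=len(out))
    for i in np.nonzero(n_events)[0]:
        for _ in range(n_events[i]):
            out[i] = _propose_base(out[i], kappa, rng)
    return "".join(out)


def evolve_cds(seq: str, branch_length: float, kappa: float, omega: float,
               rng: np.random.Generator, protect_ends: bool = True) -> str:
    """Codon-aware evolution of an in-frame CDS in sense orientation.

    Candidate substitutions arrive at rate *branch_length* per site;
    synonymous candidates are always accepted, nonsynonymous ones with
    probability min(1, omega), stop-creating ones never.  With
    *protect_ends* the first codon and any terminal stop/incomplete tail are
    held fixed.
    """
    out = list(seq.upper())
    n = len(out)
    n_full = n - n % 3
    lo = 3 if protect_ends else 0
    hi = (n_full - 3 if (protect_ends and n % 3 == 0) else n_full)
    n_candidates = rng.poisson(branch_length * n)
    for _ in range(n_candidates):
        i = int(rng.integers(n))
        if protect_ends and not (lo <= i < hi):
            continue
        old = out[i]
        new = _propose_base(old, kappa, rng)
        k = i // 3
        codon = "".join(out[3 * k : 3 * k + 3])
        mutant = codon[: i % 3] + new + codon[i % 3 + 1 :]
        if is_stop(mutant):
            continue
        if translate_codon(codon) != translate_codon(mutant):
            if rng.random() >= min(1.0, omega):
                continue
        out[i] = new
    return "".join(out)


def evolve_taxa(root: MitogenomeRecord, evo: EvolutionParams) -> list[MitogenomeRecord]:
    """Evolve descendant records from *root* on a star phylogeny.

    Each gene evolves independently in its sense frame (PCGs codon-aware,
    everything else neutral, intergenic/CR bases neutral); a final repair
    pass restores coding constraints on bases shared by overlapping genes.
    """
    n_taxa = evo.n_taxa or len(evo.branch_lengths)
    bls = list(evo.branch_lengths)
    if len(bls) == 1:
        bls *= n_taxa
    if len(bls) != n_taxa:
        raise ValueError("branch_lengths must have length 1 or n_taxa")
    rng = np.random.default_rng(evo.seed)
    taxa = []
    for t in range(n_taxa):
        genome = list(root.sequence)
        covered = set()
        for f in root.features:
            view = _SenseView(genome, f)
            sense = extract_gene(root, f)
            w = (evo.omega.get(f.name, 1.0) if isinstance(evo.omega, dict)
                 else evo.omega)
            if f.type is FeatureType.PCG:
                new = evolve_cds(sense, bls[t], evo.kappa, w, rng)
            else:
                new = evolve_sequence(sense, bls[t], evo.kappa, rng)
            for i, b in enumerate(new):
                view.set(i, b)
            covered.update(view._idx)
        free = [i for i in range(len(genome)) if i not in covered]
        if free:
            spacer = evolve_sequence("".join(genome[i] for i in free),
                                     bls[t], evo.kappa, rng)
            for i, b in zip(free, spacer):
                genome[i] = b
        _repair_pcgs(genome, root.features, rng,
                     {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25})
        taxa.append(MitogenomeRecord(
            accession=f"{root.accession}_T{t + 1}",
            species=f"{root.species} taxon {t + 1}",
            sequence="".join(genome),
            circular=root.circular,
            features=list(root.features),
        ))
    return taxa


def make_alignment(records: Sequence[MitogenomeRecord],
                   gene_set: Sequence[str] | None = None) -> dict[str, str]:
    """Concatenated per-gene alignment ``{accession: sequence}``.

    All records must share the root layout (same gene names, lengths,
    strands); since the generator never simulates indels, positional
    extraction is the alignment.
    """
    if not records:
        raise ValueError("no records")
    ref = records[0]
    names = list(gene_set) if gene_set is not None else [
        f.name for f in ref.features if f.type is FeatureType.PCG
    ]
    out = {}
    for rec in records:
        parts = []
        for name in names:
            f = rec.feature(name)
            ref_f = ref.feature(name)
            if f.length(len(rec)) != ref_f.length(len(ref)) or f.strand != ref_f.strand:
                raise ValueError(f"layout mismatch at {name} in {rec.accession}")
            parts.append(extract_gene(rec, f))
        out[rec.accession] = "".join(parts)
    if len({len(s) for s in out.values()}) != 1:
        raise ValueError("alignment rows have unequal length")
    return out
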