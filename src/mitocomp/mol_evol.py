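"""Pairwise Ka/Ks (Nei-Gojobori 1986), nucleotide diversity, and
transition/transversion saturation against F84 distances.

Ka/Ks follows the NG86 counting method under the vertebrate mitochondrial
code with equal pathway weighting and Jukes-Cantor correction (the DnaSP
default).  Site counting: each of the up-to-9 single-base neighbours of a
codon is classified synonymous or nonsynonymous; mutations into stop codons
are excluded from both numerator and denominator, so a codon's synonymous +
nonsynonymous site total is 3 minus one third per stop neighbour.  For codons
differing at 2-3 positions, difference counts average equally over all
mutational pathways that avoid stop codons; if every pathway is blocked, all
pathways are used and steps through stops count as nonsynonymous.

Nucleotide diversity (pi) is the mean over unordered sequence pairs of the
per-site difference proportion; gap/ambiguity handling is switchable between
pairwise deletion (default) and complete deletion.  The F84 distance uses
base frequencies averaged over the pair and reduces to K80 at equal
frequencies; log-domain failures are flagged as saturated, never silent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations
from typing import Iterable, Sequence

from .genetic_code import (
    BASES,
    CODON_TO_AA,
    STOP_CODONS,
    is_stop,
    is_transition,
    translate_codon,
)

__all__ = [
    "PairwiseSelection",
    "DiversityWindow",
    "DiversitySummary",
    "SaturationPoint",
    "ng86_site_counts",
    "ng86_pairwise",
    "gene_kaks_summary",
    "jukes_cantor",
    "nucleotide_diversity",
    "sliding_window_pi",
    "f84_distance",
]

_ACGT = frozenset(BASES)


@dataclass(frozen=True)
class PairwiseSelection:
    gene: str | None
    species_pair: tuple[str, str] | None
    ka: float | None
    ks: float | None
    ratio: float | None
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float

    @property
    def defined(self) -> bool:
        return self.ratio is not None


@dataclass(frozen=True)
class DiversityWindow:
    start: int  # 1-based inclusive alignment coordinates
    end: int
    midpoint: float
    pi: float
    n_sites_used: int


@dataclass(frozen=True)
class DiversitySummary:
    pi_total: float
    S: int
    n_sequences: int
    length: int


@dataclass(frozen=True)
class SaturationPoint:
    species_pair: tuple[str, str] | None
    s: float
    v: float
    d: float | None
    saturated_flag: bool


# ---------------------------------------------------------------------------
# NG86 Ka/Ks
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon.

    Each non-stop single-base neighbour contributes 1/3 to one of the two
    tallies; neighbours that are stop codons contribute to neither.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _ACGT for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    if is_stop(codon):
        raise ValueError(f"stop codon {codon} has no NG86 site counts")
    aa = translate_codon(codon)
    syn = nonsyn = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if is_stop(mutant):
                continue
            if translate_codon(mutant) == aa:
                syn += 1.0 / 3.0
            else:
                nonsyn += 1.0 / 3.0
    return syn, nonsyn


@lru_cache(maxsize=None)
def _codon_pair_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) difference counts between two sense codons with equal
    pathway weighting; pathways through stops are excluded when possible."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    path_counts: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in permutations(positions):
        cur = c1
        syn = nonsyn = 0.0
        hits_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if is_stop(cur) or is_stop(nxt):
                hits_stop = True
                nonsyn += 1.0  # only used in the all-blocked fallback
            elif translate_codon(cur) == translate_codon(nxt):
                syn += 1.0
            else:
                nonsyn += 1.0
            cur = nxt
        (blocked if hits_stop else path_counts).append((syn, nonsyn))
    chosen = path_counts if path_counts else path_counts + blocked
    sd = sum(p[0] for p in chosen) / len(chosen)
    nd = sum(p[1] for p in chosen) / len(chosen)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69-corrected distance -(3/4)ln(1-4p/3); None when p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_pairwise(
    cds_a: str,
    cds_b: str,
    gene: str | None = None,
    species_pair: tuple[str, str] | None = None,
) -> PairwiseSelection:
    """NG86 Ka/Ks for a codon-aligned pair of CDS sequences.

    Codons containing non-ACGT symbols, or that are stops in either
    sequence, are skipped (pairwise deletion at the codon level).  Ka and Ks
    are JC-corrected; the ratio is undefined (None) when Ks is 0 or a
    correction fails.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences must be equal length")
    if len(a) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if any(x not in _ACGT for x in ca + cb):
            continue
        if is_stop(ca) or is_stop(cb):
            continue
        sa = ng86_site_counts(ca)
        sb = ng86_site_counts(cb)
        S += (sa[0] + sb[0]) / 2.0
        N += (sa[1] + sb[1]) / 2.0
        d = _codon_pair_diffs(ca, cb)
        Sd += d[0]
        Nd += d[1]
    ks = ka = None
    if S > 0:
        ks = jukes_cantor(Sd / S)
    if N > 0:
        ka = jukes_cantor(Nd / N)
    ratio = None
    if ka is not None and ks is not None and ks > 0:
        ratio = ka / ks
    return PairwiseSelection(gene, species_pair, ka, ks, ratio, S, N, Sd, Nd)


def gene_kaks_summary(
    results: Iterable[PairwiseSelection], gene: str | None = None
) -> tuple[float | None, float | None, int]:
    """(mean, sample SD, n_undefined) of the defined Ka/Ks ratios, optionally
    restricted to one gene."""
    pool = [r for r in results if gene is None or r.gene == gene]
    ratios = [r.ratio for r in pool if r.ratio is not None]
    n_undef = sum(1 for r in pool if r.ratio is None)
    if not ratios:
        return None, None, n_undef
    mean = sum(ratios) / len(ratios)
    if len(ratios) < 2:
        return mean, 0.0, n_undef
    var = sum((x - mean) ** 2 for x in ratios) / (len(ratios) - 1)
    return mean, math.sqrt(var), n_undef


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def _pair_diff(a: str, b: str) -> tuple[int, int]:
    """(differences, comparable sites) over pairwise-complete positions."""
    diffs = sites = 0
    for x, y in zip(a, b):
        if x in _ACGT and y in _ACGT:
            sites += 1
            if x != y:
                diffs += 1
    return diffs, sites


def _complete_columns(seqs: Sequence[str]) -> list[int]:
    return [j for j in range(len(seqs[0]))
            if all(s[j] in _ACGT for s in seqs)]


def nucleotide_diversity(
    alignment: Sequence[str], deletion: str = "pairwise"
) -> DiversitySummary:
    """Average pairwise difference proportion (pi) and segregating sites (S).

    *deletion* is ``"pairwise"`` (each pair compared over its own complete
    sites) or ``"complete"`` (columns with any gap/ambiguity dropped for all
    pairs).
    """
    seqs = [s.upper() for s in alignment]
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must be aligned to equal length")
    if deletion not in ("pairwise", "complete"):
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    if deletion == "complete":
        cols = _complete_columns(seqs)
        seqs = ["".join(s[j] for j in cols) for s in seqs]
    fractions = []
    for a, b in combinations(seqs, 2):
        diffs, sites = _pair_diff(a, b)
        if sites:
            fractions.append(diffs / sites)
    pi = sum(fractions) / len(fractions) if fractions else 0.0
    S = 0
    for j in range(len(seqs[0])):
        states = {s[j] for s in seqs if s[j] in _ACGT}
        if len(states) >= 2:
            S += 1
    return DiversitySummary(pi_total=pi, S=S, n_sequences=len(alignment),
                            length=len(alignment[0]))


def sliding_window_pi(
    alignment: Sequence[str],
    window: int = 200,
    step: int = 25,
    deletion: str = "pairwise",
) -> list[DiversityWindow]:
    """Sliding-window pi with 1-based windows starting at 1, 1+step, ...

    The terminal partial window is dropped, giving exactly
    ``floor((L - window)/step) + 1`` windows.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    L = len(alignment[0])
    if window > L:
        raise ValueError("window longer than alignment")
    out = []
    for start in range(0, L - window + 1, step):
        sub = [s[start : start + window] for s in alignment]
        summ = nucleotide_diversity(sub, deletion=deletion)
        out.append(DiversityWindow(
            start=start + 1,
            end=start + window,
            midpoint=start + (window + 1) / 2.0,
            pi=summ.pi_total,
            n_sites_used=len(_complete_columns([s.upper() for s in sub])),
        ))
    return out


# ---------------------------------------------------------------------------
# F84 distance and saturation
# ---------------------------------------------------------------------------

def f84_distance(
    seq_a: str, seq_b: str, species_pair: tuple[str, str] | None = None
) -> SaturationPoint:
    """Transition/transversion proportions and the F84 distance of a pair.

    Base frequencies are averaged over the two sequences (computed on the
    pairwise-complete sites).  When any logarithm argument is non-positive
    the distance is undefined and the saturated flag is set.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences must be equal length")
    sites = trans = transv = 0
    counts_a = {x: 0 for x in BASES}
    counts_b = {x: 0 for x in BASES}
    for x, y in zip(a, b):
        if x not in _ACGT or y not in _ACGT:
            continue
        sites += 1
        counts_a[x] += 1
        counts_b[y] += 1
        if x != y:
            if is_transition(x, y):
                trans += 1
            else:
                transv += 1
    if sites == 0:
        raise ValueError("no comparable sites")
    P = trans / sites
    Q = transv / sites
    freqs = {x: (counts_a[x] + counts_b[x]) / (2.0 * sites) for x in BASES}
    pR = freqs["A"] + freqs["G"]
    pY = freqs["C"] + freqs["T"]
    if pR == 0 or pY == 0:
        return SaturationPoint(species_pair, P, Q, None, True)
    A = freqs["A"] * freqs["G"] / pR + freqs["C"] * freqs["T"] / pY
    B = freqs["A"] * freqs["G"] + freqs["C"] * freqs["T"]
    C = pR * pY
    if A == 0 or C == 0:
        return SaturationPoint(species_pair, P, Q, None, True)
    arg1 = 1.0 - P / (2.0 * A) - (A - B) * Q / (2.0 * A * C)
    arg2 = 1.0 - Q / (2.0 * C)
    if arg1 <= 0 or arg2 <= 0:
        return SaturationPoint(species_pair, P, Q, None, True)
    d = -2.0 * A * math.log(arg1) + 2.0 * (A - B - C) * math.log(arg2)
    return SaturationPoint(species_pair, P, Q, d, False)
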