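"""NG86 Ka/Ks, nucleotide diversity, sliding windows and F84 saturation."""

import math
from itertools import combinations, permutations

import numpy as np
import pytest
from Bio.Seq import Seq

from mitocomp.genetic_code import SENSE_CODONS, STOP_CODONS
from mitocomp.mol_evol import (
    f84_distance,
    gene_kaks_summary,
    jukes_cantor,
    ng86_pairwise,
    ng86_site_counts,
    nucleotide_diversity,
    sliding_window_pi,
)
from mitocomp.synthetic_data import evolve_cds, evolve_sequence


def _aa(codon):
    return str(Seq(codon).translate(table=2))


def oracle_site_counts(codon):
    """Independent 9-neighbour enumeration using Biopython translation."""
    syn = nonsyn = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if mut in STOP_CODONS:
                continue
            if _aa(mut) == _aa(codon):
                syn += 1 / 3
            else:
                nonsyn += 1 / 3
    return syn, nonsyn


def oracle_pair_diffs(c1, c2):
    """Equal-weight pathway enumeration avoiding stops where possible."""
    pos = [i for i in range(3) if c1[i] != c2[i]]
    if not pos:
        return 0.0, 0.0
    clean, blocked = [], []
    for order in permutations(pos):
        cur, s, n, hit = c1, 0.0, 0.0, False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if cur in STOP_CODONS or nxt in STOP_CODONS:
                hit, n = True, n + 1
            elif _aa(cur) == _aa(nxt):
                s += 1
            else:
                n += 1
            cur = nxt
        (blocked if hit else clean).append((s, n))
    use = clean or blocked
    return (sum(x[0] for x in use) / len(use), sum(x[1] for x in use) / len(use))


def test_site_counts_examples():
    assert ng86_site_counts("TTT") == pytest.approx((1 / 3, 8 / 3))
    # ATA is Met under the mito code, so ATG has one synonymous neighbour,
    # and AGG (a stop) is excluded from the denominator
    assert ng86_site_counts("ATG") == pytest.approx((1 / 3, 7 / 3))


def test_site_counts_all_sense_codons_match_oracle():
    for codon in SENSE_CODONS:
        got = ng86_site_counts(codon)
        exp = oracle_site_counts(codon)
        assert got == pytest.approx(exp), codon
        assert got[0] + got[1] <= 3.0 + 1e-12


def test_stop_codon_input_rejected():
    with pytest.raises(ValueError):
        ng86_site_counts("TAA")


def test_identical_sequences():
    r = ng86_pairwise("ATGGCT", "ATGGCT")
    assert r.ka == 0.0 and r.ks == 0.0 and r.ratio is None


def test_single_synonymous_difference_exact():
    """One Gly<->Gly change embedded where the JC correction stays defined."""
    a, b = "TTTAAAGGA", "TTTAAAGGG"
    r = ng86_pairwise(a, b)
    # site counts: TTT 1/3, AAA 1/3, GGA 1 synonymous site
    assert r.syn_sites == pytest.approx(5 / 3)
    assert r.syn_diffs == pytest.approx(1.0)
    assert r.nonsyn_diffs == pytest.approx(0.0)
    assert r.ka == 0.0
    assert r.ks == pytest.approx(-0.75 * math.log(1 - 4 * 0.6 / 3))
    assert r.ratio == 0.0


def test_saturated_proportion_flagged_undefined():
    # all differences synonymous on few synonymous sites: pS >= 3/4
    r = ng86_pairwise("GGA", "GGG")
    assert r.ks is None and r.ratio is None


def test_pairwise_symmetry_and_additivity():
    rng = np.random.default_rng(21)
    codons = list(SENSE_CODONS)
    def rand_cds(n):
        return "".join(codons[i] for i in rng.integers(len(codons), size=n))
    a1, b1 = rand_cds(20), rand_cds(20)
    a2, b2 = rand_cds(15), rand_cds(15)
    r_ab = ng86_pairwise(a1, b1)
    r_ba = ng86_pairwise(b1, a1)
    assert (r_ab.syn_sites, r_ab.syn_diffs, r_ab.nonsyn_diffs) == pytest.approx(
        (r_ba.syn_sites, r_ba.syn_diffs, r_ba.nonsyn_diffs))
    r1, r2 = ng86_pairwise(a1, b1), ng86_pairwise(a2, b2)
    rc = ng86_pairwise(a1 + a2, b1 + b2)
    assert rc.syn_sites == pytest.approx(r1.syn_sites + r2.syn_sites)
    assert rc.syn_diffs == pytest.approx(r1.syn_diffs + r2.syn_diffs)
    assert rc.nonsyn_diffs == pytest.approx(r1.nonsyn_diffs + r2.nonsyn_diffs)


def test_pairwise_diffs_match_pathway_oracle():
    rng = np.random.default_rng(8)
    codons = list(SENSE_CODONS)
    for _ in range(200):
        a = "".join(codons[i] for i in rng.integers(len(codons), size=5))
        b = "".join(codons[i] for i in rng.integers(len(codons), size=5))
        r = ng86_pairwise(a, b)
        exp_s = exp_n = 0.0
        for i in range(0, 15, 3):
            s, n = oracle_pair_diffs(a[i:i + 3], b[i:i + 3])
            exp_s += s
            exp_n += n
        assert r.syn_diffs == pytest.approx(exp_s)
        assert r.nonsyn_diffs == pytest.approx(exp_n)


def test_omega_zero_construction_gives_zero_ka():
    rng = np.random.default_rng(4)
    codons = list(SENSE_CODONS)
    root = "ATG" + "".join(codons[i] for i in rng.integers(len(codons), size=50)) + "TAA"
    taxon = evolve_cds(root, 0.2, 2.0, 0.0, rng)
    r = ng86_pairwise(root, taxon)
    assert r.ka == 0.0


def test_gene_summary_mean_sd():
    from mitocomp.mol_evol import PairwiseSelection
    def ps(ratio):
        return PairwiseSelection("g", None, 0.1, 0.2, ratio, 1, 2, 0, 0)
    mean, sd, n_undef = gene_kaks_summary([ps(0.5), ps(0.5), ps(0.5)])
    assert (mean, sd, n_undef) == (0.5, 0.0, 0)
    mean, sd, n_undef = gene_kaks_summary([ps(0.2), ps(0.4), ps(None)])
    assert mean == pytest.approx(0.3)
    assert sd == pytest.approx(np.std([0.2, 0.4], ddof=1))
    assert n_undef == 1
    mean, sd, n_undef = gene_kaks_summary([ps(None)])
    assert mean is None and sd is None and n_undef == 1


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def brute_force_pi(seqs):
    fr = []
    for a, b in combinations(seqs, 2):
        pairs = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
        if pairs:
            fr.append(sum(x != y for x, y in pairs) / len(pairs))
    return sum(fr) / len(fr) if fr else 0.0


def test_diversity_trivial_cases():
    assert nucleotide_diversity(["ACGT", "ACGT"]).pi_total == 0.0
    assert nucleotide_diversity(["ACGT", "ACGT"]).S == 0
    d = nucleotide_diversity(["AAAAAAAAAA", "AAAAAAAATT"])
    assert d.pi_total == pytest.approx(0.2) and d.S == 2
    with pytest.raises(ValueError):
        nucleotide_diversity(["ACGT"])


def test_diversity_matches_brute_force_with_ambiguity():
    aln = ["ACGTACGTACGT", "ACGTNCGTACGA", "TCGTACGAACGT"]
    d = nucleotide_diversity(aln)
    assert d.pi_total == pytest.approx(brute_force_pi(aln))


def test_complete_deletion_mode():
    aln = ["ACGT", "ANGT", "ACGA"]
    # complete deletion drops column 2 entirely
    d = nucleotide_diversity(aln, deletion="complete")
    kept = ["".join(s[j] for j in (0, 2, 3)) for s in aln]
    assert d.pi_total == pytest.approx(brute_force_pi(kept))


def test_window_count_closed_form():
    aln = ["A" * 1000, "A" * 1000]
    wins = sliding_window_pi(aln, window=200, step=25)
    assert len(wins) == (1000 - 200) // 25 + 1 == 33
    assert wins[0].start == 1 and wins[0].end == 200
    assert wins[1].start == 26
    assert all(w.pi == 0.0 for w in wins)


def test_window_localization():
    rng = np.random.default_rng(17)
    L = 600
    a = "".join("ACGT"[i] for i in rng.integers(4, size=L))
    b = list(a)
    for i in range(300, 350):  # variation confined to one 50 bp block
        b[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[i]]
    wins = sliding_window_pi([a, "".join(b)], window=100, step=50)
    for w in wins:
        overlaps = w.start <= 350 and w.end >= 301
        assert (w.pi > 0) == overlaps


def test_windows_partition_reconstructs_total():
    rng = np.random.default_rng(23)
    aln = ["".join("ACGT"[i] for i in rng.integers(4, size=400)) for _ in range(4)]
    wins = sliding_window_pi(aln, window=100, step=100)
    total = nucleotide_diversity(aln).pi_total
    weighted = sum(w.pi * (w.end - w.start + 1) for w in wins) / 400
    assert weighted == pytest.approx(total)


def test_window_longer_than_alignment_rejected():
    with pytest.raises(ValueError):
        sliding_window_pi(["ACGT", "ACGT"], window=10, step=1)


# ---------------------------------------------------------------------------
# F84
# ---------------------------------------------------------------------------

def k80(P, Q):
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


def test_f84_identical():
    pt = f84_distance("ACGTACGT", "ACGTACGT")
    assert (pt.s, pt.v, pt.d, pt.saturated_flag) == (0.0, 0.0, 0.0, False)


def test_f84_equals_k80_at_equal_frequencies():
    base = "ACGT" * 100
    lst = list(base)
    # composition-preserving swaps: two transitions (A<->G), two transversions
    lst[0], lst[2] = "G", "A"
    lst[13], lst[15] = "T", "C"
    lst[4], lst[5] = "C", "A"
    seq_b = "".join(lst)
    pt = f84_distance(base, seq_b)
    assert pt.d == pytest.approx(k80(pt.s, pt.v), abs=1e-12)


def test_f84_saturation_flagged():
    a = "A" * 40 + "C" * 40
    b = "G" * 40 + "T" * 40  # every site a transition
    pt = f84_distance(a, b)
    assert pt.saturated_flag and pt.d is None


def test_f84_monotone_in_branch_length():
    means = []
    for bl in (0.02, 0.05, 0.1, 0.2, 0.4):
        vals = []
        for rep in range(10):
            rng = np.random.default_rng(1000 * rep + int(bl * 1000))
            seq = "".join("ACGT"[i] for i in rng.integers(4, size=1500))
            other = evolve_sequence(seq, bl, 3.0, rng)
            vals.append(f84_distance(seq, other).d)
        means.append(np.mean(vals))
    assert all(a < b for a, b in zip(means, means[1:]))


def test_jc_distance_recovery():
    """JC-corrected p recovers the simulated distance within 3 SE."""
    for t in (0.05, 0.2):
        ests = []
        for rep in range(200):
            rng = np.random.default_rng(7000 + rep)
            seq = "".join("ACGT"[i] for i in rng.integers(4, size=800))
            other = evolve_sequence(seq, t, 1.0, rng)
            p = sum(a != b for a, b in zip(seq, other)) / len(seq)
            ests.append(jukes_cantor(p))
        mean = np.mean(ests)
        se = np.std(ests, ddof=1) / math.sqrt(len(ests))
        assert abs(mean - t) < 3 * se
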