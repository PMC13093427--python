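# Methods

## Coordinate and adjacency conventions

Coordinates are 1-based inclusive throughout, matching GenBank feature
tables; a feature with `end < start` spans the origin of a circular genome.
Adjacency for intergenic accounting is defined along the single circular
sequence regardless of coding strand, so the signed distance between
consecutive features is `next.start − prev.end − 1`, overlaps between
opposite-strand genes (e.g. trnI/trnQ) count exactly like same-strand ones,
and the closing adjacency (last feature back to the first) is included.
Gaps of exactly 0 are counted as neither overlap nor spacer; ties for the
longest overlap/spacer resolve to the first in genome order. Under these
rules the circular conservation identity

    Σ gene lengths − Σ overlap bp + Σ spacer bp = genome length

holds for any full annotation, and is asserted on both shipped published
reconstructions and on generated genomes.

Strand tallies count the 37 genes (13 PCGs, 2 rRNAs, 22 tRNAs); the
control region, although carried as a feature, is non-genic and excluded.

## Composition and rounding

Percentages are computed over counted A/C/G/T only; IUPAC ambiguity codes
are excluded from numerator and denominator (their incidence in real
mitogenome deposits is negligible). Partition composition uses gene
sequences in sense (5′→3′) orientation after strand correction — an
annotation-centric convention that changes skew signs for light-strand
genes relative to raw heavy-strand slices, and is therefore stated here and
in output metadata. Overlapping genes contribute shared bases once per
member, so the PCG partition length equals the sum of the 13 printed gene
lengths (11,427 bp on the default layout).

Full precision is kept internally. At the reporting layer percentages are
rounded to 2 decimals and skews to 3 decimals; partition fractions are
*truncated* to 2 decimals, the convention the reference tabulations follow
(2,673/16,943 reports as 15.77, and 11,420/16,176 as 70.59, which rounding
would print as 15.78/70.60).

Stop codons are read from the annotation boundary of each PCG: length
divisible by 3 ends in a full codon (TAA/TAG complete, AGA/AGG
nonstandard); remainder 2 ending in TA is the incomplete stop `TA-`,
remainder 1 ending in T is `T--` (both completed to TAA by
post-transcriptional polyadenylation in vivo); any other tail is flagged
unclassifiable rather than guessed.

## Codon usage and RSCU

Counting uses the vertebrate mitochondrial code (NCBI table 2, taken from
Biopython). Trailing incomplete codons are dropped rather than completed —
completion would fabricate bases. Codons containing non-ACGT symbols are
skipped and tallied separately. Synonymous families are defined by amino
acid, giving 6-codon Leu and Ser families; RSCU for a codon is its count
divided by the family mean, so family RSCU values sum to the family size
and unbiased usage gives 1.0. The four stops (TAA/TAG/AGA/AGG) form a
family that is excluded from RSCU by default and can be included by flag.

## Ka/Ks (Nei–Gojobori 1986, Jukes–Cantor corrected)

The counting variant implemented is NG86 with equal pathway weighting,
matching the default of the common desktop implementations. Site counting:
each of a codon's single-base neighbours is classified synonymous or
nonsynonymous; neighbours that are stop codons are excluded from both
numerator and denominator, so a codon's site total is 3 minus one third per
stop neighbour. Pair site counts average the two sequences. Difference
counting for codons differing at 2–3 positions averages equally over all
orderings of single steps, excluding pathways that pass through a stop
codon; in the rare case where every pathway is blocked, all pathways are
used and steps into/out of stops count as nonsynonymous (classifying a
stop-involving step is otherwise undefined). Codons containing ambiguity,
or that are stops in either sequence, are skipped (codon-level pairwise
deletion). Proportions pS = Sd/S and pN = Nd/N are corrected by
d = −(3/4)·ln(1 − 4p/3); the correction is undefined for p ≥ 3/4 and the
result is then flagged, never silently zeroed. Ka/Ks is reported only when
Ks > 0; per-gene summaries give the mean and *sample* standard deviation
(n − 1) over defined ratios, with the number of undefined pairs reported.

## Nucleotide diversity and sliding windows

π is the mean over unordered sequence pairs of the per-site difference
proportion; S counts columns with at least two distinct unambiguous states.
Gap/ambiguity handling is switchable: pairwise deletion (default; each pair
compared over its own complete sites) or complete deletion (columns with
any gap/ambiguity removed globally, the DnaSP default) — both are provided
because the two conventions differ on real data. Windows are 1-based on
the concatenated-PCG alignment, starting at 1, 1+step, …, with the
terminal partial window dropped, giving exactly
`floor((L − window)/step) + 1` windows; defaults are window = 200 bp,
step = 25 bp. With step = window and no excluded columns, the site-weighted
mean of window π reconstructs the whole-alignment π exactly (asserted).

## F84 distance and saturation

For a pair, s and v are the transition and transversion difference
proportions over pairwise-complete sites. The F84 distance uses base
frequencies *averaged over the two sequences*:

    A = πAπG/πR + πCπT/πY,  B = πAπG + πCπT,  C = πRπY
    d = −2A·ln(1 − s/2A − (A−B)v/2AC) + 2(A−B−C)·ln(1 − v/2C)

with πR = πA+πG, πY = πC+πT. At equal frequencies this reduces exactly to
the Kimura two-parameter closed form (asserted to 1e−9). Whenever a
logarithm argument is non-positive the distance is undefined and the point
is flagged saturated — a flagged value, never a silent NaN or zero.

## Synthetic-data generator

The generator emulates the canonical teleost mitogenome that motivates the
package: the default layout is the published 16,943 bp gene map (37 genes +
control region), so generated records carry the real architecture — the
10 bp ATP8/ATP6 and 7 bp ND4L/ND4 overlaps, the 34 bp trnN–trnC spacer, the
light-strand set {ND6, trnQ, trnA, trnN, trnC, trnY, trnS2, trnE, trnP},
COI's GTG start and AGG stop, and the published incomplete-stop classes.
The heavy strand is drawn i.i.d. from base probabilities
(A .321, C .278, G .151, T .250 by default, giving AT% ≈ 57 and a negative
heavy-strand GC-skew). Protein-coding constraints — start codon, stop codon
or incomplete tail, stop-free internal frame in sense orientation — are then
imposed by an iterative repair pass over all PCGs. Because overlapping
genes constrain shared bases (e.g. ATP6's ATG sits inside ATP8's frame),
a repaired third-position base can be overwritten by another gene's
hard-set codon; codons that keep re-appearing as stops therefore escalate
the edit to the 2nd, then 1st codon position until the fix persists, and
the pass iterates to a fixed point (non-convergence raises rather than
returning an invalid genome). Same seed ⇒ byte-identical GenBank output;
the RNG is numpy's PCG64 via `default_rng(seed)`, and the seeding
discipline is part of the public contract.

Evolution is a star phylogeny. Neutral sequence evolves by
Poisson(branch length) substitution events per site, each event choosing a
transition with probability κ/(κ+2); the expected number of events per site
equals the branch length, so Jukes–Cantor-corrected distances recover it
(asserted within 3 SE over 200 replicates at t = 0.05 and 0.2). Within
PCGs, candidate substitutions are accepted always if synonymous, with
probability min(1, ω) if nonsynonymous, and never if stop-creating; the
first codon and the terminal stop/tail are held fixed. Each gene evolves
independently in its sense frame; bases shared by overlapping genes take
the later gene's value and a final repair pass restores coding validity.
No indels are simulated, so positional per-gene extraction *is* the
codon-exact alignment — this keeps the Ka/Ks and π oracles exact and avoids
shipping an aligner. The default κ is 4 (a realistic fish-mtDNA
transition bias); the Ka/Ks recovery validation runs at κ = 1, i.e. under
the NG86 counting model's own no-transition-bias assumption, which is the
appropriate regime for validating that estimator (at ω = 1 the recovered
mean ratio is ≈ 1.04 over 50 replicates of 5 taxa × 500 codons).

What the generator does **not** emulate: control-region tandem repeats,
heteroplasmy, realistic tRNA secondary structure, among-site rate
heterogeneity, and indels. Passing tests therefore demonstrate correctness
of the accounting and estimators under the stated models, not robustness
to alignment error or repeat-induced assembly artefacts in real data.

## Validation problem sizes

The suite validates NG86 counting against an exhaustive
9-neighbour/pathway-enumeration oracle on all 60 sense codons and 1,000
random 30-codon pairs; π against a brute-force pairwise oracle on 500
random alignments up to 6 × 30 (with ambiguity and gap symbols); F84
monotonicity over branch lengths {0.02, 0.05, 0.1, 0.2, 0.4}; Ka/Ks
recovery over 50 seeded replicates per ω ∈ {0.05, 0.5, 1.0}; and the
coverage identity on 100 generated genomes. These sizes keep the default
test run to well under a minute per module while giving the estimators
non-trivial coverage.

## Known limitations

- Whole-accession statistics (full-length compositions, the multi-species
  π and per-gene Ka/Ks of real notopterid alignments) require the deposited
  sequences and an alignment step; the package consumes pre-aligned input
  and the shipped data cover only what is reproducible from printed tables.
- The ND4-style Ka/Ks > 1 phenomenon on real data is sensitive to the
  deletion mode; both pairwise and complete deletion are provided, and the
  mode is recorded in outputs.
- The GenBank reader canonicalizes names via a shipped alias table; deposits
  using exotic nomenclature fall back to verbatim names with a warning
  rather than silent guessing.
- The published OQ446559 Cytb row is internally inconsistent (printed end
  contradicts printed size); the shipped table uses the self-consistent
  boundary. The reader itself never repairs user inputs.
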