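# Methods

## Scope and model

`phage-ssr` surveys perfect microsatellites (simple sequence repeats, SSRs)
and compound microsatellites (cSSRs) in bacteriophage-scale genomes
(tens of kb). An SSR is a maximal perfect tandem tract of an aperiodic
motif of 1–6 bp with at least a threshold number of whole copies; a cSSR
is a chain of two or more SSRs whose intervening distances are each at
most dMAX bases. The pipeline computes per-genome abundance and density
statistics, a cohort-level expectation model for compound incidence,
coding/non-coding placement against a CDS annotation, and a chi-square
comparison of motif composition between genome groups.

## Detection

Thresholds default to 6 whole copies for mononucleotides and 3 for di-
through hexanucleotides — the standard perfect-mode mining settings for
small viral genomes. Rules that matter for reproducibility:

- **Maximality.** A tract cannot be extended left or right by a full or
  partial motif copy while remaining perfect. Partial trailing copies are
  excluded from the copy count and from the coordinates (a 7-base CG
  region is (CG)₃ spanning 6 bases).
- **Minimal period.** A motif must be aperiodic: ATATAT is reported once
  as (AT)₃ and never again at period 4 or 6. This prevents double
  counting; all composition classes used downstream are aperiodic.
- **N handling.** N never certifies a perfect copy: it breaks runs and
  never appears inside a reported tract. IUPAC ambiguity codes are mapped
  to N at ingest (with a logged count), and matching is case-insensitive
  via uppercasing.
- **Strand.** Only the forward strand is scanned. A tandem repeat's
  reverse complement is itself a tandem repeat at the same coordinates, so
  one strand finds every tract; CDS strand is kept for reporting only.
- **Overlap.** Tracts of different motif classes may overlap; tracts of
  one class and period form a single maximal run by construction.

The scanner compares the sequence against itself shifted by each period
k ∈ {1..6} and run-length-encodes the match vector; a maximal run of m
matches is a perfect region of m + k bases with ⌊(m+k)/k⌋ whole copies.
Its output is verified, in tests, against an independent brute-force
reference (`brute_force_ssr_oracle`: every start, every period, maximal
extension, aperiodicity by the string-doubling criterion) on hundreds of
random sequences; the two implementations share no code.

Motif classes for composition summaries are cyclic-rotation classes,
represented by the lexicographically smallest rotation (GC → CG,
GGC → CGG). Reverse complements are *not* merged: C and G runs, or CT and
GA, are biologically distinct signals on the annotated strand and are
kept apart.

## Compound chaining and classification

Gap between two tracts = start₂ − end₁ − 1 (intervening bases; negative
means overlap, which always chains). The prose convention "separated by
less than 10 bp" and the setting dMAX = 10 conflict at the boundary; the
setting wins: the rule is **gap ≤ dMAX**, boundary-tested at gap 10 vs 11.
dMAX is restricted to [0, 50].

Chaining is greedy left-to-right with the test applied against the
chain's maximum end seen so far, which equals connected components of the
pairwise gap graph (asserted against a union-find oracle in tests).
Chains of ≥ 2 members become compound loci; each input SSR ends up in
exactly one chain or the standalone list.

Classification (in rule order): 2 members of the same rotation class with
a gap ≥ 1 → *interrupted-pure*; 2 members of different classes at gap 0 →
*compound*; with a gap → *interrupted-compound*; ≥ 3 members with all
gaps 0 → *compound*; with any gap → *complex*. Two same-class members at
gap 0 can occur at a rotation phase break (ACACAC|CACACA: the junction
breaks period 2, so maximality does not merge them); such pairs are
classified *compound*.

Raising dMAX can only grow chain membership, so the total number of SSRs
inside compound loci (CcSSR) is non-decreasing in dMAX. The *count* of
compound loci is not monotone in general — two loci can merge into one —
though it is monotone when clusters are farther apart than the largest
dMAX examined, the regime the sweep summaries describe. `dmax_sweep`
therefore reports counts without claiming monotonicity.

## Statistics

Per genome of length L (kb = L/1000):

- RA = n_SSR / kb; RD = SSR tract bp / kb; cRA = n_cSSR / kb;
  cRD = compound span bp / kb. Compound span includes interruptions
  (switchable to members-only was considered and rejected: "sequence
  space" of a compound locus is naturally its full extent).
- Two distinct compound percentages are kept apart because both readings
  are in circulation: `cssr_percent` = 100·n_cSSR/n_SSR (count of loci)
  and `ssr_in_cssr_percent` = 100·CcSSR/n_SSR (membership). The former is
  bounded above by the latter since every locus has ≥ 2 members.
- Cohort expectation: c′ = (1/n) Σᵢ CcSSRᵢ/cSSRᵢ over genomes with at
  least one compound locus (genomes with zero loci are excluded — the
  ratio is undefined — and flagged). Per genome E = CcSSR/c′ and
  z = (O − E)/√E with O the observed locus count; z > 0 iff O > E.
  Genomes with CcSSR = 0 are flagged rather than assigned z = 0.
- Regressions of SSR metrics on genome size / GC are ordinary least
  squares (scipy), reporting R², slope, and the slope's p-value.
- Group comparisons pool motif-class counts within each group and apply
  Pearson chi-square on the count table (never on percentages); classes
  absent from every group are dropped; no continuity correction by
  default (a Yates flag exists for 2×2 tables).

Full precision is kept internally; tables round to 2 decimals at
serialization only.

## Coding / non-coding placement

CDS intervals come from GenBank flat files (1-based inclusive
coordinates everywhere in serialized tables). join/complement locations
collapse to their spanning interval — phage genes are effectively never
spliced, and placement needs only extent — with a flag noting the
compound location. Labels prefer /gene, then /product, then /locus_tag,
then an ordinal. The CDS feature kind is the default; the reader accepts
any feature-kind set.

An SSR is *coding* when it overlaps any CDS by ≥ 1 bp (boundary-spanning
tracts count as coding); an alternative assign-by-start rule is available
behind a flag. Among overlapping CDS the largest overlap wins, ties to
the smallest start — deterministic and order-independent. Cross-genome
aggregation of per-CDS distributions is by identical CDS label only.

## Synthetic data

The generator emulates the study conditions rather than any particular
genome: iid per-base background (the analysis uses only repeat content
and GC, so Markov structure would add nothing testable), lengths
42–112 kb, GC 0.50–0.69, and non-overlapping CDS intervals covering a
0.78 target fraction (construction is exact up to integer rounding; CDS
and gap lengths are Dirichlet-distributed).

Planted repeats are written at explicit positions or auto-placed with a
repeat-free buffer of 6·max(iterations) bases (explicit positions may be
arbitrarily close, as compound layouts require, but never overlap). With
`scrub=True`, every background window that spontaneously contains a
qualifying repeat is resampled (the planted bases are protected) until
the detector finds exactly the planted set — bounded at 1000 rounds, then
an error. This makes the planted list *exhaustive* truth, so recovery
tests assert precision = recall = 1.0 exactly. The expected compound
count at each dMAX is derived from planted coordinates by the gap rule,
independently of the chaining engine.

The cohort generator places ~2 loci per kb, ~12% of them as 2–3-member
clusters with 1–9 bp gaps (so they compound at dMAX 10), isolated loci
≥ 60 bp apart (so they never chain even at dMAX 50), and each locus in a
coding region with probability equal to the coding fraction. The motif
pool is GC-biased, mirroring the high-GC genomes this emulates, and every
pool motif was chosen so its pure tract contains no other qualifying
repeat — a prerequisite for exhaustive truth. Compound incidence in the
simulated cohort sits near the top of the range seen in real phage
surveys; the clusters are denser than nature to exercise the chaining
and classification paths.

What passing on synthetic data does *not* show: performance on real
annotation quirks (pseudo-genes, programmed frameshifts), on imperfect
or interrupted single repeats (out of scope by design — perfect mode
only), or agreement with any specific published genome table.

## Numerical and degenerate-input choices

- GC fraction of an all-N sequence is reported as 0 (guarded
  denominator).
- Empty SSR lists are legal everywhere downstream; `coding_fraction` of
  zero labels and c′ of a compound-free cohort are errors, not zeros.
- Motif-length rows with no SSRs are reported as NaN ("absent"), never 0%.
- A zero margin in a contingency table is an error naming the cell class.
- Reruns of the survey with the same config are byte-identical: no
  timestamps in outputs, fixed rounding, fixed iteration order.

## Problem sizes in the test suite

Oracle equivalence runs on 100 random 2 kb sequences plus
property-based small cases; chaining is checked against the union-find
oracle on dozens of random layouts; recovery uses 20 seeds at 12 kb; the
end-to-end check simulates 20 genomes at the full 42–112 kb study scale.
These sizes were chosen to exercise every code path at the cohort's
realistic scale while keeping the suite fast enough to run on every
commit.
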