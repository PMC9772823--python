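# Methods

## Scope and model

`tcrbseq` classifies TCRβ 5'RACE amplicon reads by the recombination
and splicing state their alignment to the germline locus implies, and
derives two families of statistics from the labels: repertoire
compositions (clonality read-out) and the abundance of non-recombined
J2-2P~J2-3 transcripts (digital-PCR biomarker read-out). The
classification is purely descriptive of the RNA molecule observed: an
aberrantly spliced read says nothing definitive about the underlying
DNA recombination state, and the classifier makes no such inference.

## The synthetic locus

Real TCRβ loci are ~600 kb with ~65 V genes; the synthetic locus is a
~5 kb miniature that preserves every feature the classifier's rules
touch, in germline order:

* five V segments (280 bp) whose final 20 bp are distinct random
  20-mers, giving the primer-audit module unambiguous targets;
* D1 (30 bp), a J1 cluster (3 × 50 bp), C1 (200 bp);
* D2, a J2 cluster in which the 40 bp pseudogene **J2-2P** sits 40 bp
  upstream of the last J ("J2-3"), then C2;
* C2 is a copy of C1 with one substitution inside the first 23 bp (the
  3' PCR-primer window), emulating the near-identity of the real C1/C2
  that motivates the C1→C2 re-annotation rule;
* GT donors after every V/D/J segment and AG acceptors before every
  D/J/C segment; two additional intergenic donors upstream of D1, the
  major one exactly 174 bp upstream of the D1 start (the dominant
  aberrant-splice donor position the evidence summary reports);
* one cryptic 23RSS (CACAGTG + 23 bp spacer + ACAAAAACC) planted on
  the plus strand of the C1–D2 intergenic region.

Real D segments are 12–16 bp; the synthetic 30 bp keeps them above the
20 bp minimum alignable-segment length so D-containing categories are
exercisable. Default inter-segment introns are 100 bp (≥30 bp
everywhere), large enough that the ≥15 bp upstream-intron rules have
room on both sides of their boundary. Intron length retained around
each segment is a free parameter of the miniature, not an estimate of
the real locus.

Coordinates are 0-based half-open internally and 1-based inclusive in
GFF3 output. Cryptic RSS sites are consumed as *annotation* by the
classifier; a consensus scan (heptamer/nonamer, ≤2 mismatches) is
provided for exploration only, so classification correctness does not
hinge on motif-scan heuristics.

## Read simulation

Inserts are cut constructively from the locus so that each read
satisfies its category's defining rule by construction; ground truth
is therefore exact. Key generator conditions:

* default category mix CR 0.41, NR 0.40, AS 0.08, PR 0.03, NS 0.04,
  AR 0.01, UC 0.015, CH 0.015 — CR and NR dominate, aberrant splicing
  outweighs partial recombination, UC+CH ≈ 3 %;
* NR reads draw the J2-3 segment with weight 0.5 and cover J2-2P with
  probability 0.762; upstream introns are drawn 20–80 bp (41–75 bp
  when covering J2-2P), leaving a safety margin above the 15 bp
  boundary so that alignment-end fuzz under sequencing errors does not
  flip categories;
* UC reads use 0–14 bp introns (strictly below the boundary);
* CR junctions are 6–20 random bases, or two 3–10 base junctions
  around an optionally trimmed D; a configurable fraction (default
  0.10) of CR reads are short V-(D)-only molecules;
* AS reads are 80 % intergenic→C (of which 80 % use the major donor
  174 bp upstream of D1), 15 % V→C, 5 % intergenic→J→C far from the
  cryptic RSS; AR reads end 0–30 bp before the cryptic RSS start;
* technical layout: 25 bp adapter + 10 bp barcode + 22 bp universal
  primer, insert, reverse-complemented barcode + adapter. The 3'
  gene-specific primer site is part of the insert's C region, as in a
  real 5'RACE amplicon, so it is not appended separately;
* errors: independent per-base substitutions and indels (insertion /
  deletion equally likely). No flowgram/homopolymer error structure
  and no length-dependent amplification bias are modelled; passing
  tests therefore demonstrate rule correctness and robustness to
  generic point errors, not performance on real 454 chemistry;
* 20 % of inserts are reverse-complemented to exercise minus-strand
  handling.

Sample barcodes must be pairwise Hamming ≥3; a deterministic generator
provides such sets.

## Preprocessing

Technical anchors are located by tolerant infix alignment (edlib) with
a 90 % identity floor; a barcode is called when ≥8/10 bases match.
Reads whose two end barcodes disagree are discarded; reads with one
detectable end are assigned to that sample (only *inconsistent* pairs
are evidence of mis-pooling; `require_both_ends` restores the stricter
behaviour). Trimmed reads shorter than 150 bp are dropped (150 kept,
149 dropped) so NR intronic context stays detectable. Every read is
accounted for: assigned + discarded (with reason codes) = input.

## Alignment and chaining

Reads are aligned by exact 13-mer seeding against a cached locus
index, greedy diagonal clustering (band 8, gap ≤35 bp), and ungapped
x-drop end extension (match +1, mismatch −2, drop 4); segment identity
is computed with edlib. The read is reverse-complemented up front when
the minus orientation has more seed support, so downstream stages see
one canonical orientation; cross-strand fragments are still collected
as chimera evidence.

Three post-processing rules mirror how broken or ambiguous local
alignments must be repaired before classification:

1. **merge broken alignments** — same-strand neighbours with read-gap
   d_r and reference-gap d_g, both ≤30 bp, merge iff
   |d_r − d_g| < max(d_r, d_g)/2, iterated to fixpoint. Abutting
   fragments (0/0) also merge: the strict inequality is undefined
   there and the fragmentation is an alignment artifact. The 30 bp
   closeness threshold is deliberately below the 100 bp minimum intron
   so genuine splice junctions are never merged across.
2. **C1→C2 re-annotation** — an order-violating C1 call whose
   homologous C2 placement restores the germline order is relabeled
   C2 (one direction only).
3. **splice-aware overlap splitting** — read-overlapping neighbours
   (overlap ≤30 bp) are split at the breakpoint flanked by a GT donor
   and an AG acceptor in the reference, maximising matched bases;
   without such support the midpoint is used and the pair flagged.
   Overlaps larger than 30 bp are near-duplicate placements of the
   same read span (the near-identical C1/C2 produce one for every
   C-bearing read) and are left for chain selection to arbitrate.

Chain selection maximises identity-weighted aligned length over
strand-consistent, order-consistent subsets (monotone reference order,
≤5 bp residual overlap), ties broken toward more segments and then the
leftmost chain start; a dynamic program reproduces the exhaustive
subset-enumeration optimum (property-tested). Excluded segments whose
read span does not overlap the chain by ≥50 % of their length are kept
as conflicts (chimera evidence); heavier overlap marks an alternative
alignment, which is discarded.

Segments are labeled by the most downstream gene segment their
reference interval overlaps, with the distance from the segment start
back to the alignment start recorded as `upstream_intron_bp` (a J2-3
alignment reaching over J2-2P counts the pseudogene span as upstream
intron); pseudogene-only or gene-free intervals are intergenic.
Minimum segment length 20 bp and identity 85 % exclude spurious
10-mer-scale hits while keeping the 23 bp C primer region alignable.

## Classification

Rules are applied in precedence order CH, CR, PR, AR, AS, NR, NS, UC
(chimera first; AR before AS because it is the more specific reading
of intergenic-J-(C)). Boundary semantics are exact: intron ≥15 bp,
V-(D)-only tail ≤60 bp, NS unaligned ≤120 bp, AR distance ≤30 bp.
GT/AG motifs are recorded as evidence, never required — splice-site
support is a post-hoc justification fraction, not a filter. D-J-(C)
chains lacking the ≥15 bp intron and J-(C) chains lacking it fall to
UC (their recombination state is uncertain); D-C chains are AS.

One deliberate robustness allowance: the AR distance is measured as a
signed offset to the nearest cryptic-RSS start and up to 8 bp of
*overshoot* past the start is tolerated, because x-drop extension can
carry an alignment end a few chance-matching bases beyond the true
junction. The ≤30 bp rule on the upstream side is unchanged.

The classifier is checked against an independent predicate-based
oracle on an exhaustive enumeration of ≤4-segment templates crossed
with boundary values (intron 14/15/16, tails 59/60/61 and 119/120/121,
RSS distance 29/30/31).

## Repertoire statistics

Category compositions are normalised over the six informative
categories after excluding UC/CH (an eight-way audit table is
retained). CDR3 is operationalised as the read interval between the
end of the V alignment and the start of the J alignment — nucleotide
identity, no conserved-Cys/Phe trimming — and clonotypes are keyed
(V, J, CDR3). V-(D)-only CR reads and D-only PR reads are excluded
from clonotype / D-J statistics. An NR read is J2-2P~J2-3 when its
alignment covers ≥1 bp of the J2-2P interval (configurable).

## Biomarker statistics

The ratio is 100·c(J2-2P~J2-3)/c(J2-3), reported half-up at one
decimal with the unrounded value retained; a sample is positive when
the ratio is ≥ the cutoff (default 5 %, boundary positive). The
bundled reference cohort (9 TCL, 6 non-TCL) carries its published
one-decimal ratios as the authoritative reported values because some
printed ratios are inconsistent with one-decimal recomputation from
the printed concentrations (e.g. 2.6/9.7 = 26.8 % vs a printed
26.6 %), implying they were computed from unrounded instrument
concentrations; recomputed ratios are stored alongside, and tests
assert equality only on the self-consistent rows.

The group comparison is an exact two-sided Wilcoxon rank-sum test:
with ≤20 observations and no ties, the rank-sum distribution is
enumerated by dynamic programming and the smaller one-sided tail is
doubled (capped at 1). On the reference cohort the groups separate
completely, giving p = 2/C(15,9) = 2/5005 ≈ 0.0004. With ties or
larger samples a mid-rank normal approximation with tie correction and
continuity correction is used and flagged as approximate. BIOMED-2
annotations are parsed as monoclonal iff either gene shows a
monoclonal pattern; dPCR-positive samples without one are counted as
assay-discordant detections.

## Primer audit

Ungapped sliding-window matching on both strands with ≤4 mismatches —
a gapped mode is unnecessary under that mismatch budget for 15–30-mers
— keeping per gene segment the fewest-mismatch (then leftmost) hit.
Distance from the primer 3' end counts the terminal base as 0, so
"within 10 bases of the 3' end" is distance ≤10. `match_delta` is +1
when the alternate allele matches the primer base the reference
mismatched, −1 for the reverse, 0 otherwise. Variant discovery itself
is out of scope: the module consumes SNP tables and applies the
population filter (drop when all named population frequencies are
zero, annotate the maximum otherwise). Segment exclusion is a generic
list argument rather than a hard-coded set.

## Problem sizes and statistical checks

The test suite and acceptance script use seeded simulations at sizes
chosen to make multinomial checks decisive while keeping runs fast:
10,000-read cohorts for per-category truth recovery (≥99 % error-free;
≥90 % at 1 % substitutions + 0.2 % indels), 20 × 400-read replicates
for parameter recovery, 800 reads for clonal-spike recovery. Parameter
recovery is asserted on counts pooled across the 20 replicates within
3 multinomial σ of the pooled size — the sharper test of estimator
bias — with a per-replicate 4σ guard against gross outliers. The
spike-recovery check uses a CR-only design with the V-(D)-only
subtype disabled so the expected top-clonotype fraction equals the
designed spike fraction exactly.

## Known limitations

* The locus is a miniature: no allelic variation, one cryptic RSS, a
  single V family; V-call ambiguity of real repertoires is absent.
* Error model is i.i.d. substitutions/indels; homopolymer errors
  (454's dominant mode) are not simulated.
* Amplification length bias (shorter molecules amplify better) is not
  modelled, so simulated compositions are unbiased by construction;
  real 5'RACE compositions are not directly comparable to dPCR ratios.
* CDR3 extraction is nucleotide-interval based; amino-acid clonotyping
  and diversity indices are out of scope.
* The chimera rule counts any retained cross-strand or order conflict;
  at very high error rates spurious conflicts could inflate CH.
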