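# tcrbseq

Tools for characterising **TCRβ transcripts captured by 5'RACE
amplicon sequencing**, with a focus on the reads that conventional
repertoire pipelines throw away: non-recombined (NR) germline
transcripts in which a J gene segment is spliced directly to the
constant (C) segment without V(D)J recombination.

T-cell lymphoma (TCL) diagnosis leans on clonality assays (BIOMED-2
multiplex PCR) that detect a dominant *recombined* TCR allele. Some
lymphomas — notably a subset with polyclonal TCRβ — escape that assay.
NR TCRβ transcripts, and specifically those whose J2-3 alignment
extends over the upstream pseudogene **J2-2P** ("J2-2P~J2-3" reads),
behave as an orthogonal biomarker: their relative abundance against
all J2-3-containing transcripts, measured by digital PCR, separates
TCL from non-TCL bone-marrow samples at a **≥5 %** cutoff.

The package has three layers:

1. **Read classification.** Reads trimmed of technical sequence are
   aligned to an annotated TCRβ-like locus and each read's ordered
   segment chain is assigned one of eight categories:

   | category | structure (upstream → downstream) |
   |---|---|
   | CR | V‑(D)‑J‑(C), completely recombined (V‑(D)-only reads included, excluded from clonotype stats) |
   | PR | D‑J‑(C) with ≥15 bp intron immediately upstream of D |
   | NR | J‑(C) with ≥15 bp intron immediately upstream of J |
   | NS | C only, intron retained (≥15 bp), ≤120 bp unaligned |
   | AS | C spliced downstream of a V, D or intergenic segment |
   | AR | intergenic‑J‑(C) ending within 30 bp of a cryptic 23RSS |
   | UC | uncertain (e.g. J‑(C) without the ≥15 bp intron) |
   | CH | chimeric: cross-strand, order-violating, or ≥2 C segments |

2. **Repertoire statistics.** Per-sample category compositions,
   VJ-pairing and CDR3-clonotype tables with top-k dominance (CDR3 =
   the read interval between the V and J alignments), J-gene usage per
   category, and the NR split into J2-2P~J2-3 vs J2-3_only.

3. **Biomarker statistics.** Digital-PCR ratio
   `100 · c(J2-2P~J2-3) / c(J2-3)`, the ≥5 % positivity call, and an
   exact two-sided Wilcoxon rank-sum comparison of TCL vs non-TCL
   ratios; a reference cohort of 9 TCL and 6 non-TCL bone-marrow
   samples ships with the package.

Because public raw 454 data are not needed for development or testing,
the package includes a **synthetic locus builder and read simulator**:
a compact TCRβ-like locus (V…, D1, J1 cluster, C1, D2, J2 cluster with
J2-2P immediately upstream of J2-3, C2, near-identical C1/C2, GT/AG
splice motifs, planted intergenic splice donors and a cryptic 23RSS)
and a generator of barcoded, adapter-wrapped, error-mutated reads with
exact ground-truth labels for all eight categories.

A `primer_audit` module maps multiplex-PCR primer oligos onto the
locus (ungapped, ≤4 mismatches, best hit per gene segment) and
assesses SNPs for primer-site overlap, distance from the primer 3'
end, match improvement, and population-frequency filtering.

## Worked example

```python
from tcrbseq import (build_synthetic_locus, CategoryMix, SampleDesign,
                     default_barcodes, simulate_cohort, demultiplex,
                     annotate_reads, classify_chains, category_composition,
                     ErrorModel)

locus = build_synthetic_locus(seed=1)
bc = default_barcodes(1)[0]
records, truth = simulate_cohort(
    locus, [SampleDesign("S1", bc, CategoryMix(), 2000)],
    ErrorModel(0.01, 0.002), seed=5)
kept, dropped = demultiplex([(r.id, str(r.seq)) for r in records], {"S1": bc})
chains, _ = annotate_reads(kept, locus)
labels = classify_chains(chains, locus)
print(labels.category.value_counts())
```

prints (2 000 reads at a 1 % substitution / 0.2 % indel error rate):

```
category
CR    832
NR    802
AS    140
NS     83
PR     61
UC     37
CH     32
AR     12
Name: count, dtype: int64
```

i.e. the simulated mix (41 % CR, 40 % NR, 8 % AS, …) is recovered
after demultiplexing, trimming, alignment and classification, with
per-category agreement against the simulator's ground truth ≥90 % at
this error rate (100 % on error-free reads).

The biomarker layer on the bundled reference cohort:

```python
from tcrbseq import load_dpcr_table, cohort_report
report = cohort_report(load_dpcr_table(), cutoff=5.0)
print(report["wilcoxon_p"])      # 0.0003996003996003996  (= 2/5005)
print(report["n_positive"])      # 9   (all TCL samples)
print(report["n_negative"])      # 6   (all non-TCL samples)
```

The same steps are exposed as a CLI (`tcrbseq build-locus | simulate |
preprocess | annotate | classify | report | biomarker | primer-audit`).

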