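"""Multiplex-primer site mapping and variant assessment.

Primer oligos are mapped onto the locus by ungapped sliding-window
comparison on both strands, allowing at most four mismatches; per gene
segment the best (fewest-mismatch, then leftmost) hit is retained.
Supplied SNPs are then assessed for whether they fall inside a primer
site, how far they sit from the primer 3' end (terminal base = 0, so
"within 10 bases of the 3' end" means distance <= 10), and whether the
alternate allele improves or worsens the primer match.  A simple
population-frequency filter drops variants absent from all named
populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .locus import LocusModel
from .simulate import revcomp


@dataclass
class PrimerHit:
    primer_id: str
    segment_name: str
    ref_start: int
    ref_end: int
    strand: str
    mismatches: int
    mismatch_positions: list[int] = field(default_factory=list)  # offsets from 3' end


@dataclass
class VariantRecord:
    position: int  # 0-based reference coordinate
    ref_allele: str
    alt_allele: str
    population_freqs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError("only single-base SNPs are supported")
        for f in self.population_freqs.values():
            if not 0.0 <= f <= 1.0:
                raise ValueError("allele frequencies must be in [0, 1]")


def _window_hits(primer: str, seq: str, max_mismatch: int):
    m = len(primer)
    for start in range(len(seq) - m + 1):
        mm = [i for i in range(m) if seq[start + i] != primer[i]]
        if len(mm) <= max_mismatch:
            yield start, mm


def map_primers(
    primers: list[tuple[str, str]],
    locus: LocusModel,
    max_mismatch: int = 4,
) -> tuple[list[PrimerHit], list[str]]:
    """Best primer hit per gene segment; segments with none are listed
    as unmapped.

    Ungapped matching on both strands; per segment the hit with the
    fewest mismatches is retained, ties broken by leftmost reference
    start.  Mismatch positions are reported as offsets from the primer
    3' end (terminal base = 0).
    """
    for pid, seq in primers:
        if not 15 <= len(seq) <= 30:
            raise ValueError(f"primer {pid}: length must be 15-30 nt")
    hits: list[PrimerHit] = []
    seq = locus.sequence
    for pid, primer in primers:
        m = len(primer)
        for strand, query in (("+", primer), ("-", revcomp(primer))):
            for start, mm in _window_hits(query, seq, max_mismatch):
                # offsets from the primer 3' end on the primer's own strand
                if strand == "+":
                    offsets = [m - 1 - i for i in mm]
                else:
                    offsets = [i for i in mm]
                for gene in locus.segments_overlapping(start, start + m):
                    hits.append(
                        PrimerHit(pid, gene.name, start, start + m, strand, len(mm), sorted(offsets))
                    )
    best: dict[str, PrimerHit] = {}
    for hit in hits:
        cur = best.get(hit.segment_name)
        if cur is None or (hit.mismatches, hit.ref_start) < (cur.mismatches, cur.ref_start):
            best[hit.segment_name] = hit
    unmapped = [s.name for s in locus.segments if s.name not in best]
    return sorted(best.values(), key=lambda h: h.ref_start), unmapped


def assess_variant(
    variant: VariantRecord,
    hit: PrimerHit,
    primer_seq: str,
    locus: LocusModel,
) -> dict:
    """Is the variant in the primer site, how close to the 3' end, and
    does the alternate allele improve the primer match?

    ``match_delta`` is +1 when the alternate allele matches the primer
    base where the reference did not (a better match), -1 for the
    reverse, 0 otherwise.
    """
    if not 0 <= variant.position < len(locus.sequence):
        raise ValueError("variant position outside locus")
    in_site = hit.ref_start <= variant.position < hit.ref_end
    if not in_site:
        return {"in_site": False, "dist_from_3prime": None, "match_delta": 0}
    if hit.strand == "+":
        offset = variant.position - hit.ref_start
        dist = len(primer_seq) - 1 - offset
        primer_base = primer_seq[offset]
        ref_base, alt_base = variant.ref_allele, variant.alt_allele
    else:
        offset = variant.position - hit.ref_start
        dist = offset  # primer 3' end sits at the hit's reference start
        primer_base = revcomp(primer_seq)[offset]
        ref_base, alt_base = variant.ref_allele, variant.alt_allele
    ref_match = primer_base == ref_base
    alt_match = primer_base == alt_base
    delta = (0 if ref_match else 1) if alt_match else (-1 if ref_match else 0)
    return {"in_site": True, "dist_from_3prime": dist, "match_delta": delta}


def filter_variants_by_freq(
    variants: list[VariantRecord],
    population_names: list[str],
) -> list[tuple[VariantRecord, float]]:
    """Keep variants with a non-zero allele frequency in at least one
    named population, annotated with the maximum such frequency.

    Missing population keys are treated as frequency 0 (with a
    warning).  Idempotent: filtering the retained set again changes
    nothing.
    """
    kept = []
    for v in variants:
        freqs = []
        for name in population_names:
            if name not in v.population_freqs:
                warnings.warn(f"variant at {v.position}: missing population {name!r}, treated as 0")
                freqs.append(0.0)
            else:
                freqs.append(v.population_freqs[name])
        top = max(freqs) if freqs else 0.0
        if top > 0:
            kept.append((v, top))
    return kept


def read_variants_tsv(path) -> list[VariantRecord]:
    """Minimal variant TSV: position (1-based), ref, alt, then one
    column per population frequency."""
    df = pd.read_csv(path, sep="\t")
    pops = [c for c in df.columns if c not in ("position", "ref", "alt")]
    return [
        VariantRecord(int(r["position"]) - 1, r["ref"], r["alt"], {p: float(r[p]) for p in pops})
        for _, r in df.iterrows()
    ]
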