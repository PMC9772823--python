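"""Labeled 5'RACE/454-style read simulation.

Generates inserts for all eight read categories (CR, PR, NR, NS, AS,
AR, UC, CH) directly from an annotated synthetic locus, wraps them in
technical sequences (adapter + 10 bp sample barcode + universal
primer), applies a simple substitution/indel error process, and emits
a pooled read file together with a per-read ground-truth table.

Insert construction is *constructive*: each insert satisfies the
defining structural rule of its category by how it is cut from the
locus, so truth labels are exact by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .locus import LocusModel

CATEGORIES = ("CR", "PR", "NR", "NS", "AS", "AR", "UC", "CH")

# Technical oligos of the 5'RACE/454 library layout.
ADAPTER1 = "CGTATCGCCTCCCTCGCGCCATCAG"
ADAPTER2 = "CTATGCGCCTTGCCAGCCCGCTCAG"
UPM = "CTAATACGACTCACTATAGGGC"

BARCODE_LEN = 10


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class ErrorModel:
    """Per-base substitution / indel error process (454 emulation)."""

    substitution_rate: float = 0.0
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= r <= 0.2:
                raise ValueError("error rates must be in [0, 0.2]")


@dataclass
class ClonalSpike:
    v_name: str
    j_name: str
    cdr3_seq: str
    fraction: float


@dataclass
class CategoryMix:
    """Per-sample category proportions, with an optional clonal CR spike.

    Defaults mirror a healthy-repertoire-like mix: CR and NR dominate,
    aberrant splicing outweighs partial recombination, aberrant
    recombination is rare, and UC/CH together are ~3% of reads.
    """

    proportions: dict[str, float] = field(
        default_factory=lambda: {
            "CR": 0.41, "NR": 0.40, "AS": 0.08, "PR": 0.03,
            "NS": 0.04, "AR": 0.01, "UC": 0.015, "CH": 0.015,
        }
    )
    clonal_spike: ClonalSpike | None = None
    # probability that a CR insert is a short V-(D)-only read
    v_only_prob: float = 0.10
    # probability that a J2-3 NR insert extends over the J2-2P pseudogene
    j22p_prob: float = 0.762
    # sampling weight of J2-3 among NR J choices
    nr_j23_weight: float = 0.5

    def validate(self) -> None:
        for cat, p in self.proportions.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")
            if p < 0:
                raise ValueError("proportions must be non-negative")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category proportions must sum to 1 (got {total})")
        if self.clonal_spike is not None:
            if self.clonal_spike.fraction > self.proportions.get("CR", 0.0) + 1e-12:
                raise ValueError("clonal_spike fraction must be <= the CR fraction")


@dataclass
class TruthRecord:
    read_id: str
    sample_id: str
    category: str
    subtype: str = ""
    v_name: str = ""
    d_name: str = ""
    j_name: str = ""
    c_name: str = ""
    cdr3_seq: str = ""
    intron_len: int = 0
    strand: str = "+"
    insert_start: int = -1  # technical-layout coordinates on the raw read
    insert_end: int = -1


# ---------------------------------------------------------------------------
# Insert construction
# ---------------------------------------------------------------------------


def _c_for_j(locus: LocusModel, j_name: str) -> str:
    return "C1" if j_name.startswith("J1") else "C2"


def _c_prefix(locus: LocusModel, c_name: str, rng: np.random.Generator,
              lo: int = 100, hi: int = 180) -> str:
    c = locus.segment(c_name)
    n = min(int(rng.integers(lo, hi + 1)), len(c))
    return locus.subseq(c.start, c.start + n)


def _choose_nr_j(locus: LocusModel, mix: CategoryMix, rng: np.random.Generator) -> str:
    js = [s.name for s in locus.segments_of_kind("J")]
    last_j2 = max(n for n in js if n.startswith("J2"))
    weights = np.array(
        [mix.nr_j23_weight if n == last_j2 else (1 - mix.nr_j23_weight) / (len(js) - 1) for n in js]
    )
    return str(rng.choice(js, p=weights / weights.sum()))


def simulate_insert(
    locus: LocusModel,
    category: str,
    rng: np.random.Generator,
    mix: CategoryMix | None = None,
    spike: ClonalSpike | None = None,
) -> tuple[str, TruthRecord]:
    """Construct one insert of the requested category plus its truth.

    The returned insert, annotated perfectly against the locus,
    satisfies the defining structural rule of its category.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    mix = mix or CategoryMix()
    t = TruthRecord(read_id="", sample_id="", category=category)
    vs = [s.name for s in locus.segments_of_kind("V")]
    js = [s.name for s in locus.segments_of_kind("J")]
    sub = locus.subseq

    if category == "CR":
        if spike is not None:
            v, j = locus.segment(spike.v_name), locus.segment(spike.j_name)
            cdr3 = spike.cdr3_seq
            v_part = sub(v.end - 200, v.end)
            c_name = _c_for_j(locus, j.name)
            insert = v_part + cdr3 + sub(j.start, j.end) + _c_prefix(locus, c_name, rng)
            t.subtype, t.v_name, t.j_name, t.c_name, t.cdr3_seq = "spike", v.name, j.name, c_name, cdr3
            return insert, t
        v = locus.segment(str(rng.choice(vs)))
        v_part = sub(v.end - int(rng.integers(100, len(v) + 1)), v.end)
        if rng.random() < mix.v_only_prob:
            tail = _rand(rng, int(rng.integers(0, 21)))  # short unaligned CDR3 stub
            t.subtype, t.v_name = "V-only", v.name
            insert = v_part + tail
            if len(insert) < 150:  # pad with more V so the read survives the length filter
                v_part = sub(v.end - 180, v.end)
                insert = v_part + tail
            return insert, t
        j = locus.segment(str(rng.choice(js)))
        use_d = rng.random() < 0.5
        if use_d:
            d_name = "D1" if j.name.startswith("J1") else str(rng.choice(["D1", "D2"]))
            d = locus.segment(d_name)
            n1, n2 = int(rng.integers(3, 11)), int(rng.integers(3, 11))
            trim = int(rng.integers(0, 4))
            cdr3 = _rand(rng, n1) + sub(d.start + trim, d.end - trim) + _rand(rng, n2)
            t.d_name = d_name
        else:
            cdr3 = _rand(rng, int(rng.integers(6, 21)))
        c_name = _c_for_j(locus, j.name)
        insert = v_part + cdr3 + sub(j.start, j.end) + _c_prefix(locus, c_name, rng)
        t.subtype, t.v_name, t.j_name, t.c_name, t.cdr3_seq = "full", v.name, j.name, c_name, cdr3
        return insert, t

    if category == "PR":
        d_name = str(rng.choice(["D1", "D2"]))
        d = locus.segment(d_name)
        intron = int(rng.integers(15, 81))
        junction = _rand(rng, int(rng.integers(0, 11)))
        j_name = str(rng.choice([n for n in js if n.startswith("J1" if d_name == "D1" else "J2")]))
        j = locus.segment(j_name)
        c_name = _c_for_j(locus, j_name)
        insert = sub(d.start - intron, d.end) + junction + sub(j.start, j.end) + _c_prefix(locus, c_name, rng)
        t.d_name, t.j_name, t.c_name, t.intron_len = d_name, j_name, c_name, intron
        return insert, t

    if category == "NR":
        j_name = _choose_nr_j(locus, mix, rng)
        j = locus.segment(j_name)
        last_j2 = max(n for n in js if n.startswith("J2"))
        if j_name == last_j2 and rng.random() < mix.j22p_prob:
            j22p = locus.segment("J2-2P")
            cover = int(rng.integers(1, len(j22p) - 4))
            start = j22p.end - cover
            t.subtype = "J2-2P~J2-3"
        else:
            prev = [s for s in locus.segments if s.end <= j.start]
            gap = j.start - max(s.end for s in prev)
            hi = min(80, gap - 1)
            intron = int(rng.integers(15 if j_name != last_j2 else 20, hi + 1))
            start = j.start - intron
            t.subtype = "J2-3_only" if j_name == last_j2 else "other-J"
        c_name = _c_for_j(locus, j_name)
        insert = sub(start, j.end) + _c_prefix(locus, c_name, rng)
        t.j_name, t.c_name, t.intron_len = j_name, c_name, j.start - start
        return insert, t

    if category == "NS":
        c_name = str(rng.choice(["C1", "C2"]))
        c = locus.segment(c_name)
        intron = int(rng.integers(20, 101))
        n = min(int(rng.integers(150, 201)), len(c))
        insert = sub(c.start - intron, c.start + n)
        t.c_name, t.intron_len = c_name, intron
        return insert, t

    if category == "AS":
        d1 = locus.segment("D1")
        r = rng.random()
        if r < 0.80:  # intergenic donor -> C; major donor 174 bp upstream of D1
            donor = d1.start - (174 if rng.random() < 0.8 else 280)
            room = donor - max(s.end for s in locus.segments if s.end <= donor)
            length = int(rng.integers(100, min(251, room)))
            insert = sub(donor - length, donor) + _c_prefix(locus, "C1", rng)
            t.subtype, t.c_name = "I-C", "C1"
        elif r < 0.95:  # V donor -> C
            v = locus.segment(str(rng.choice(vs)))
            insert = sub(v.end - int(rng.integers(100, 201)), v.end) + _c_prefix(locus, "C1", rng)
            t.subtype, t.v_name, t.c_name = "V-C", v.name, "C1"
        else:  # intergenic -> J -> C, far (>30 bp) from the cryptic RSS
            c1 = locus.segment("C1")
            end = c1.end + int(rng.integers(70, 111))
            start = end - int(rng.integers(40, 66))
            j_name = str(rng.choice([n for n in js if n.startswith("J2")]))
            j = locus.segment(j_name)
            insert = sub(start, end) + sub(j.start, j.end) + _c_prefix(locus, "C2", rng)
            t.subtype, t.j_name, t.c_name = "I-J-C", j_name, "C2"
        return insert, t

    if category == "AR":
        rss = next(x for x in locus.rss_sites if x.cryptic)
        d = int(rng.integers(0, 31))
        end = rss.start - d
        start = end - int(rng.integers(60, 111))
        j_name = str(rng.choice([n for n in js if n.startswith("J2")]))
        j = locus.segment(j_name)
        insert = sub(start, end) + sub(j.start, j.end) + _c_prefix(locus, "C2", rng)
        t.subtype, t.j_name, t.c_name, t.intron_len = f"rss_dist={d}", j_name, "C2", d
        return insert, t

    if category == "UC":
        j_name = str(rng.choice(js))
        j = locus.segment(j_name)
        intron = int(rng.integers(0, 15))
        c_name = _c_for_j(locus, j_name)
        insert = sub(j.start - intron, j.end) + _c_prefix(locus, c_name, rng, 120, 200)
        t.subtype, t.j_name, t.c_name, t.intron_len = "J-C_short_intron", j_name, c_name, intron
        return insert, t

    # CH: chimeric joins violating segment order / strand, or two C segments
    variant = int(rng.integers(0, 3))
    c1, c2 = locus.segment("C1"), locus.segment("C2")
    if variant == 0:  # C-J-C (two C segments)
        j = locus.segment(str(rng.choice([n for n in js if n.startswith("J2")])))
        insert = sub(c1.start, c1.start + 80) + sub(j.start, j.end) + sub(c2.start, c2.start + 80)
        t.subtype, t.j_name, t.c_name = "C-J-C", j.name, "C1,C2"
    elif variant == 1:  # cross-strand V + J-C
        v = locus.segment(str(rng.choice(vs)))
        j = locus.segment(str(rng.choice([n for n in js if n.startswith("J2")])))
        insert = revcomp(sub(v.end - 120, v.end)) + sub(j.start, j.end) + sub(c2.start, c2.start + 100)
        t.subtype, t.v_name, t.j_name, t.c_name = "revV-J-C", v.name, j.name, "C2"
    else:  # order violation: late J, then early J, then C1
        j_late = locus.segment(max(n for n in js if n.startswith("J2")))
        j_early = locus.segment(min(n for n in js if n.startswith("J1")))
        insert = (
            sub(j_late.start - 30, j_late.end)
            + sub(j_early.start - 30, j_early.end)
            + sub(c1.start, c1.start + 100)
        )
        t.subtype, t.j_name, t.c_name = "J2-J1-C", f"{j_late.name},{j_early.name}", "C1"
    return insert, t


def _rand(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n)) if n else ""


# ---------------------------------------------------------------------------
# Technical layout, errors, cohort pooling
# ---------------------------------------------------------------------------


def attach_technical(insert: str, barcode: str, truth: TruthRecord | None = None) -> str:
    """Wrap an insert in the technical read layout.

    Raw read = adapter1 + barcode + UPM + insert + rc(barcode) + rc(adapter2).
    The 3' gene-specific primer site lies inside the insert's C region,
    as in a real 5'RACE amplicon, so it is not appended separately.
    """
    if len(barcode) != BARCODE_LEN:
        raise ValueError(f"barcode must be {BARCODE_LEN} bp")
    head = ADAPTER1 + barcode + UPM
    read = head + insert + revcomp(barcode) + revcomp(ADAPTER2)
    if truth is not None:
        truth.insert_start = len(head)
        truth.insert_end = len(head) + len(insert)
    return read


def apply_errors(read: str, model: ErrorModel, rng: np.random.Generator) -> str:
    """Apply per-base substitutions and indels; deterministic for a
    fixed generator state."""
    if model.substitution_rate == 0 and model.indel_rate == 0:
        return read
    out: list[str] = []
    bases = "ACGT"
    for b in read:
        u = rng.random()
        if u < model.indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(b)
            out.append(bases[int(rng.integers(4))])  # insertion
        elif u < model.indel_rate + model.substitution_rate:
            out.append(bases[(bases.index(b) + 1 + int(rng.integers(3))) % 4] if b in bases else b)
        else:
            out.append(b)
    return "".join(out)


def default_barcodes(n: int, seed: int = 7, min_dist: int = 3) -> list[str]:
    """Deterministic set of 10-mers with pairwise Hamming distance >= 3."""
    rng = np.random.default_rng(seed)
    codes: list[str] = []
    while len(codes) < n:
        cand = _rand(rng, BARCODE_LEN)
        if all(sum(a != b for a, b in zip(cand, c)) >= min_dist for c in codes):
            codes.append(cand)
    return codes


@dataclass
class SampleDesign:
    sample_id: str
    barcode: str
    mix: CategoryMix
    n_reads: int


def simulate_cohort(
    locus: LocusModel,
    samples: list[SampleDesign],
    error_model: ErrorModel | None = None,
    seed: int = 0,
    minus_strand_prob: float = 0.2,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Simulate a pooled multi-sample read set plus its truth table.

    Reads from all samples are pooled (as barcoded 454 libraries were);
    a fraction of inserts is reverse-complemented to emulate transcripts
    sequenced in the minus orientation relative to the reference.
    """
    error_model = error_model or ErrorModel()
    rng = np.random.default_rng(seed)
    barcodes = [s.barcode for s in samples]
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcode across samples")
    for i, a in enumerate(barcodes):
        for b in barcodes[i + 1 :]:
            if sum(x != y for x, y in zip(a, b)) < 3:
                raise ValueError("barcodes must have pairwise Hamming distance >= 3")

    records: list[SeqRecord] = []
    truths: list[TruthRecord] = []
    counter = 0
    for design in samples:
        design.mix.validate()
        cats = list(design.mix.proportions)
        probs = np.array([design.mix.proportions[c] for c in cats])
        spike = design.mix.clonal_spike
        p_spike_given_cr = (
            spike.fraction / design.mix.proportions["CR"] if spike is not None else 0.0
        )
        draws = rng.choice(cats, size=design.n_reads, p=probs)
        for cat in draws:
            use_spike = spike if (cat == "CR" and rng.random() < p_spike_given_cr) else None
            insert, truth = simulate_insert(locus, str(cat), rng, design.mix, spike=use_spike)
            if rng.random() < minus_strand_prob:
                insert = revcomp(insert)
                truth.strand = "-"
            truth.read_id = f"read{counter:06d}"
            truth.sample_id = design.sample_id
            counter += 1
            raw = attach_technical(insert, design.barcode, truth)
            raw = apply_errors(raw, error_model, rng)
            records.append(SeqRecord(Seq(raw), id=truth.read_id, description=""))
            truths.append(truth)
    truth_df = pd.DataFrame([vars(t) for t in truths])
    return records, truth_df


def write_cohort(
    records: list[SeqRecord], truth: pd.DataFrame, out_prefix: str | Path, fmt: str = "fasta"
) -> tuple[Path, Path]:
    prefix = Path(out_prefix)
    reads_path = prefix.with_suffix(".fastq" if fmt == "fastq" else ".fa")
    if fmt == "fastq":
        for rec in records:
            rec.letter_annotations["phred_quality"] = [30] * len(rec)
    SeqIO.write(records, str(reads_path), fmt)
    truth_path = prefix.parent / (prefix.name + ".truth.tsv")
    truth.to_csv(truth_path, sep="\t", index=False)
    return reads_path, truth_path
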