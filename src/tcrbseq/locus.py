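"""Annotated TCRβ-like reference locus.

The locus is a single contiguous sequence carrying gene segments in the
germline order V…, D1, J1-cluster, C1, D2, J2-cluster, C2, with the
pseudogene J2-2P sitting immediately upstream of J2-3.  Intronic /
intergenic sequence separates the segments.  The model also records
splice motifs (GT donors / AG acceptors) and recombination-signal
sequences, including planted *cryptic* 23RSS sites in intergenic
regions, which downstream classification consumes as annotation.

Coordinates are 0-based half-open internally; GFF3 output is 1-based
inclusive per the format.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SEGMENT_KINDS = ("V", "D", "J", "C", "pseudo-J")

RSS_HEPTAMER = "CACAGTG"
RSS_NONAMER = "ACAAAAACC"


@dataclass(frozen=True)
class GeneSegment:
    """One annotated gene segment on the locus."""

    name: str
    kind: str  # V, D, J, C, pseudo-J
    start: int
    end: int
    functional: bool = True

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not self.start < self.end:
            raise ValueError(f"segment {self.name}: start must be < end")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SpliceSite:
    """A splice donor (GT immediately after ``position``) or acceptor
    (AG immediately before ``position``)."""

    position: int
    role: str  # "donor" | "acceptor"

    def __post_init__(self) -> None:
        if self.role not in ("donor", "acceptor"):
            raise ValueError(f"unknown splice role {self.role!r}")


@dataclass(frozen=True)
class RSSSite:
    """A recombination signal sequence (heptamer-spacer-nonamer)."""

    start: int
    spacer: int  # 12 or 23
    strand: str = "+"
    cryptic: bool = False

    def __post_init__(self) -> None:
        if self.spacer not in (12, 23):
            raise ValueError("RSS spacer must be 12 or 23")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass
class LocusModel:
    """Sequence plus typed, ordered annotations of a TCRβ-like locus."""

    sequence: str
    segments: list[GeneSegment]
    splice_sites: list[SpliceSite] = field(default_factory=list)
    rss_sites: list[RSSSite] = field(default_factory=list)
    name: str = "TCRB_synthetic"

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ---------------------------------------------------------

    def segment(self, name: str) -> GeneSegment:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise KeyError(name)

    def segments_of_kind(self, *kinds: str) -> list[GeneSegment]:
        return [s for s in self.segments if s.kind in kinds]

    def segments_overlapping(self, start: int, end: int) -> list[GeneSegment]:
        return [s for s in self.segments if s.start < end and start < s.end]

    def subseq(self, start: int, end: int) -> str:
        return self.sequence[start:end]

    def has_donor(self, position: int) -> bool:
        """GT immediately after ``position``?"""
        return self.sequence[position : position + 2] == "GT"

    def has_acceptor(self, position: int) -> bool:
        """AG immediately before ``position``?"""
        return position >= 2 and self.sequence[position - 2 : position] == "AG"

    def nearest_cryptic_rss(self, position: int) -> int | None:
        """Distance (bp) from ``position`` to the start of the nearest
        *downstream* cryptic 23RSS, or None if there is none."""
        if not 0 <= position <= len(self.sequence):
            raise ValueError(f"position {position} outside locus bounds")
        dists = [
            r.start - position
            for r in self.rss_sites
            if r.cryptic and r.spacer == 23 and r.start >= position
        ]
        return min(dists) if dists else None

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        n = len(self.sequence)
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValueError("segment names must be unique")
        ordered = sorted(self.segments, key=lambda s: s.start)
        if ordered != self.segments:
            raise ValueError("segments must be listed in coordinate order")
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start < a.end:
                raise ValueError(f"segments {a.name} and {b.name} overlap")
        for seg in self.segments:
            if seg.end > n:
                raise ValueError(f"segment {seg.name} extends past locus end")
        for site in self.splice_sites:
            if site.role == "donor" and not self.has_donor(site.position):
                raise ValueError(f"donor at {site.position} lacks GT")
            if site.role == "acceptor" and not self.has_acceptor(site.position):
                raise ValueError(f"acceptor at {site.position} lacks AG")
        for rss in self.rss_sites:
            if not 0 <= rss.start < n:
                raise ValueError("RSS start outside locus bounds")


# ---------------------------------------------------------------------------
# Synthetic locus construction
# ---------------------------------------------------------------------------


@dataclass
class LocusConfig:
    """Layout of the synthetic locus.

    Defaults give a compact locus (~6 kb) with every feature the read
    categories exercise: two D segments, two J clusters, near-identical
    C1/C2, a J2-2P pseudogene 40 bp upstream of J2-3, GT/AG motifs at
    every used splice junction, one cryptic 23RSS in the C1–D2
    intergenic region, and two intergenic splice donors upstream of D1
    (the major one 174 bp upstream of D1, mirroring the dominant
    aberrant-splice donor position).
    """

    n_v: int = 5
    v_len: int = 280
    v_gap: int = 120
    d_len: int = 30
    n_j1: int = 3
    n_j2: int = 3  # functional J2s (J2-2P is added on top, before J2-3)
    j_len: int = 50
    j22p_len: int = 40
    j22p_gap: int = 40  # gap between J2-2P end and J2-3 start
    c_len: int = 200
    intron: int = 100  # default inter-segment gap
    v_d1_gap: int = 600
    c1_d2_gap: int = 250
    flank: int = 200
    as_donor_offset: int = 174  # major aberrant donor, bp upstream of D1 start
    alt_as_donor_offset: int = 280  # minority aberrant donor
    cryptic_rss_offset: int = 150  # bp downstream of C1 end
    c_divergence: int = 1  # substitutions C1 -> C2, within first 23 bp
    primer_site_len: int = 20  # distinct V 3'-suffix length

    def validate(self) -> None:
        if self.n_v < 2:
            raise ValueError("config must request >=2 V segments")
        if self.n_j1 < 2 or self.n_j2 < 2:
            raise ValueError("config must request >=2 J per cluster")
        gaps = [self.v_gap, self.intron, self.j22p_gap, self.v_d1_gap, self.c1_d2_gap]
        if min(gaps) < 30:
            raise ValueError("minimum intron gap is 30 bp")
        if not 1 <= self.c_divergence <= 3:
            raise ValueError("C1/C2 divergence must be 1-3 substitutions")
        if max(self.as_donor_offset, self.alt_as_donor_offset) >= self.v_d1_gap:
            raise ValueError("AS donor offsets must fall inside the V-D1 gap")
        if self.v_d1_gap - self.alt_as_donor_offset < 150:
            raise ValueError("alt AS donor needs >=150 bp of intergenic room upstream")
        if self.cryptic_rss_offset + 7 + 23 + 9 >= self.c1_d2_gap:
            raise ValueError("cryptic RSS must fit inside the C1-D2 gap")


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def build_synthetic_locus(
    config: LocusConfig | None = None, seed: int = 0
) -> LocusModel:
    """Build a synthetic annotated locus; deterministic for a fixed seed."""
    cfg = config or LocusConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    seq: list[str] = []
    segments: list[GeneSegment] = []
    pos = 0

    def emit(n: int) -> int:
        nonlocal pos
        seq.append(_rand_seq(rng, n))
        pos += n
        return pos

    def add_segment(name: str, kind: str, length: int, functional: bool = True) -> GeneSegment:
        nonlocal pos
        start = pos
        emit(length)
        seg = GeneSegment(name, kind, start, pos, functional)
        segments.append(seg)
        return seg

    emit(cfg.flank)
    for i in range(cfg.n_v):
        if i:
            emit(cfg.v_gap)
        add_segment(f"V{i + 1}", "V", cfg.v_len)
    emit(cfg.v_d1_gap)
    add_segment("D1", "D", cfg.d_len)
    for i in range(cfg.n_j1):
        emit(cfg.intron)
        add_segment(f"J1-{i + 1}", "J", cfg.j_len)
    emit(cfg.intron)
    c1 = add_segment("C1", "C", cfg.c_len)
    emit(cfg.c1_d2_gap)
    add_segment("D2", "D", cfg.d_len)
    for i in range(cfg.n_j2 - 1):
        emit(cfg.intron)
        add_segment(f"J2-{i + 1}", "J", cfg.j_len)
    emit(cfg.intron)
    add_segment("J2-2P", "pseudo-J", cfg.j22p_len, functional=False)
    emit(cfg.j22p_gap)
    add_segment(f"J2-{cfg.n_j2}", "J", cfg.j_len)
    emit(cfg.intron)
    c2 = add_segment("C2", "C", cfg.c_len)
    emit(cfg.flank)

    sequence = list("".join(seq))

    # C2 is a near-copy of C1, diverging only at the 5'RACE primer window
    # (first 23 bp), emulating the one-base C1/C2 difference there.
    c1_seq = sequence[c1.start : c1.end]
    sequence[c2.start : c2.end] = c1_seq
    div_pos = rng.choice(23, size=cfg.c_divergence, replace=False)
    for p in div_pos:
        old = sequence[c2.start + p]
        sequence[c2.start + p] = rng.choice([b for b in "ACGT" if b != old])

    # Distinct 20-mer primer-site suffix per V segment.
    by_name = {s.name: s for s in segments}
    suffixes: set[str] = set()
    for i in range(cfg.n_v):
        v = by_name[f"V{i + 1}"]
        while True:
            suf = _rand_seq(rng, cfg.primer_site_len)
            if suf not in suffixes:
                suffixes.add(suf)
                break
        sequence[v.end - cfg.primer_site_len : v.end] = list(suf)

    splice_sites: list[SpliceSite] = []

    def plant_donor(p: int) -> None:
        sequence[p : p + 2] = list("GT")
        splice_sites.append(SpliceSite(p, "donor"))

    def plant_acceptor(p: int) -> None:
        sequence[p - 2 : p] = list("AG")
        splice_sites.append(SpliceSite(p, "acceptor"))

    for seg in segments:
        if seg.kind in ("V", "D", "J"):
            plant_donor(seg.end)
        if seg.kind in ("D", "J", "C"):
            plant_acceptor(seg.start)

    d1 = by_name["D1"]
    plant_donor(d1.start - cfg.as_donor_offset)
    plant_donor(d1.start - cfg.alt_as_donor_offset)

    # Cryptic 23RSS on the plus strand in the C1-D2 intergenic region.
    rss_start = c1.end + cfg.cryptic_rss_offset
    motif = RSS_HEPTAMER + _rand_seq(rng, 23) + RSS_NONAMER
    sequence[rss_start : rss_start + len(motif)] = list(motif)
    rss_sites = [RSSSite(rss_start, 23, "+", cryptic=True)]

    # Canonical (non-cryptic) RSSs flanking D and J segments, for
    # completeness of the annotation.
    for seg in segments:
        if seg.kind == "J":
            rss_sites.append(RSSSite(max(0, seg.start - 28), 12, "+", cryptic=False))
        elif seg.kind == "D":
            rss_sites.append(RSSSite(seg.end, 23, "+", cryptic=False))
    rss_sites.sort(key=lambda r: r.start)

    return LocusModel("".join(sequence), segments, splice_sites, rss_sites)


# ---------------------------------------------------------------------------
# Motif scans
# ---------------------------------------------------------------------------


def scan_splice_motifs(locus: LocusModel) -> list[SpliceSite]:
    """All GT-donor and AG-acceptor contexts in the locus sequence.

    This is a superset of the planted ``locus.splice_sites``.
    """
    if not locus.sequence:
        raise ValueError("locus sequence is empty")
    seq = locus.sequence
    sites = []
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if pair == "GT":
            sites.append(SpliceSite(i, "donor"))
        if pair == "AG":
            sites.append(SpliceSite(i + 2, "acceptor"))
    return sites


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def scan_cryptic_rss(locus: LocusModel, max_mismatch: int = 2) -> list[RSSSite]:
    """Consensus scan for 23RSS-like motifs on the plus strand.

    Heptamer CACAGTG + 23±1 bp spacer + nonamer ACAAAAACC with at most
    ``max_mismatch`` total mismatches.  Provided for exploration;
    classification consumes the planted annotation only.
    """
    seq = locus.sequence
    hits = []
    for i in range(len(seq) - (7 + 22 + 9) + 1):
        hep = seq[i : i + 7]
        mm_h = _hamming(hep, RSS_HEPTAMER)
        if mm_h > max_mismatch:
            continue
        for spacer in (22, 23, 24):
            j = i + 7 + spacer
            non = seq[j : j + 9]
            if len(non) < 9:
                continue
            if mm_h + _hamming(non, RSS_NONAMER) <= max_mismatch:
                hits.append(RSSSite(i, 23, "+", cryptic=True))
                break
    return hits


# ---------------------------------------------------------------------------
# FASTA + GFF3 round trip
# ---------------------------------------------------------------------------


def write_locus(locus: LocusModel, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.fa`` and ``<prefix>.gff3``; returns the two paths."""
    prefix = Path(out_prefix)
    fasta = prefix.with_suffix(".fa")
    gff = prefix.with_suffix(".gff3")
    SeqIO.write([SeqRecord(Seq(locus.sequence), id=locus.name, description="")], str(fasta), "fasta")
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {locus.name} 1 {len(locus.sequence)}\n")
        for seg in locus.segments:
            attrs = f"Name={seg.name};kind={seg.kind};functional={str(seg.functional).lower()}"
            fh.write(
                f"{locus.name}\ttcrbseq\tgene_segment\t{seg.start + 1}\t{seg.end}\t.\t+\t.\t{attrs}\n"
            )
        for site in locus.splice_sites:
            fh.write(
                f"{locus.name}\ttcrbseq\tsplice_site\t{site.position + 1}\t{site.position + 1}"
                f"\t.\t+\t.\trole={site.role}\n"
            )
        for rss in locus.rss_sites:
            fh.write(
                f"{locus.name}\ttcrbseq\trss_site\t{rss.start + 1}\t{rss.start + 1}\t.\t{rss.strand}\t.\t"
                f"spacer={rss.spacer};cryptic={str(rss.cryptic).lower()}\n"
            )
    return fasta, gff


def _parse_attrs(text: str) -> dict[str, str]:
    return dict(kv.split("=", 1) for kv in text.strip().split(";") if "=" in kv)


def read_locus(prefix: str | Path) -> LocusModel:
    """Read a locus written by :func:`write_locus`."""
    prefix = Path(prefix)
    record = next(SeqIO.parse(str(prefix.with_suffix(".fa")), "fasta"))
    segments: list[GeneSegment] = []
    splice_sites: list[SpliceSite] = []
    rss_sites: list[RSSSite] = []
    with open(prefix.with_suffix(".gff3")) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            ftype, start, end, strand, attrs = cols[2], int(cols[3]), int(cols[4]), cols[6], _parse_attrs(cols[8])
            if ftype == "gene_segment":
                segments.append(
                    GeneSegment(
                        attrs["Name"], attrs["kind"], start - 1, end,
                        functional=attrs.get("functional", "true") == "true",
                    )
                )
            elif ftype == "splice_site":
                splice_sites.append(SpliceSite(start - 1, attrs["role"]))
            elif ftype == "rss_site":
                rss_sites.append(
                    RSSSite(start - 1, int(attrs["spacer"]), strand, attrs.get("cryptic") == "true")
                )
    return LocusModel(str(record.seq), segments, splice_sites, rss_sites, name=record.id)
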