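"""Read-to-locus annotation: local alignment, post-processing, chaining.

A processed read is aligned to the locus by exact k-mer seeding and
diagonal clustering, refined with edlib.  Three post-processing rules
are then applied to the raw aligned segments:

1. *merge broken alignments* — two same-strand neighbours close in
   both the read and the reference are merged when their read-gap and
   reference-gap differ by less than half of the larger gap (gaps of
   0/0, i.e. abutting fragments, are also merged);
2. *C1/C2 order repair* — a C1 call that violates the germline segment
   order while the homologous C2 placement would restore it is
   relabeled C2 (one direction only, exploiting the near-identity of
   the two C segments);
3. *splice-aware overlap splitting* — when two neighbouring alignments
   overlap on the read, the overlap is split at a breakpoint flanked by
   a GT donor (upstream side) and an AG acceptor (downstream side) in
   the reference; without such support the midpoint is used and the
   pair flagged.

Finally the highest-scoring strand- and order-consistent subset of
segments is chained; segments excluded by chaining are retained as
conflict evidence for chimera detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import edlib

from .locus import LocusModel
from .preprocess import ProcessedRead
from .simulate import revcomp


@dataclass
class AlignParams:
    k: int = 13  # seed length
    band: int = 8  # diagonal band for seed clustering
    seed_gap: int = 35  # max seed-to-cluster gap during clustering
    min_seg_len: int = 20
    min_identity: float = 0.85
    close_threshold: int = 30  # "close in both read and gene" for merging
    chain_slack: int = 5  # tolerated residual overlap when chaining
    alt_overlap_frac: float = 0.5  # conflict vs alternative-alignment cutoff
    max_kmer_hits: int = 50


@dataclass
class AlignedSegment:
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    strand: str  # '+' or '-', relative to the canonical read orientation
    identity: float = 1.0
    label: str = ""  # gene segment name, or "intergenic"
    kind: str = ""  # V, D, J, C, I
    upstream_intron_bp: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def read_len(self) -> int:
        return self.read_end - self.read_start

    @property
    def score(self) -> float:
        return self.read_len * self.identity


@dataclass
class PairEvidence:
    distance_in_read: int
    distance_in_ref: int
    donor_GT: bool
    acceptor_AG: bool


@dataclass
class SegmentChain:
    read_id: str
    sample_id: str
    read_seq: str  # canonical (plus-locus) orientation
    strand: str  # orientation of the original read vs the locus
    segments: list[AlignedSegment]
    conflicts: list[AlignedSegment] = field(default_factory=list)
    pairs: list[PairEvidence] = field(default_factory=list)

    @property
    def unaligned_head(self) -> int:
        return self.segments[0].read_start if self.segments else 0

    @property
    def unaligned_tail(self) -> int:
        return len(self.read_seq) - self.segments[-1].read_end if self.segments else 0

    @property
    def kinds(self) -> list[str]:
        return [s.kind for s in self.segments]


def _identity(read_part: str, ref_part: str) -> float:
    if not read_part or not ref_part:
        return 0.0
    ed = edlib.align(read_part, ref_part, mode="NW", task="distance")["editDistance"]
    return 1.0 - ed / max(len(read_part), len(ref_part))


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------


class Aligner:
    """Caches the locus k-mer index across reads."""

    def __init__(self, locus: LocusModel, params: AlignParams | None = None):
        self.locus = locus
        self.params = params or AlignParams()
        k = self.params.k
        idx: dict[str, list[int]] = {}
        seq = locus.sequence
        for i in range(len(seq) - k + 1):
            idx.setdefault(seq[i : i + k], []).append(i)
        self.index = {
            kmer: pos for kmer, pos in idx.items() if len(pos) <= self.params.max_kmer_hits
        }

    # -- seed clustering -------------------------------------------------

    def _seeds(self, query: str) -> list[tuple[int, int]]:
        k = self.params.k
        out = []
        for i in range(len(query) - k + 1):
            for p in self.index.get(query[i : i + k], ()):
                out.append((i, p))
        return out

    def _cluster(self, query: str) -> list[list[int]]:
        """Greedy diagonal clustering of seeds; returns [qs, qe, rs, re]."""
        p = self.params
        seeds = self._seeds(query)
        seeds.sort()
        clusters: list[list[int]] = []  # qs, qe, rs, re, diag
        for q, r in seeds:
            diag = q - r
            placed = False
            for c in reversed(clusters):
                if (
                    abs(diag - c[4]) <= p.band
                    and -p.k <= q - (c[1] - p.k) <= p.seed_gap + p.k
                    and -p.k <= r - (c[3] - p.k) <= p.seed_gap + p.k
                    and r >= c[2]
                ):
                    c[1] = max(c[1], q + p.k)
                    c[3] = max(c[3], r + p.k)
                    placed = True
                    break
            if not placed:
                clusters.append([q, q + p.k, r, r + p.k, diag])
        return [c[:4] for c in clusters]

    def _extend(self, query: str, c: list[int], xdrop: int = 4) -> list[int]:
        """Ungapped x-drop extension of a seed cluster in both directions.

        Crossing isolated mismatches (match +1, mismatch -2, stop when
        the running score drops ``xdrop`` below its maximum) keeps
        segment ends accurate when a sequencing error falls near a true
        junction; the extension never crosses an indel — those pieces
        are rejoined by merge_broken.
        """
        seq = self.locus.sequence
        qs, qe, rs, re = c
        n, m = len(query), len(seq)
        best, gain, bq, br = 0, 0, qe, re
        while qe < n and re < m:
            gain += 1 if query[qe] == seq[re] else -2
            qe, re = qe + 1, re + 1
            if gain > best:
                best, bq, br = gain, qe, re
            elif gain < best - xdrop:
                break
        qe, re = bq, br
        best, gain, bq, br = 0, 0, qs, rs
        while qs > 0 and rs > 0:
            gain += 1 if query[qs - 1] == seq[rs - 1] else -2
            qs, rs = qs - 1, rs - 1
            if gain > best:
                best, bq, br = gain, qs, rs
            elif gain < best - xdrop:
                break
        return [bq, qe, br, re]

    def raw_segments(self, read: str) -> tuple[list[AlignedSegment], str]:
        """Aligned segments in canonical orientation plus the orientation.

        The read is reverse-complemented first when the minus
        orientation carries more seed support, so downstream stages see
        one canonical orientation; cross-strand pieces (chimera
        evidence) are reported with strand '-'.
        """
        fwd = self._seeds(read)
        rc = revcomp(read)
        rev = self._seeds(rc)
        if len(rev) > len(fwd):
            canonical, orient = rc, "-"
        else:
            canonical, orient = read, "+"
        segments = []
        for c in self._cluster(canonical):
            qs, qe, rs, re = self._extend(canonical, c)
            segments.append(
                AlignedSegment(qs, qe, rs, re, "+", _identity(canonical[qs:qe], self.locus.sequence[rs:re]))
            )
        # cross-strand evidence: seeds of the rc of the canonical read
        anti = revcomp(canonical)
        L = len(canonical)
        for c in self._cluster(anti):
            qs, qe, rs, re = self._extend(anti, c)
            segments.append(
                AlignedSegment(L - qe, L - qs, rs, re, "-", _identity(anti[qs:qe], self.locus.sequence[rs:re]))
            )
        return segments, orient


# ---------------------------------------------------------------------------
# Post-processing modifications
# ---------------------------------------------------------------------------


def merge_broken(
    segments: list[AlignedSegment],
    read: str,
    locus: LocusModel,
    close_threshold: int = 30,
) -> list[AlignedSegment]:
    """Iteratively merge broken alignments until fixpoint.

    Two same-strand read-adjacent segments with read-gap d_r and
    reference-gap d_g, both within ``close_threshold``, are merged iff
    |d_r - d_g| < max(d_r, d_g)/2, or both gaps are exactly 0.
    """
    segs = sorted(segments, key=lambda s: (s.strand, s.read_start, s.ref_start))
    changed = True
    while changed:
        changed = False
        for i in range(len(segs) - 1):
            a, b = segs[i], segs[i + 1]
            if a.strand != b.strand:
                continue
            d_r = b.read_start - a.read_end
            d_g = b.ref_start - a.ref_end
            if not (0 <= d_r <= close_threshold and 0 <= d_g <= close_threshold):
                continue
            if (d_r, d_g) != (0, 0) and not abs(d_r - d_g) < max(d_r, d_g) / 2:
                continue
            merged = AlignedSegment(
                a.read_start, b.read_end, a.ref_start, b.ref_end, a.strand,
                _identity(read[a.read_start : b.read_end], locus.sequence[a.ref_start : b.ref_end]),
            )
            segs[i : i + 2] = [merged]
            changed = True
            break
    return segs


def label_segments(segments: list[AlignedSegment], locus: LocusModel) -> list[AlignedSegment]:
    """Label each segment by the gene segment(s) its reference interval
    overlaps.

    A segment extending into the intron upstream of a gene keeps the
    gene label plus an ``upstream_intron_bp`` count (measured from the
    gene start, so a J2-3 alignment covering the J2-2P pseudogene
    counts the pseudogene span as upstream intron); a segment entirely
    between genes is "intergenic" (kind I); pseudogene-only overlap is
    also treated as intergenic context.
    """
    kind_map = {"V": "V", "D": "D", "J": "J", "C": "C", "pseudo-J": "I"}
    for seg in segments:
        hits = locus.segments_overlapping(seg.ref_start, seg.ref_end)
        real = [g for g in hits if g.kind != "pseudo-J"]
        if real:
            gene = real[-1]  # most downstream, per transcript reading direction
            seg.label, seg.kind = gene.name, kind_map[gene.kind]
            seg.upstream_intron_bp = max(0, gene.start - seg.ref_start)
        elif hits:
            gene = hits[-1]
            seg.label, seg.kind = gene.name, "I"
            seg.upstream_intron_bp = max(0, gene.start - seg.ref_start)
        else:
            seg.label, seg.kind = "intergenic", "I"
            seg.upstream_intron_bp = 0
    return segments


def fix_c_order(
    segments: list[AlignedSegment], locus: LocusModel, read: str | None = None
) -> list[AlignedSegment]:
    """Relabel order-violating C1 calls as C2 (one direction only).

    The two C segments are near-identical, so a sequencing error can
    flip which C wins the alignment; when a C1 call breaks the germline
    order of the read's segments and the homologous C2 interval would
    restore it, the call is remapped to C2.
    """
    c1, c2 = locus.segment("C1"), locus.segment("C2")
    offset = c2.start - c1.start
    segs = sorted(segments, key=lambda s: s.read_start)
    for i, seg in enumerate(segs):
        if seg.label != "C1" or seg.strand != "+":
            continue
        before = [s for s in segs[:i] if s.strand == "+"]
        if not before or max(s.ref_end for s in before) <= seg.ref_start:
            continue  # ordered as-is
        new_start, new_end = seg.ref_start + offset, seg.ref_end + offset
        if new_start >= max(s.ref_end for s in before) and new_end <= len(locus.sequence):
            seg.ref_start, seg.ref_end = new_start, new_end
            seg.label = "C2"
            if read is not None:
                seg.identity = _identity(
                    read[seg.read_start : seg.read_end], locus.sequence[new_start:new_end]
                )
    return segs


def split_overlap_at_splice(
    segments: list[AlignedSegment], locus: LocusModel, read: str,
    max_overlap: int = 30,
) -> list[AlignedSegment]:
    """Split read-overlapping neighbours at a GT/AG-supported breakpoint.

    Among candidate breakpoints x (read coordinate), the upstream
    segment keeps read[..x) and the downstream keeps read[x..); a
    candidate is splice-consistent when the upstream reference context
    ends right before a GT donor and the downstream context begins
    right after an AG acceptor.  The consistent candidate maximizing
    total matched bases wins; without one the midpoint is used and the
    pair is flagged "no_splice_support".
    """
    seq = locus.sequence
    segs = sorted(segments, key=lambda s: (s.read_start, s.ref_start))
    for i in range(len(segs) - 1):
        a, b = segs[i], segs[i + 1]
        if a.strand != b.strand or a.strand != "+":
            continue
        ov_start, ov_end = b.read_start, a.read_end
        if ov_end <= ov_start:
            continue
        if ov_end - ov_start > max_overlap:
            # near-duplicate placements (e.g. the homologous C1/C2 pair)
            # are alternative alignments, not a broken junction; chain
            # selection keeps the better one
            continue
        best_x, best_m = None, -1
        for x in range(ov_start, ov_end + 1):
            a_ref_end = a.ref_end - (a.read_end - x)
            b_ref_start = b.ref_start + (x - b.read_start)
            if not (locus.has_donor(a_ref_end) and locus.has_acceptor(b_ref_start)):
                continue
            m = sum(
                read[p] == seq[a.ref_start + (p - a.read_start)] for p in range(a.read_start, x)
            ) + sum(
                read[p] == seq[b.ref_start + (p - b.read_start)] for p in range(x, b.read_end)
            )
            if m > best_m:
                best_x, best_m = x, m
        if best_x is None:
            best_x = (ov_start + ov_end) // 2
            a.flags.append("no_splice_support")
            b.flags.append("no_splice_support")
        a.ref_end -= a.read_end - best_x
        a.read_end = best_x
        b.ref_start += best_x - b.read_start
        b.read_start = best_x
    return [s for s in segs if s.read_len > 0]


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------


def _compatible(a: AlignedSegment, b: AlignedSegment, slack: int, increasing: bool) -> bool:
    """Can b follow a on an order-consistent chain (b after a in the read)?"""
    if b.read_start < a.read_end - slack:
        return False
    if increasing:
        return b.ref_start >= a.ref_end - slack and b.ref_start > a.ref_start
    return b.ref_end <= a.ref_start + slack and b.ref_start < a.ref_start


def _best_chain(
    segments: list[AlignedSegment], slack: int, increasing: bool
) -> tuple[float, list[AlignedSegment]]:
    segs = sorted(segments, key=lambda s: (s.read_start, s.ref_start))
    n = len(segs)
    best: list[tuple[float, int, int]] = [(0.0, 0, 0)] * n  # score, n_seg, -start
    prev = [-1] * n
    for i in range(n):
        key = (segs[i].score, 1, -segs[i].read_start)
        prev_i = -1
        for j in range(i):
            if _compatible(segs[j], segs[i], slack, increasing):
                cand = (best[j][0] + segs[i].score, best[j][1] + 1, best[j][2])
                if cand > key:
                    key, prev_i = cand, j
        best[i] = key
        prev[i] = prev_i
    if not segs:
        return 0.0, []
    top = max(range(n), key=lambda i: best[i])
    chain = []
    i = top
    while i >= 0:
        chain.append(segs[i])
        i = prev[i]
    chain.reverse()
    return best[top][0], chain


def build_chain(
    segments: list[AlignedSegment],
    read: str | ProcessedRead,
    locus: LocusModel,
    params: AlignParams | None = None,
    orient: str = "+",
) -> SegmentChain:
    """Select the highest-scoring strand/order-consistent chain.

    Score is identity-weighted aligned length; ties break toward more
    segments, then the leftmost chain start.  Excluded segments whose
    read span does not substantially overlap the chain (alternative
    alignments of the near-identical C1/C2 pair do, and are dropped)
    are retained as conflict evidence for chimera detection.
    """
    if not segments:
        raise ValueError("cannot build a chain from zero segments")
    params = params or AlignParams()
    if isinstance(read, ProcessedRead):
        read_id, sample_id, seq = read.read_id, read.sample_id, read.sequence
    else:
        read_id, sample_id, seq = "", "", read

    plus = [s for s in segments if s.strand == "+"]
    minus = [s for s in segments if s.strand == "-"]
    score_p, chain_p = _best_chain(plus, params.chain_slack, increasing=True)
    score_m, chain_m = _best_chain(minus, params.chain_slack, increasing=False)
    chain = chain_p if score_p >= score_m else chain_m

    conflicts = []
    for s in segments:
        if s in chain:
            continue
        ov = max(
            (
                min(s.read_end, c.read_end) - max(s.read_start, c.read_start)
                for c in chain
            ),
            default=0,
        )
        if ov < params.alt_overlap_frac * s.read_len:
            conflicts.append(s)

    pairs = [
        PairEvidence(
            b.read_start - a.read_end,
            b.ref_start - a.ref_end,
            locus.has_donor(a.ref_end),
            locus.has_acceptor(b.ref_start),
        )
        for a, b in zip(chain, chain[1:])
    ]
    return SegmentChain(read_id, sample_id, seq, orient, chain, conflicts, pairs)


# ---------------------------------------------------------------------------
# Per-read driver
# ---------------------------------------------------------------------------


def align_read(
    read: ProcessedRead, aligner: Aligner
) -> SegmentChain | None:
    """Full annotation of one processed read; None when unannotatable."""
    params = aligner.params
    segments, orient = aligner.raw_segments(read.sequence)
    canonical = read.sequence if orient == "+" else revcomp(read.sequence)
    plus = [s for s in segments if s.strand == "+"]
    minus = [s for s in segments if s.strand == "-"]
    plus = merge_broken(plus, canonical, aligner.locus, params.close_threshold)
    segments = plus + minus
    segments = [
        s
        for s in segments
        if s.read_len >= params.min_seg_len and s.identity >= params.min_identity
    ]
    if not segments:
        return None
    segments = split_overlap_at_splice(
        segments, aligner.locus, canonical, max_overlap=params.close_threshold
    )
    segments = [s for s in segments if s.read_len >= params.min_seg_len]
    if not segments:
        return None
    label_segments(segments, aligner.locus)
    segments = fix_c_order(segments, aligner.locus, canonical)
    chain = build_chain(segments, canonical, aligner.locus, params, orient)
    chain.read_id, chain.sample_id = read.read_id, read.sample_id
    label_segments(chain.segments, aligner.locus)  # refresh after C remap
    return chain


def annotate_reads(
    reads: list[ProcessedRead], locus: LocusModel, params: AlignParams | None = None
) -> tuple[list[SegmentChain], list[str]]:
    """Annotate a batch; returns chains and unannotatable read ids."""
    aligner = Aligner(locus, params)
    chains, unannotated = [], []
    for read in reads:
        chain = align_read(read, aligner)
        if chain is None:
            unannotated.append(read.read_id)
        else:
            chains.append(chain)
    return chains, unannotated
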