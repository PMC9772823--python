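"""Independent reference implementations used to cross-check the
package: brute-force chain selection by subset enumeration, a
predicate-based category oracle, and a brute-force exact rank-sum test.

These deliberately re-derive each rule from its definition rather than
calling into the package internals they check.
"""

from __future__ import annotations

import re
from itertools import combinations
from math import comb

from tcrbseq.annotate import AlignedSegment, PairEvidence, SegmentChain


# ---------------------------------------------------------------------------
# Chain selection by exhaustive subset enumeration
# ---------------------------------------------------------------------------


def _subset_is_chain(segs: list[AlignedSegment], slack: int) -> bool:
    """Strand-consistent, read/ref order-consistent subset?"""
    if len({s.strand for s in segs}) > 1:
        return False
    increasing = segs[0].strand == "+"
    ordered = sorted(segs, key=lambda s: (s.read_start, s.ref_start))
    for a, b in zip(ordered, ordered[1:]):
        if b.read_start < a.read_end - slack:
            return False
        if increasing:
            if not (b.ref_start >= a.ref_end - slack and b.ref_start > a.ref_start):
                return False
        else:
            if not (b.ref_end <= a.ref_start + slack and b.ref_start < a.ref_start):
                return False
    return True


def best_chain_bruteforce(
    segments: list[AlignedSegment], slack: int = 5
) -> tuple[float, int, int]:
    """(score, n_segments, -chain_start) of the best chain over all
    non-empty subsets; the key the DP must reproduce."""
    best = None
    for r in range(1, len(segments) + 1):
        for subset in combinations(segments, r):
            segs = list(subset)
            if not _subset_is_chain(segs, slack):
                continue
            ordered = sorted(segs, key=lambda s: (s.read_start, s.ref_start))
            key = (
                sum(s.score for s in segs),
                len(segs),
                -ordered[0].read_start,
            )
            if best is None or key > best:
                best = key
    return best


# ---------------------------------------------------------------------------
# Category oracle on abstract chain templates
# ---------------------------------------------------------------------------


def classify_template(
    kinds: tuple[str, ...],
    intron: int = 0,
    head: int = 0,
    tail: int = 0,
    rss_dist: int | None = None,
    cross_conflict: bool = False,
    order_conflict: bool = False,
    intron_min: int = 15,
    tail_max: int = 60,
    c_unaligned_max: int = 120,
    rss_window: int = 30,
    rss_overshoot: int = 8,
) -> str:
    """Category of an abstract chain, testing each category's defining
    predicate independently and applying the stated precedence."""
    pattern = "".join(kinds)
    n_c = pattern.count("C")

    is_ch = cross_conflict or order_conflict or n_c >= 2
    is_cr_full = bool(re.fullmatch("VD?JC?", pattern))
    is_cr_vonly = bool(re.fullmatch("VD?", pattern)) and (tail == 0 or tail <= tail_max)
    is_pr_full = bool(re.fullmatch("DJC?", pattern)) and intron >= intron_min
    is_pr_donly = pattern == "D" and tail > 0
    is_ijc = bool(re.fullmatch("IJC?", pattern))
    is_ar = is_ijc and rss_dist is not None and -rss_overshoot <= rss_dist <= rss_window
    is_as = is_ijc or any(
        a in "VDI" and b == "C" for a, b in zip(pattern, pattern[1:])
    )
    is_nr = bool(re.fullmatch("JC?", pattern)) and intron >= intron_min
    is_ns = (
        pattern == "C" and intron >= intron_min and max(head, tail) <= c_unaligned_max
    )

    if is_ch:
        return "CH"
    if is_cr_full or is_cr_vonly:
        return "CR"
    if is_pr_full or is_pr_donly:
        return "PR"
    if is_ar:
        return "AR"
    if is_as:
        return "AS"
    if is_nr:
        return "NR"
    if is_ns:
        return "NS"
    return "UC"


def make_template_chain(
    locus,
    kinds: tuple[str, ...],
    intron: int = 0,
    head: int = 0,
    tail: int = 0,
    rss_dist: int | None = None,
    cross_conflict: bool = False,
    order_conflict: bool = False,
) -> SegmentChain:
    """Materialise an abstract template as a SegmentChain object."""
    rss_start = next(r.start for r in locus.rss_sites if r.cryptic)
    segments = []
    read_pos = head
    ref_pos = 100
    for i, kind in enumerate(kinds):
        length = 50
        if i == 0 and rss_dist is not None:
            ref_start = rss_start - rss_dist - length
        else:
            ref_start = ref_pos
        seg = AlignedSegment(
            read_pos, read_pos + length, ref_start, ref_start + length, "+",
            identity=1.0, label=kind, kind=kind,
            upstream_intron_bp=intron if i == 0 else 0,
        )
        segments.append(seg)
        read_pos += length
        ref_pos = max(ref_pos, seg.ref_end) + 60
    conflicts = []
    if cross_conflict:
        conflicts.append(
            AlignedSegment(read_pos, read_pos + 30, 4000, 4030, "-", 1.0, "V1", "V")
        )
    if order_conflict:
        conflicts.append(
            AlignedSegment(read_pos, read_pos + 30, 10, 40, "+", 1.0, "V1", "V")
        )
    read_len = read_pos + tail + (30 if conflicts else 0)
    return SegmentChain(
        "template", "S", "A" * read_len, "+", segments, conflicts,
        [PairEvidence(0, 0, True, True) for _ in range(len(segments) - 1)],
    )


# ---------------------------------------------------------------------------
# Exact rank-sum by full enumeration
# ---------------------------------------------------------------------------


def wilcoxon_bruteforce(group_a: list[float], group_b: list[float]) -> float:
    """Two-sided exact rank-sum p by enumerating every assignment of
    pooled ranks to group A (tail doubling, capped at 1)."""
    pooled = sorted(group_a + group_b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n_a = len(group_a)
    w_obs = sum(ranks[v] for v in group_a)
    all_ranks = list(range(1, len(pooled) + 1))
    sums = [sum(c) for c in combinations(all_ranks, n_a)]
    total = len(sums)
    assert total == comb(len(pooled), n_a)
    p_low = sum(s <= w_obs for s in sums) / total
    p_high = sum(s >= w_obs for s in sums) / total
    return min(1.0, 2.0 * min(p_low, p_high))
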