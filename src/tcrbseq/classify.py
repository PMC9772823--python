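"""Eight-way recombination/splicing classification of segment chains.

Categories (precedence order):

CH  chimeric — cross-strand or order-violating segments, or >=2 C calls
CR  completely recombined — ordered V-(D)-J-(C); V-(D)-only reads that
    end within V or leave an unaligned tail of <=60 bp also count but
    are excluded from clonotype statistics
PR  partially recombined — D-J-(C) with >=15 bp of intron immediately
    upstream of the D; D-only reads with an unaligned tail also count
    but are excluded from D-J statistics
AR  aberrantly recombined — intergenic-J-(C) whose intergenic segment
    ends within 30 bp of the start of a cryptic 23RSS
AS  aberrantly spliced — a C segment concatenated downstream of a V, D
    or intergenic segment (I-C, V-C, D-C), plus I-J-(C) chains that
    fail the AR distance rule; GT/AG motifs are recorded as evidence,
    not required
NR  non-recombined — J-(C) with >=15 bp of intron immediately upstream
    of the J (the germline J spliced to C)
NS  non-spliced — C only, with >=15 bp upstream intron and unaligned
    portions of <=120 bp
UC  uncertain — everything else, notably J-(C) without the >=15 bp
    intron and C-only reads with >120 bp unaligned
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .annotate import SegmentChain
from .locus import LocusModel

CATEGORY_ORDER = ("CH", "CR", "PR", "AR", "AS", "NR", "NS", "UC")


@dataclass
class Thresholds:
    intron_min: int = 15  # >= : recombination/splicing status certain
    tail_max: int = 60  # <= : V-(D)-only unaligned tail allowance
    c_unaligned_max: int = 120  # <= : NS unaligned allowance
    rss_window: int = 30  # <= : AR distance to cryptic 23RSS start
    rss_overshoot: int = 8  # alignment-end fuzz tolerated past the RSS start


@dataclass
class Evidence:
    upstream_intron_bp: int = 0
    unaligned_head_bp: int = 0
    unaligned_tail_bp: int = 0
    donor_GT: bool | None = None
    acceptor_AG: bool | None = None
    rss_distance_bp: int | None = None
    n_C_segments: int = 0
    strand_consistent: bool = True
    order_consistent: bool = True


@dataclass
class CategoryLabel:
    category: str
    subtype: str = ""
    evidence: Evidence = field(default_factory=Evidence)
    stats_eligible: bool = True


def classify_chain(
    chain: SegmentChain, locus: LocusModel, thresholds: Thresholds | None = None
) -> CategoryLabel:
    """Assign exactly one of the eight categories, with evidence."""
    th = thresholds or Thresholds()
    if not chain.segments:
        raise ValueError("empty chain")
    kinds = chain.kinds
    pattern = "".join(kinds)
    ev = Evidence(
        upstream_intron_bp=chain.segments[0].upstream_intron_bp,
        unaligned_head_bp=chain.unaligned_head,
        unaligned_tail_bp=chain.unaligned_tail,
        n_C_segments=kinds.count("C"),
    )
    cross = [c for c in chain.conflicts if c.strand != chain.segments[0].strand]
    order = [c for c in chain.conflicts if c.strand == chain.segments[0].strand]
    ev.strand_consistent = not cross
    ev.order_consistent = not order
    if chain.pairs:
        ev.donor_GT = chain.pairs[-1].donor_GT
        ev.acceptor_AG = chain.pairs[-1].acceptor_AG

    # (1) chimeric
    if cross or order or ev.n_C_segments >= 2:
        return CategoryLabel("CH", "multi-C" if ev.n_C_segments >= 2 else
                             ("cross-strand" if cross else "order-violation"), ev, False)
    # (2) completely recombined
    if re.fullmatch("VD?JC?", pattern):
        return CategoryLabel("CR", "full", ev, True)
    if re.fullmatch("VD?", pattern):
        ends_within_v = ev.unaligned_tail_bp == 0
        if ends_within_v or ev.unaligned_tail_bp <= th.tail_max:
            return CategoryLabel("CR", "V-(D)-only", ev, False)
    # (3) partially recombined
    if re.fullmatch("DJC?", pattern) and ev.upstream_intron_bp >= th.intron_min:
        return CategoryLabel("PR", "full", ev, True)
    if pattern == "D" and ev.unaligned_tail_bp > 0:
        return CategoryLabel("PR", "D-only", ev, False)
    # (4) aberrant recombination: I-J-(C) near a cryptic 23RSS.  The
    # intergenic segment must end within rss_window bp upstream of the
    # RSS start; a few bp of overshoot past it (x-drop extension fuzz)
    # are tolerated.
    if re.fullmatch("IJC?", pattern):
        pos = chain.segments[0].ref_end
        dists = [
            r.start - pos
            for r in locus.rss_sites
            if r.cryptic and r.spacer == 23
        ]
        dist = min(dists, key=abs) if dists else None
        ev.rss_distance_bp = dist
        if dist is not None and -th.rss_overshoot <= dist <= th.rss_window:
            return CategoryLabel("AR", "", ev, True)
        # (5a) falls through to aberrant splicing
        return CategoryLabel("AS", "I-J-C", ev, True)
    # (5) aberrant splicing: C directly downstream of V, D or I
    for (a, b), pair in zip(zip(chain.segments, chain.segments[1:]), chain.pairs):
        if b.kind == "C" and a.kind in ("V", "D", "I"):
            ev.donor_GT, ev.acceptor_AG = pair.donor_GT, pair.acceptor_AG
            return CategoryLabel("AS", f"{a.kind}-C", ev, True)
    # (6) non-recombined
    if re.fullmatch("JC?", pattern) and ev.upstream_intron_bp >= th.intron_min:
        return CategoryLabel("NR", "", ev, True)
    # (7) non-spliced
    if pattern == "C" and ev.upstream_intron_bp >= th.intron_min and max(
        ev.unaligned_head_bp, ev.unaligned_tail_bp
    ) <= th.c_unaligned_max:
        return CategoryLabel("NS", "", ev, True)
    # (8) uncertain
    if re.fullmatch("JC?", pattern):
        subtype = "J-no-intron"
    elif pattern == "C":
        subtype = "C-long-unaligned" if max(ev.unaligned_head_bp, ev.unaligned_tail_bp) > th.c_unaligned_max else "C-no-intron"
    else:
        subtype = "other"
    return CategoryLabel("UC", subtype, ev, False)


def classify_chains(
    chains: list[SegmentChain], locus: LocusModel, thresholds: Thresholds | None = None
) -> pd.DataFrame:
    """Label a batch of chains; tidy per-read table."""
    rows = []
    for chain in chains:
        lab = classify_chain(chain, locus, thresholds)
        rows.append(
            {
                "read_id": chain.read_id,
                "sample_id": chain.sample_id,
                "category": lab.category,
                "subtype": lab.subtype,
                "stats_eligible": lab.stats_eligible,
                "pattern": "-".join(s.label for s in chain.segments),
                "upstream_intron_bp": lab.evidence.upstream_intron_bp,
                "unaligned_head_bp": lab.evidence.unaligned_head_bp,
                "unaligned_tail_bp": lab.evidence.unaligned_tail_bp,
                "rss_distance_bp": lab.evidence.rss_distance_bp,
                "n_C_segments": lab.evidence.n_C_segments,
            }
        )
    return pd.DataFrame(rows)


def splice_evidence_summary(
    chains: list[SegmentChain],
    labels: pd.DataFrame,
    locus: LocusModel,
) -> pd.DataFrame:
    """GT/AG support per aberrant-splice configuration plus the modal
    donor position.

    For each AS subtype (I-C, V-C, D-C, I-J-C) reports the fraction of
    junctions with a GT donor immediately after the upstream segment
    and an AG acceptor immediately before the downstream segment, the
    most frequent donor coordinate, and its offset relative to the D1
    gene-segment start (negative = upstream).
    """
    as_ids = set(labels.loc[labels.category == "AS", "read_id"])
    by_subtype: dict[str, dict[str, list]] = {}
    sub_of = dict(zip(labels.read_id, labels.subtype))
    for chain in chains:
        if chain.read_id not in as_ids:
            continue
        # the spliced junction is the one into the C segment when a C is
        # present (in I-J-C the I-J join is recombination-like, not a
        # splice); otherwise the first junction
        pairs = list(zip(chain.segments, chain.segments[1:]))
        a, b = next(((x, y) for x, y in pairs if y.kind == "C"), pairs[0])
        rec = by_subtype.setdefault(
            sub_of[chain.read_id], {"gt": [], "ag": [], "donor": []}
        )
        rec["gt"].append(locus.has_donor(a.ref_end))
        rec["ag"].append(locus.has_acceptor(b.ref_start))
        rec["donor"].append(a.ref_end)
    d1_start = locus.segment("D1").start
    rows = []
    for subtype, rec in sorted(by_subtype.items()):
        modal_donor, modal_n = Counter(rec["donor"]).most_common(1)[0]
        n = len(rec["gt"])
        rows.append(
            {
                "subtype": subtype,
                "n": n,
                "donor_GT_fraction": sum(rec["gt"]) / n,
                "acceptor_AG_fraction": sum(rec["ag"]) / n,
                "modal_donor_position": modal_donor,
                "modal_donor_offset_from_D1": modal_donor - d1_start,
                "modal_donor_fraction": modal_n / n,
            }
        )
    return pd.DataFrame(rows)
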