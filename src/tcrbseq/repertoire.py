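"""Per-sample repertoire composition statistics.

Category compositions, VJ-pairing and CDR3-clonotype tables with
top-k dominance, J-gene usage per category, and the split of
non-recombined J2-3 reads into J2-2P~J2-3 (alignment extends over the
upstream pseudogene) versus J2-3_only.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .annotate import SegmentChain
from .locus import LocusModel

SIX_CATEGORIES = ("CR", "PR", "NR", "NS", "AS", "AR")


def category_composition(labels: pd.DataFrame, include_uc_ch: bool = False) -> pd.DataFrame:
    """Per-sample category fractions.

    UC and CH reads are excluded before normalising over the six
    informative categories (set ``include_uc_ch`` for the eight-way
    audit table instead).  Columns: sample_id, category, count, fraction.
    """
    if labels.empty:
        raise ValueError("no labeled reads")
    cats = list(SIX_CATEGORIES) + (["UC", "CH"] if include_uc_ch else [])
    sub = labels[labels.category.isin(cats)]
    rows = []
    for sample, grp_all in labels.groupby("sample_id"):
        grp = sub[sub.sample_id == sample]
        total = len(grp)
        if total == 0:
            warnings.warn(f"sample {sample}: no reads after UC/CH exclusion")
            continue
        counts = grp.category.value_counts()
        for cat in cats:
            n = int(counts.get(cat, 0))
            rows.append(
                {"sample_id": sample, "category": cat, "count": n, "fraction": n / total}
            )
    return pd.DataFrame(rows)


def _eligible_cr(labels: pd.DataFrame) -> set[str]:
    mask = (labels.category == "CR") & labels.stats_eligible
    return set(labels.loc[mask, "read_id"])


def _chain_vjc(chain: SegmentChain) -> dict[str, str]:
    names = {"V": "", "D": "", "J": "", "C": ""}
    for seg in chain.segments:
        if seg.kind in names and not names[seg.kind]:
            names[seg.kind] = seg.label
    return names


def clonotype_tables(
    chains: list[SegmentChain], labels: pd.DataFrame, top_k: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """VJ-pairing and CDR3-clonotype tables from eligible CR reads.

    The CDR3 is operationalised as the read subsequence between the end
    of the V alignment and the start of the J alignment; clonotypes are
    keyed (v_name, j_name, cdr3_seq).  Also returns per-sample top-k
    cumulative fractions for k = 1..``top_k``.
    """
    eligible = _eligible_cr(labels)
    rows = []
    for chain in chains:
        if chain.read_id not in eligible:
            continue
        names = _chain_vjc(chain)
        v_seg = next(s for s in chain.segments if s.kind == "V")
        j_seg = next(s for s in chain.segments if s.kind == "J")
        cdr3 = chain.read_seq[v_seg.read_end : j_seg.read_start]
        rows.append(
            {
                "sample_id": chain.sample_id,
                "v_name": names["V"],
                "j_name": names["J"],
                "cdr3_seq": cdr3,
            }
        )
    if not rows:
        empty = pd.DataFrame()
        return empty, empty, empty
    df = pd.DataFrame(rows)

    def counted(keys: list[str]) -> pd.DataFrame:
        out = df.groupby(["sample_id"] + keys).size().rename("count").reset_index()
        out["fraction"] = out["count"] / out.groupby("sample_id")["count"].transform("sum")
        return out.sort_values(["sample_id", "count"], ascending=[True, False]).reset_index(drop=True)

    vj = counted(["v_name", "j_name"])
    cdr3 = counted(["v_name", "j_name", "cdr3_seq"])
    top_rows = []
    for sample, grp in cdr3.groupby("sample_id"):
        fr = grp.fraction.to_numpy()
        vj_fr = vj.loc[vj.sample_id == sample, "fraction"].to_numpy()
        for k in range(1, top_k + 1):
            top_rows.append(
                {
                    "sample_id": sample,
                    "k": k,
                    "top_cdr3_fraction": float(fr[:k].sum()),
                    "top_vj_fraction": float(vj_fr[:k].sum()),
                }
            )
    return vj, cdr3, pd.DataFrame(top_rows)


def j_usage(
    chains: list[SegmentChain], labels: pd.DataFrame, category: str
) -> pd.DataFrame:
    """Per-sample J-gene usage fractions within one of CR/PR/NR."""
    if category not in ("CR", "PR", "NR"):
        raise ValueError("j_usage is defined for CR, PR and NR")
    wanted = set(
        labels.loc[(labels.category == category) & labels.stats_eligible, "read_id"]
    )
    rows = []
    for chain in chains:
        if chain.read_id not in wanted:
            continue
        j = next((s.label for s in chain.segments if s.kind == "J"), None)
        if j is not None:
            rows.append({"sample_id": chain.sample_id, "j_name": j})
    if not rows:
        return pd.DataFrame(columns=["sample_id", "j_name", "count", "fraction"])
    df = pd.DataFrame(rows)
    out = df.groupby(["sample_id", "j_name"]).size().rename("count").reset_index()
    out["fraction"] = out["count"] / out.groupby("sample_id")["count"].transform("sum")
    return out


def nr_subtype_split(
    chains: list[SegmentChain],
    labels: pd.DataFrame,
    locus: LocusModel,
    j22p_min_overlap: int = 1,
) -> pd.DataFrame:
    """Split NR reads into J2-2P~J2-3, J2-3_only, and other-J.

    An NR read whose J segment is the J immediately downstream of the
    J2-2P pseudogene is J2-2P~J2-3 when its alignment (including the
    upstream-intron extension) covers at least ``j22p_min_overlap`` bp
    of the annotated J2-2P interval, else J2-3_only; NR reads on other
    J genes are binned separately.
    """
    j22p = locus.segment("J2-2P")
    target_j = min(
        (s for s in locus.segments_of_kind("J") if s.start >= j22p.end),
        key=lambda s: s.start,
    )
    nr_ids = set(labels.loc[labels.category == "NR", "read_id"])
    rows = []
    for chain in chains:
        if chain.read_id not in nr_ids:
            continue
        j_seg = next((s for s in chain.segments if s.kind == "J"), None)
        if j_seg is None:
            continue
        if j_seg.label != target_j.name:
            bin_ = "other-J"
        else:
            overlap = min(j_seg.ref_end, j22p.end) - max(j_seg.ref_start, j22p.start)
            bin_ = "J2-2P~J2-3" if overlap >= j22p_min_overlap else "J2-3_only"
        rows.append({"sample_id": chain.sample_id, "bin": bin_})
    if not rows:
        return pd.DataFrame(columns=["sample_id", "bin", "count", "fraction"])
    df = pd.DataFrame(rows)
    out = df.groupby(["sample_id", "bin"]).size().rename("count").reset_index()
    out["fraction"] = out["count"] / out.groupby("sample_id")["count"].transform("sum")
    return out
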