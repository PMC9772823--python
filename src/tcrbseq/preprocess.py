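"""De-multiplexing and technical-sequence trimming of pooled reads.

The raw read layout is 5'adapter + 10 bp barcode + universal primer,
then the insert, then the reverse-complemented 10 bp barcode + 3'
adapter.  Technical sequences are located by tolerant local (infix)
alignment, the barcode at each end is called against the sample map,
reads with inconsistent end barcodes are discarded, and trimmed reads
shorter than 150 bp are dropped so that intronic context in
non-recombined transcripts remains detectable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .simulate import ADAPTER1, ADAPTER2, UPM, BARCODE_LEN, revcomp

MIN_LEN_DEFAULT = 150


@dataclass
class EndHit:
    """Best technical-sequence hit at one read end."""

    barcode_sample: str | None  # sample_id of best barcode, or None
    barcode_matches: int  # matched bases out of BARCODE_LEN
    tech_span: tuple[int, int] | None  # interval of the read to trim away


@dataclass
class ProcessedRead:
    read_id: str
    sample_id: str
    sequence: str
    trim_coords: tuple[int, int]


@dataclass
class DiscardRecord:
    read_id: str
    reason: str  # inconsistent_barcodes | no_barcode | too_short | no_insert


def _best_infix(query: str, target: str, max_ed: int) -> tuple[int, int, int] | None:
    """Best infix alignment of query in target: (start, end, edit_distance)."""
    res = edlib.align(query, target, mode="HW", task="locations", k=max_ed)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    return start, end + 1, res["editDistance"]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b)) + abs(len(a) - len(b))


def find_technical(
    read: str,
    barcode_map: dict[str, str],
    identity_floor: float = 0.9,
    min_barcode_matches: int = 8,
) -> tuple[EndHit, EndHit]:
    """Locate the 5' and 3' technical spans and call the end barcodes.

    The anchors (adapter+UPM at the 5' end, the 3' adapter) are found by
    tolerant infix alignment; hits below ``identity_floor`` are ignored.
    A barcode is called when >= ``min_barcode_matches`` of its 10 bases
    match the read in the slot between anchor hits.
    """
    if not barcode_map:
        raise ValueError("barcode map is empty")

    def call_barcode(observed: str) -> tuple[str | None, int]:
        best, best_m = None, -1
        for sample, bc in barcode_map.items():
            m = BARCODE_LEN - _hamming(observed, bc)
            if m > best_m:
                best, best_m = sample, m
        if best_m >= min_barcode_matches:
            return best, best_m
        return None, max(best_m, 0)

    # 5' end: adapter1 ... barcode ... UPM
    head = read[: len(ADAPTER1) + BARCODE_LEN + len(UPM) + 30]
    max_ed1 = int(len(ADAPTER1) * (1 - identity_floor))
    max_edu = int(len(UPM) * (1 - identity_floor))
    a1 = _best_infix(ADAPTER1, head, max_ed1)
    upm = _best_infix(UPM, head, max_edu)
    if upm is not None and (a1 is None or a1[1] <= upm[0]):
        bc_obs = head[upm[0] - BARCODE_LEN : upm[0]] if a1 is None else head[a1[1] : upm[0]]
        sample, m = call_barcode(bc_obs)
        five = EndHit(sample, m, (0, upm[1]))
    elif a1 is not None:
        bc_obs = head[a1[1] : a1[1] + BARCODE_LEN]
        sample, m = call_barcode(bc_obs)
        five = EndHit(sample, m, (0, min(len(read), a1[1] + BARCODE_LEN + len(UPM))))
    else:
        five = EndHit(None, 0, None)

    # 3' end: rc(barcode) ... rc(adapter2)
    tail_len = len(ADAPTER2) + BARCODE_LEN + 30
    tail = read[-tail_len:] if len(read) > tail_len else read
    offset = len(read) - len(tail)
    max_ed2 = int(len(ADAPTER2) * (1 - identity_floor))
    a2 = _best_infix(revcomp(ADAPTER2), tail, max_ed2)
    if a2 is not None:
        bc_start = offset + a2[0] - BARCODE_LEN
        bc_obs = revcomp(read[max(0, bc_start) : offset + a2[0]])
        sample, m = call_barcode(bc_obs)
        three = EndHit(sample, m, (max(0, bc_start), len(read)))
    else:
        three = EndHit(None, 0, None)
    return five, three


def trim_and_filter(
    read_id: str,
    read: str,
    sample_id: str,
    five: EndHit,
    three: EndHit,
    min_len: int = MIN_LEN_DEFAULT,
) -> ProcessedRead | DiscardRecord:
    """Keep the interior between the innermost technical spans; drop
    short (< ``min_len``) or insert-free reads."""
    start = five.tech_span[1] if five.tech_span else 0
    end = three.tech_span[0] if three.tech_span else len(read)
    if end <= start:
        return DiscardRecord(read_id, "no_insert")
    insert = read[start:end]
    if len(insert) < min_len:
        return DiscardRecord(read_id, "too_short")
    return ProcessedRead(read_id, sample_id, insert, (start, end))


def demultiplex(
    reads: list[tuple[str, str]],
    barcode_map: dict[str, str],
    min_len: int = MIN_LEN_DEFAULT,
    require_both_ends: bool = False,
    identity_floor: float = 0.9,
) -> tuple[list[ProcessedRead], list[DiscardRecord]]:
    """Assign pooled reads to samples, trim, and length-filter.

    A read is assigned when the barcodes called at the two ends agree;
    reads with only one detectable barcode are assigned to that sample
    unless ``require_both_ends``.  Reads with conflicting end barcodes
    are discarded ("inconsistent_barcodes"), reads with none
    ("no_barcode").  ``assigned + discarded == input`` always holds.
    """
    values = list(barcode_map.values())
    if len(set(values)) != len(values):
        raise ValueError("barcode map must be injective")
    kept: list[ProcessedRead] = []
    dropped: list[DiscardRecord] = []
    for read_id, seq in reads:
        five, three = find_technical(seq, barcode_map, identity_floor=identity_floor)
        s5, s3 = five.barcode_sample, three.barcode_sample
        if s5 is not None and s3 is not None:
            if s5 != s3:
                dropped.append(DiscardRecord(read_id, "inconsistent_barcodes"))
                continue
            sample = s5
        elif s5 is None and s3 is None:
            dropped.append(DiscardRecord(read_id, "no_barcode"))
            continue
        elif require_both_ends:
            dropped.append(DiscardRecord(read_id, "single_end_barcode"))
            continue
        else:
            sample = s5 if s5 is not None else s3
        result = trim_and_filter(read_id, seq, sample, five, three, min_len=min_len)
        if isinstance(result, DiscardRecord):
            dropped.append(result)
        else:
            kept.append(result)
    return kept, dropped
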