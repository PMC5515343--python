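"""Copy-number evidence of tumor in adjacent-normal tissue.

An adjacent segment counts as shared with the tumor when the two
segments reciprocally overlap by at least 50% of each segment's length,
both exceed the |log2| > 0.1 amplitude filter, and carry the same sign
of change. Any overlap with an amplitude-passing blood segment (a
germline CNV) vetoes the candidate. Summed shared basepairs are tiered:
>100 kb shared -> evidence of tumor (triplets) or likely evidence
(tumor/adjacent pairs without blood); 1,000-99,999 bp -> small evidence;
below -> normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from fieldscape.io_formats import FieldscapeValidationError, SegRecord

logger = logging.getLogger(__name__)

EVIDENCE_BP = 100_000
SMALL_EVIDENCE_BP = 1_000


@dataclass(frozen=True)
class SegmentMatch:
    adjacent: SegRecord
    tumor: SegRecord
    overlap_bp: int


@dataclass(frozen=True)
class CnCall:
    sample_id: str
    shared_bp: int
    n_matched_segments: int
    mode: str  # triplet | pair
    category: str  # evidence_of_tumor | small_evidence | likely_evidence | normal


def reciprocal_overlap(a: SegRecord, b: SegRecord) -> tuple[int, float, float]:
    """Overlap in bp and the fraction of each segment covered by it.

    Different chromosomes give (0, 0.0, 0.0); half-open arithmetic.
    """
    if a.chrom != b.chrom:
        return 0, 0.0, 0.0
    overlap = max(0, min(a.end, b.end) - max(a.start, b.start))
    return overlap, overlap / a.length, overlap / b.length


def match_adjacent_to_tumor(
    adjacent: Sequence[SegRecord],
    tumor: Sequence[SegRecord],
    blood: Sequence[SegRecord] | None = None,
    min_ro: float = 0.5,
    min_abs_log2: float = 0.1,
    require_sign_concordance: bool = True,
) -> list[SegmentMatch]:
    """One-to-one matching of adjacent segments to tumor segments.

    Each amplitude-passing adjacent segment takes at most one tumor
    partner: the one with the largest overlap (ties: longer tumor
    segment, then leftmost). A >= 1 bp overlap with any amplitude-passing
    blood segment vetoes the candidate.
    """
    tumor_ok = [t for t in tumor if abs(t.seg_mean) > min_abs_log2]
    blood_ok = [b for b in (blood or []) if abs(b.seg_mean) > min_abs_log2]
    matches: list[SegmentMatch] = []
    for adj in adjacent:
        if abs(adj.seg_mean) <= min_abs_log2:
            continue
        if any(reciprocal_overlap(adj, b)[0] >= 1 for b in blood_ok):
            continue
        best: tuple | None = None
        for tum in tumor_ok:
            if require_sign_concordance and adj.seg_mean * tum.seg_mean <= 0:
                continue
            ov, fa, fb = reciprocal_overlap(adj, tum)
            if fa >= min_ro and fb >= min_ro:
                key = (-ov, -tum.length, tum.chrom, tum.start)
                if best is None or key < best[0]:
                    best = (key, tum, ov)
        if best is not None:
            matches.append(SegmentMatch(adjacent=adj, tumor=best[1], overlap_bp=best[2]))
    return matches


def classify_cn(
    matches: Sequence[SegmentMatch],
    mode: str,
    sample_id: str = "",
    blood_provided: bool | None = None,
    evidence_bp: int = EVIDENCE_BP,
    small_evidence_bp: int = SMALL_EVIDENCE_BP,
) -> CnCall:
    """Tier summed shared basepairs; pairs (no blood) can only reach 'likely'."""
    if mode not in ("triplet", "pair"):
        raise FieldscapeValidationError(f"unknown mode {mode!r}")
    if mode == "pair" and blood_provided:
        raise FieldscapeValidationError("pair mode with a blood profile supplied")
    shared_bp = int(sum(m.overlap_bp for m in matches))
    if shared_bp == evidence_bp:
        logger.info(
            "%s: shared_bp exactly %d sits on the tier boundary; assigned to the "
            "evidence tier", sample_id, evidence_bp,
        )
    if mode == "triplet":
        if shared_bp >= evidence_bp:
            category = "evidence_of_tumor"
        elif shared_bp >= small_evidence_bp:
            category = "small_evidence"
        else:
            category = "normal"
    else:
        category = "likely_evidence" if shared_bp >= evidence_bp else "normal"
    return CnCall(
        sample_id=sample_id,
        shared_bp=shared_bp,
        n_matched_segments=len(matches),
        mode=mode,
        category=category,
    )


def call_sample(
    adjacent: Sequence[SegRecord],
    tumor: Sequence[SegRecord],
    blood: Sequence[SegRecord] | None = None,
    sample_id: str = "",
    min_ro: float = 0.5,
    min_abs_log2: float = 0.1,
) -> tuple[CnCall, list[SegmentMatch]]:
    """Match then tier one sample; mode follows blood availability."""
    mode = "triplet" if blood is not None else "pair"
    matches = match_adjacent_to_tumor(adjacent, tumor, blood, min_ro, min_abs_log2)
    call = classify_cn(matches, mode, sample_id=sample_id)
    return call, matches
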