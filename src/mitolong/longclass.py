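"""Selection and classification of long mitochondrial reads.

A read is "long" when its alignments jointly cover more than 8000 bp of the
circular reference and more than 80% of the read aligns (both strictly).
Selected reads are categorised by the ratio of read length to the longest
single alignment: values near 1 are ordinary reads, larger values flag reads
whose alignment is fragmented — either multi-revolution rolling-circle reads
(the read wraps past one full turn of the circle) or "2D-like" chimeras that
contain the same segment twice, usually in opposite orientations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .circref import (
    CircularReference,
    FoldedAlignment,
    LinearAlignment,
    fold_alignment,
    fold_read_alignments,
    segment_coverage,
)

MIN_REF_SPAN = 8000
MIN_ALIGNED_FRACTION = 0.80
RATIO_LOW = 1.1
RATIO_HIGH = 1.2


@dataclass
class LongReadClass:
    read_id: str
    read_length: int
    longest_alignment_length: int
    ratio: float
    category: str  # normal | middle | high
    multirev: bool
    twod_like: bool
    double_covered_bp: int


def select_long_reads(
    folded_by_read: Mapping[str, FoldedAlignment],
    min_ref_span: int = MIN_REF_SPAN,
    min_aligned_fraction: float = MIN_ALIGNED_FRACTION,
) -> dict[str, FoldedAlignment]:
    """Reads covering > min_ref_span distinct bases with > min_aligned_fraction
    of the read aligned (both strict, over the union of the read's alignments)."""
    if min_ref_span < 0 or not 0.0 <= min_aligned_fraction <= 1.0:
        raise ValueError("threshold outside valid range")
    return {
        rid: f for rid, f in folded_by_read.items()
        if f.distinct_ref_span > min_ref_span
        and f.aligned_read_fraction > min_aligned_fraction
    }


def classify_ratio(
    read_length: int,
    longest_alignment_length: int,
    low: float = RATIO_LOW,
    high: float = RATIO_HIGH,
    boundaries_middle: bool = True,
) -> str:
    """Categorise the read-length / longest-alignment-length ratio.

    < low -> "normal"; between low and high (inclusive by default) ->
    "middle"; > high -> "high".
    """
    if longest_alignment_length < 1:
        raise ValueError("zero alignment length")
    ratio = read_length / longest_alignment_length
    if boundaries_middle:
        if ratio < low:
            return "normal"
        if ratio <= high:
            return "middle"
        return "high"
    if ratio <= low:
        return "normal"
    if ratio < high:
        return "middle"
    return "high"


def detect_multirev(folded: FoldedAlignment, L: int) -> tuple[bool, int]:
    """Multi-revolution flag: some circular position covered >= 2 times.

    Returns the flag and the count of double-covered bases (835 bp for the
    archetypal 17,501 nt read on a 16,666 bp circle).
    """
    cov = segment_coverage(folded.segments, L)
    double = int(np.count_nonzero(cov >= 2))
    return double > 0, double


def _circ_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    # folded segments never wrap individually, so linear overlap suffices
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def detect_2d_like(
    alns: Sequence[LinearAlignment],
    ref: CircularReference,
    min_reciprocal_overlap: float = 0.5,
    allow_same_strand: bool = True,
) -> tuple[bool, int | None]:
    """2D-like chimera: two alignments of one read covering the same circular
    segment, on opposite strands (or the same strand for tandem-duplicate
    compounds).

    The overlap is scored against the *shorter* of the two segments: the
    second sequencing pass of a 2D-like molecule is usually truncated, so the
    signature is that the smaller segment lies mostly (>=
    ``min_reciprocal_overlap`` of its span) inside the larger one.  Returns
    the flag and an estimated junction read coordinate (midpoint between the
    two query intervals) when query coordinates are available.
    """
    if len(alns) < 2:
        return False, None
    folded = [fold_alignment(a, ref) for a in alns]
    spans = [f.distinct_ref_span for f in folded]
    for i in range(len(alns)):
        for j in range(i + 1, len(alns)):
            same_strand = alns[i].strand == alns[j].strand
            if same_strand and not allow_same_strand:
                continue
            overlap = sum(
                _circ_overlap(si[:2], sj[:2])
                for si in folded[i].segments for sj in folded[j].segments
            )
            if min(spans[i], spans[j]) == 0:
                continue
            if overlap / min(spans[i], spans[j]) >= min_reciprocal_overlap:
                junction = None
                qi, qj = alns[i], alns[j]
                if None not in (qi.query_start, qi.query_end, qj.query_start, qj.query_end):
                    first, second = sorted([qi, qj], key=lambda a: a.query_start)
                    junction = (first.query_end + second.query_start) // 2
                return True, junction
    return False, None


def classify_reads(
    alns_by_read: Mapping[str, Sequence[LinearAlignment]],
    ref: CircularReference,
    min_ref_span: int = MIN_REF_SPAN,
    min_aligned_fraction: float = MIN_ALIGNED_FRACTION,
) -> list[LongReadClass]:
    """Full long-read classification for all selected reads."""
    folded_by_read = {
        rid: fold_read_alignments(list(group), ref)
        for rid, group in alns_by_read.items()
    }
    selected = select_long_reads(folded_by_read, min_ref_span, min_aligned_fraction)
    out = []
    for rid in sorted(selected):
        folded = selected[rid]
        group = alns_by_read[rid]
        longest = max(a.ref_end - a.ref_start for a in group)
        multirev, double = detect_multirev(folded, ref.length)
        twod, _junction = detect_2d_like(group, ref)
        out.append(LongReadClass(
            read_id=rid,
            read_length=folded.read_length,
            longest_alignment_length=longest,
            ratio=folded.read_length / longest,
            category=classify_ratio(folded.read_length, longest),
            multirev=multirev,
            twod_like=twod,
            double_covered_bp=double,
        ))
    return out


def classification_table(classes: Sequence[LongReadClass]) -> pd.DataFrame:
    """Per-read table (also serves as the scatter-plot data: read length vs
    longest alignment length, coloured by category)."""
    return pd.DataFrame([vars(c) for c in classes])
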