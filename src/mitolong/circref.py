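"""Circular reference handling: pseudo-circularization and coordinate folding.

Linear aligners cannot map a read across the origin of a circular genome, so
the standard trick is to align against the reference concatenated with itself
("pseudo-circularized") and fold the resulting linear coordinates back onto
the circle by taking positions mod L.  This module owns that arithmetic:

* :class:`CircularReference` — the circle and its doubled linear form;
* :func:`fold_alignment` — map a doubled-reference interval to circular
  segments, splitting at the origin and tracking multiplicity for reads that
  span more than one full revolution;
* :func:`wrap_overlap` — bases of the circle covered twice by one alignment
  (the rolling-circle signature);
* PAF / SAM readers producing :class:`LinearAlignment` records.

Internal coordinates are 0-based half-open; all file I/O (VCF, coverage
tables) is 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_SEQ = re.compile(r"^[ACGTN]+$")

CigarOps = list[tuple[str, int]]


@dataclass(frozen=True)
class CircularReference:
    """A circular nucleotide sequence of length L."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def doubled_sequence(self) -> str:
        """The head-to-tail self-concatenation used for linear alignment."""
        return self.sequence + self.sequence

    @property
    def doubled_id(self) -> str:
        return self.id + "_dup"


def pseudo_circularize(sequence: str, ref_id: str = "ref") -> CircularReference:
    """Build a :class:`CircularReference`, validating the alphabet.

    Raises ``ValueError("empty reference")`` on an empty sequence and
    ``ValueError("invalid alphabet")`` on non-ACGTN characters.
    """
    if not sequence:
        raise ValueError("empty reference")
    sequence = sequence.upper()
    if not _VALID_SEQ.match(sequence):
        raise ValueError("invalid alphabet")
    return CircularReference(id=ref_id, sequence=sequence)


@dataclass
class LinearAlignment:
    """One alignment record on the doubled (2L) reference.

    ``ref_start``/``ref_end`` are 0-based half-open on [0, 2L].  Query
    coordinates follow the PAF convention: always on the original read, with
    the cigar describing revcomp(read[query_start:query_end]) for '-' strand.
    """

    read_id: str
    read_length: int
    ref_start: int
    ref_end: int
    strand: str
    read_aligned_bases: int
    query_start: int | None = None
    query_end: int | None = None
    cigar: CigarOps | None = None
    mapq: int | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if not 0 <= self.ref_start < self.ref_end:
            raise ValueError("invalid alignment interval")
        if self.read_aligned_bases > self.read_length:
            raise ValueError("aligned bases exceed read length")


@dataclass
class FoldedAlignment:
    """A read's alignment(s) expressed on circular coordinates.

    ``segments`` are (circ_start, circ_end, strand) 0-based half-open on
    [0, L); ``ref_span`` counts reference bases with multiplicity while
    ``distinct_ref_span`` counts circular positions covered at least once.
    """

    read_id: str
    read_length: int
    segments: list[tuple[int, int, str]] = field(default_factory=list)
    ref_span: int = 0
    distinct_ref_span: int = 0
    aligned_read_fraction: float = 0.0


def _split_interval(start: int, end: int, L: int, strand: str) -> list[tuple[int, int, str]]:
    """Split a doubled-reference interval at multiples of L and fold mod L."""
    segments = []
    cur = start
    while cur < end:
        seg_end = min(end, (cur // L + 1) * L)
        segments.append((cur % L, (seg_end - 1) % L + 1, strand))
        cur = seg_end
    return segments


def segment_coverage(segments: Iterable[tuple[int, int, str]], L: int) -> np.ndarray:
    """Per-position multiplicity of circular coverage by the given segments."""
    delta = np.zeros(L + 1, dtype=np.int64)
    for s, e, _strand in segments:
        if not 0 <= s < e <= L:
            raise ValueError(f"segment ({s}, {e}) outside circle of length {L}")
        delta[s] += 1
        delta[e] -= 1
    return np.cumsum(delta[:L])


def fold_alignment(aln: LinearAlignment, ref: CircularReference) -> FoldedAlignment:
    """Fold one doubled-reference alignment onto the circle.

    Starts at or beyond L are normalized by subtracting L (the doubled
    reference makes them ambiguous mod L).  An interval crossing position L
    is split into two circular segments; an interval longer than L produces
    segments covering part of the circle twice.
    """
    L = ref.length
    start, end = aln.ref_start, aln.ref_end
    if not (0 <= start < end <= 2 * L):
        raise ValueError("coordinate out of doubled reference")
    if start >= L:
        start -= L
        end -= L
    segments = _split_interval(start, end, L, aln.strand)
    ref_span = end - start
    cov = segment_coverage(segments, L)
    return FoldedAlignment(
        read_id=aln.read_id,
        read_length=aln.read_length,
        segments=segments,
        ref_span=ref_span,
        distinct_ref_span=int(np.count_nonzero(cov)),
        aligned_read_fraction=aln.read_aligned_bases / aln.read_length,
    )


def fold_read_alignments(alns: Sequence[LinearAlignment], ref: CircularReference) -> FoldedAlignment:
    """Fold and combine all alignments of one read (primary + supplementary).

    The aligned read fraction uses the union of query intervals when every
    record carries them, otherwise the capped sum of per-record aligned bases.
    """
    if not alns:
        raise ValueError("no alignments for read")
    read_id = alns[0].read_id
    read_length = alns[0].read_length
    segments: list[tuple[int, int, str]] = []
    ref_span = 0
    for aln in alns:
        if aln.read_id != read_id:
            raise ValueError("alignments from different reads")
        folded = fold_alignment(aln, ref)
        segments.extend(folded.segments)
        ref_span += folded.ref_span
    cov = segment_coverage(segments, ref.length)
    if all(a.query_start is not None and a.query_end is not None for a in alns):
        aligned = _union_length([(a.query_start, a.query_end) for a in alns])
    else:
        aligned = min(read_length, sum(a.read_aligned_bases for a in alns))
    return FoldedAlignment(
        read_id=read_id,
        read_length=read_length,
        segments=segments,
        ref_span=ref_span,
        distinct_ref_span=int(np.count_nonzero(cov)),
        aligned_read_fraction=aligned / read_length,
    )


def _union_length(intervals: Sequence[tuple[int, int]]) -> int:
    total = 0
    last_end = None
    for s, e in sorted(intervals):
        if last_end is None or s >= last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


def wrap_overlap(folded: FoldedAlignment, ref: CircularReference) -> int:
    """Circular bases covered at least twice by the read's folded segments.

    For a single contiguous doubled-reference interval this equals
    max(0, ref_span - L): the rolling-circle "second revolution" overlap.
    """
    cov = segment_coverage(folded.segments, ref.length)
    return int(np.count_nonzero(cov >= 2))


def group_by_read(alns: Iterable[LinearAlignment]) -> dict[str, list[LinearAlignment]]:
    groups: dict[str, list[LinearAlignment]] = {}
    for aln in alns:
        groups.setdefault(aln.read_id, []).append(aln)
    return groups


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    seq_records = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    SeqIO.write(seq_records, str(path), "fasta")


def write_doubled_fasta(ref: CircularReference, path) -> None:
    """Write the pseudo-circularized reference with a suffix-tagged id."""
    write_fasta([(ref.doubled_id, ref.doubled_sequence)], path)


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_cigar(cigar: str) -> CigarOps:
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if not ops:
        raise ValueError(f"unparseable cigar {cigar!r}")
    return ops


def cigar_to_string(ops: CigarOps) -> str:
    return "".join(f"{n}{op}" for op, n in ops)


def parse_paf(path) -> list[LinearAlignment]:
    """Read minimap2-style PAF (12 mandatory columns, optional cg:Z tag)."""
    alns = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ValueError(f"PAF line with {len(fields)} < 12 columns")
            cigar = None
            for tag in fields[12:]:
                if tag.startswith("cg:Z:"):
                    cigar = parse_cigar(tag[5:])
            alns.append(LinearAlignment(
                read_id=fields[0],
                read_length=int(fields[1]),
                query_start=int(fields[2]),
                query_end=int(fields[3]),
                strand=fields[4],
                ref_start=int(fields[7]),
                ref_end=int(fields[8]),
                read_aligned_bases=int(fields[3]) - int(fields[2]),
                cigar=cigar,
                mapq=int(fields[11]),
            ))
    return alns


def write_paf(alns: Iterable[LinearAlignment], ref_name: str, ref_length: int, path) -> None:
    with open(path, "w") as fh:
        for a in alns:
            n_match = a.read_aligned_bases
            block = a.ref_end - a.ref_start
            if a.cigar is not None:
                n_match = sum(n for op, n in a.cigar if op in "M=X")
                block = sum(n for op, n in a.cigar if op in "MID=X")
            fields = [
                a.read_id, a.read_length, a.query_start or 0,
                a.query_end if a.query_end is not None else a.read_aligned_bases,
                a.strand, ref_name, ref_length, a.ref_start, a.ref_end,
                n_match, block, a.mapq if a.mapq is not None else 60,
            ]
            line = "\t".join(str(f) for f in fields)
            if a.cigar is not None:
                line += "\tcg:Z:" + cigar_to_string(a.cigar)
            fh.write(line + "\n")


def parse_sam(path) -> list[LinearAlignment]:
    """Read single-end SAM alignments (pysam); unmapped records are skipped."""
    import pysam

    alns = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            read_length = rec.infer_read_length() or rec.query_length
            qstart, qend = rec.query_alignment_start, rec.query_alignment_end
            if rec.is_reverse:
                # convert to original-read coordinates (PAF convention)
                qstart, qend = read_length - qend, read_length - qstart
            alns.append(LinearAlignment(
                read_id=rec.query_name,
                read_length=read_length,
                ref_start=rec.reference_start,
                ref_end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                read_aligned_bases=rec.query_alignment_length,
                query_start=qstart,
                query_end=qend,
                cigar=[("MIDNSHP=XB"[op], n) for op, n in (rec.cigartuples or [])] or None,
                mapq=rec.mapping_quality,
            ))
    return alns
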