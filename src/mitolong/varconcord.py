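"""Naive pileup SNP calling and strict multi-library variant concordance.

The caller is a deliberately simple binomial pileup for synthetic data: at
each circular position, bases from covering reads are counted via the truth
(or supplied) cigars, a SNP is called when the majority non-reference base
reaches an alt fraction of >= 0.5, and site quality is the Phred-scaled
binomial surprise of the alt count under the per-base error rate.  Real-world
users supply VCFs from a production caller instead.

Concordance uses the strict multi-library rule: for a given individual
sequenced across several libraries, a true variant counts as a true positive
only when it is called (at or above the quality cutoff) in *every* library;
missing it in even one library makes it a false negative, and any called
variant absent from the truth is a false positive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_away, seq_to_codes
from .circref import CircularReference, LinearAlignment
from .readqc import ReadRecord

DEFAULT_SITE_QUALITY = 15.0
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

VariantKey = tuple[int, str, str]  # (1-based position, ref, alt)


@dataclass(frozen=True)
class VariantCall:
    position: int  # 1-based circular coordinate
    ref_allele: str
    alt_allele: str
    quality: float
    horse: str = ""
    library: str = ""
    reference_used: str = ""

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles are identical")

    @property
    def key(self) -> VariantKey:
        return (self.position, self.ref_allele, self.alt_allele)


@dataclass
class ConcordanceCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            warnings.warn("precision undefined: no positive calls")
            return float("nan")
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        if self.tp + self.fn == 0:
            warnings.warn("recall undefined: empty truth set")
            return float("nan")
        return self.tp / (self.tp + self.fn)

    @property
    def f1(self) -> float:
        return f1_score(self.precision, self.recall)


def f1_score(p: float, r: float, ndigits: int = 3) -> float:
    """Harmonic mean of precision and recall, rounded for reporting.

    F1 = 2 * p * r / (p + r); defined as 0 (with a warning) when p = r = 0.
    """
    if not (0.0 <= p <= 1.0 and 0.0 <= r <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if p == 0.0 and r == 0.0:
        warnings.warn("F1 undefined for p = r = 0; reporting 0")
        return 0.0
    return round_half_away(2.0 * p * r / (p + r), ndigits)


# ---------------------------------------------------------------------------
# pileup calling
# ---------------------------------------------------------------------------

def _site_quality(alt_count: int, depth: int, error_rate: float) -> float:
    """Phred-scaled binomial surprise of the alt count under the error model."""
    if alt_count == 0:
        return 0.0
    # P(X >= alt_count), X ~ Binom(depth, error_rate); log survival for range
    logp = stats.binom.logsf(alt_count - 1, depth, min(max(error_rate, 1e-12), 1.0))
    return float(min(10_000.0, -10.0 * logp / math.log(10.0)))


def pileup_call(
    alignments: Sequence[LinearAlignment],
    reads_by_id: Mapping[str, ReadRecord],
    ref: CircularReference,
    error_rate: float = 0.1,
    min_alt_fraction: float = 0.5,
    min_site_quality: float = DEFAULT_SITE_QUALITY,
    horse: str = "",
    library: str = "",
) -> list[VariantCall]:
    """Call SNPs from cigar-bearing alignments on the doubled reference.

    Reference positions are folded mod L, so both copies of the doubled
    reference (and both revolutions of a wrapped read) pile onto one circular
    coordinate.  Only substitutions are considered; alignments lacking cigars
    or reads missing from ``reads_by_id`` are skipped.
    """
    L = ref.length
    ref_codes = seq_to_codes(ref.sequence)
    counts = np.zeros((L, 4), dtype=np.int64)

    for aln in alignments:
        if aln.cigar is None or aln.read_id not in reads_by_id:
            continue
        read = reads_by_id[aln.read_id]
        codes = seq_to_codes(read.sequence)
        qs = aln.query_start or 0
        qe = aln.query_end if aln.query_end is not None else len(codes)
        if aln.strand == "-":
            from ._util import revcomp_codes

            seg = revcomp_codes(codes)[len(codes) - qe:len(codes) - qs]
        else:
            seg = codes[qs:qe]
        rpos = aln.ref_start
        spos = 0
        for op, n in aln.cigar:
            if op in "M=X":
                positions = (np.arange(rpos, rpos + n)) % L
                bases = seg[spos:spos + n]
                valid = bases < 4  # ignore Ns
                np.add.at(counts, (positions[valid], bases[valid]), 1)
                rpos += n
                spos += n
            elif op == "I":
                spos += n
            elif op in "DN":
                rpos += n
            elif op in "SH":
                spos += n if op == "S" else 0

    depth = counts.sum(axis=1)
    calls: list[VariantCall] = []
    covered = np.flatnonzero(depth > 0)
    for pos in covered:
        ref_code = ref_codes[pos]
        if ref_code > 3:
            continue
        alt_counts = counts[pos].copy()
        alt_counts[ref_code] = 0
        alt_code = int(alt_counts.argmax())
        alt_n = int(alt_counts[alt_code])
        if alt_n == 0 or alt_n / depth[pos] < min_alt_fraction:
            continue
        quality = _site_quality(alt_n, int(depth[pos]), error_rate)
        if quality < min_site_quality:
            continue
        calls.append(VariantCall(
            position=int(pos) + 1,
            ref_allele="ACGT"[ref_code],
            alt_allele="ACGT"[alt_code],
            quality=quality,
            horse=horse,
            library=library,
            reference_used=ref.id,
        ))
    return calls


def ts_tv_ratio(calls: Iterable[VariantCall]) -> float:
    """Transition/transversion ratio; inf when all calls are transitions."""
    ts = tv = 0
    for c in calls:
        if (c.ref_allele, c.alt_allele) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if tv == 0:
        return float("inf") if ts else float("nan")
    return ts / tv


# ---------------------------------------------------------------------------
# strict concordance
# ---------------------------------------------------------------------------

def strict_counts(
    calls_by_library: Mapping[str, Iterable[VariantKey]],
    truth: Iterable[VariantKey],
    regions: Sequence[tuple[int, int]] | None = None,
) -> ConcordanceCounts:
    """Strict multi-library concordance for one individual.

    ``regions`` (1-based inclusive intervals) optionally restricts the
    analysis to positions covered by the validation assay.
    """
    if not calls_by_library:
        raise ValueError("no libraries")

    def in_regions(key: VariantKey) -> bool:
        if regions is None:
            return True
        return any(lo <= key[0] <= hi for lo, hi in regions)

    truth_set = {k for k in truth if in_regions(k)}
    call_sets = {lib: {k for k in keys if in_regions(k)}
                 for lib, keys in calls_by_library.items()}
    all_called = set().union(*call_sets.values())
    called_everywhere = set.intersection(*call_sets.values())

    counts = ConcordanceCounts()
    for key in truth_set:
        if key in called_everywhere:
            counts.tp += 1
        else:
            counts.fn += 1
    for key in all_called - truth_set:
        counts.fp += 1
    return counts


def strict_concordance(
    calls: Mapping[str, Mapping[str, Iterable[VariantKey]]],
    truth: Mapping[str, Iterable[VariantKey]],
    regions: Sequence[tuple[int, int]] | None = None,
) -> dict[str, ConcordanceCounts]:
    """Per-individual counts plus a pooled "All" row (counts summed)."""
    out: dict[str, ConcordanceCounts] = {}
    pooled = ConcordanceCounts()
    for horse, by_library in calls.items():
        counts = strict_counts(by_library, truth.get(horse, ()), regions)
        out[horse] = counts
        pooled.tp += counts.tp
        pooled.fp += counts.fp
        pooled.fn += counts.fn
    out["All"] = pooled
    return out


def concordance_table(results: Mapping[str, ConcordanceCounts]) -> pd.DataFrame:
    rows = []
    for label, c in results.items():
        rows.append({
            "sample": label, "tp": c.tp, "fp": c.fp, "fn": c.fn,
            "precision": round_half_away(c.precision, 3) if not math.isnan(c.precision) else float("nan"),
            "recall": round_half_away(c.recall, 3) if not math.isnan(c.recall) else float("nan"),
            "f1": c.f1,
        })
    return pd.DataFrame(rows)


def found_in_all_fraction(presence) -> tuple[int, int, float]:
    """Variants found in every library: (k, n, percentage to one decimal).

    ``presence`` is a boolean variants x libraries matrix (array or
    DataFrame); e.g. 73 of 77 variants present in all seven libraries gives
    (73, 77, 94.8).
    """
    arr = np.asarray(presence, dtype=bool)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("presence matrix must be non-empty and 2-D")
    n = arr.shape[0]
    k = int(arr.all(axis=1).sum())
    return k, n, round_half_away(100.0 * k / n, 1)


def presence_matrix(
    calls_by_library: Mapping[str, Iterable[VariantKey]],
    qualities_by_library: Mapping[str, Mapping[VariantKey, float]] | None = None,
    pool: str = "max",
) -> pd.DataFrame:
    """Variant x library presence matrix (heatmap-style data).

    With qualities supplied, cells carry the call quality (NaN when absent)
    and a pooled per-variant column is added (max by default).
    """
    libraries = sorted(calls_by_library)
    variants = sorted(set().union(*(set(v) for v in calls_by_library.values())) or set())
    index = [f"{p}:{r}>{a}" for p, r, a in variants]
    if qualities_by_library is None:
        data = [[key in set(calls_by_library[lib]) for lib in libraries] for key in variants]
        return pd.DataFrame(data, index=index, columns=libraries)
    data = [[qualities_by_library.get(lib, {}).get(key, float("nan")) for lib in libraries]
            for key in variants]
    df = pd.DataFrame(data, index=index, columns=libraries)
    df["pooled"] = df.max(axis=1) if pool == "max" else df.mean(axis=1)
    return df


# ---------------------------------------------------------------------------
# VCF I/O (pysam)
# ---------------------------------------------------------------------------

def write_vcf(
    calls: Sequence[VariantCall],
    ref: CircularReference,
    path,
    min_site_quality: float = DEFAULT_SITE_QUALITY,
) -> None:
    """VCF v4.2; QUAL carries site quality, FILTER "q15" marks sub-cutoff calls."""
    import pysam

    header = pysam.VariantHeader()
    header.contigs.add(ref.id, length=ref.length)
    header.filters.add("q15", None, None, f"Site quality below {min_site_quality}")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in sorted(calls, key=lambda c: c.position):
            rec = vcf.new_record(
                contig=ref.id, start=c.position - 1,
                alleles=(c.ref_allele, c.alt_allele), qual=c.quality,
            )
            rec.filter.add("PASS" if c.quality >= min_site_quality else "q15")
            vcf.write(rec)


def read_vcf(path, horse: str = "", library: str = "") -> list[VariantCall]:
    """Read SNVs from a VCF; multi-allelic records are split per ALT."""
    import pysam

    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1 or rec.ref == alt:
                    continue
                calls.append(VariantCall(
                    position=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=alt,
                    quality=rec.qual if rec.qual is not None else float("nan"),
                    horse=horse,
                    library=library,
                    reference_used=rec.chrom,
                ))
    return calls
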