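"""Read filtering and read-set summary statistics for nanopore FASTQ data.

Mean read quality follows the convention of long-read filtering tools: the
Phred transform of the *mean per-base error probability*,
``-10 * log10(mean(10 ** (-q / 10)))``, not the arithmetic mean of Phred
values (the two differ materially for heterogeneous quality strings).

The default filter keeps reads of length >= 2000 bp with mean quality >= Q10,
the thresholds used upstream of mitochondrial variant calling; ``strict=True``
switches both comparisons to exclusive.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import round_half_away


@dataclass
class ReadRecord:
    id: str
    sequence: str
    qualities: Sequence[int]

    def __post_init__(self):
        if len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.id}: quality/sequence length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RejectionLog:
    """Counts of reads rejected by the length/quality filter, by cause.

    A read failing both checks is counted under ``too_short`` (length is
    checked first).
    """

    too_short: int = 0
    low_quality: int = 0

    @property
    def total(self) -> int:
        return self.too_short + self.low_quality


@dataclass
class ReadSetStats:
    n_reads: int = 0
    total_bases: int = 0
    mean_length: float = float("nan")
    median_length: float = float("nan")
    n50_length: int = 0
    mean_quality: float = float("nan")
    median_quality: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "Number of reads": self.n_reads,
            "Total bases (nt)": self.total_bases,
            "Mean read length (nt)": round_half_away(self.mean_length, 1)
            if self.n_reads else float("nan"),
            "Median read length (nt)": self.median_length,
            "Read length N50 (nt)": self.n50_length,
            "Mean read quality": round_half_away(self.mean_quality, 1)
            if self.n_reads else float("nan"),
            "Median read quality": round_half_away(self.median_quality, 1)
            if self.n_reads else float("nan"),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_tsv(self) -> str:
        return "\n".join(f"{k}\t{v}" for k, v in self.to_dict().items()) + "\n"


def mean_read_quality(qualities: Sequence[int]) -> float:
    """Phred value of the mean per-base error probability."""
    q = np.asarray(qualities, dtype=float)
    if q.size == 0:
        raise ValueError("no bases")
    mean_p = np.mean(10.0 ** (-q / 10.0))
    return -10.0 * math.log10(mean_p)


def filter_reads(
    reads: Iterable[ReadRecord],
    min_length: int = 2000,
    min_quality: float = 10.0,
    strict: bool = False,
) -> tuple[list[ReadRecord], RejectionLog]:
    """Keep reads passing both the length and the mean-quality threshold."""
    if min_length < 0 or min_quality < 0:
        raise ValueError("negative threshold")
    kept: list[ReadRecord] = []
    log = RejectionLog()
    for read in reads:
        length_ok = len(read) > min_length if strict else len(read) >= min_length
        if not length_ok:
            log.too_short += 1
            continue
        mq = mean_read_quality(read.qualities)
        # tolerance so an exactly-Q10 read is not lost to float round-off
        quality_ok = mq > min_quality if strict else mq >= min_quality - 1e-9
        if not quality_ok:
            log.low_quality += 1
            continue
        kept.append(read)
    return kept, log


def n50(lengths: Sequence[int]) -> int:
    """Length of the shortest read in the smallest set of longest reads
    whose summed length reaches half of the total bases."""
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if arr.size == 0:
        return 0
    half = arr.sum() / 2.0
    idx = int(np.searchsorted(np.cumsum(arr), half))
    return int(arr[min(idx, arr.size - 1)])


def read_stats(reads: Sequence[ReadRecord]) -> ReadSetStats:
    if not reads:
        return ReadSetStats()
    lengths = np.array([len(r) for r in reads], dtype=np.int64)
    mean_qs = np.array([mean_read_quality(r.qualities) for r in reads])
    return ReadSetStats(
        n_reads=len(reads),
        total_bases=int(lengths.sum()),
        mean_length=float(lengths.mean()),
        median_length=float(np.median(lengths)),
        n50_length=n50(lengths),
        mean_quality=float(mean_qs.mean()),
        median_quality=float(np.median(mean_qs)),
    )


def read_fastq(path) -> list[ReadRecord]:
    return [
        ReadRecord(rec.id, str(rec.seq), rec.letter_annotations["phred_quality"])
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    def records():
        for r in reads:
            rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = list(map(int, r.qualities))
            yield rec

    SeqIO.write(records(), str(path), "fastq")
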