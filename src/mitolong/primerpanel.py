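"""MDA primer-panel evaluation and greedy design on circular genomes.

The design rules: 10-14 nt primers, the same number hybridizing to each
strand, hybridization sites evenly spaced around the circle, and (as an
evaluation criterion) no exact matches in decoy sequences — the NUMT-bearing
nuclear contigs that caused three primers of the original panel to be
excluded.  Decoy matching is an exact full-length string match in both
orientations; even spacing is scored by the coefficient of variation of the
circular inter-primer gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import revcomp
from .circref import CircularReference

MIN_PRIMER_LEN = 10
MAX_PRIMER_LEN = 14


@dataclass
class Primer:
    name: str
    sequence: str
    strand: str  # "+" | "-"
    circ_position: int  # 1-based start of the hybridization site on the circle
    phosphorothioate_tail: bool = True  # metadata only, no computational effect

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"primer {self.name}: invalid strand {self.strand!r}")
        self.sequence = self.sequence.upper()


@dataclass
class PanelReport:
    n_primers: int
    per_strand_counts: tuple[int, int]  # (+, -)
    strand_balanced: bool
    gaps: list[int]
    gap_cv: float
    decoy_hits: dict[str, int]
    flagged: list[str]
    length_violations: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "primer": list(self.decoy_hits),
            "decoy_hits": list(self.decoy_hits.values()),
            "flagged": [p in self.flagged for p in self.decoy_hits],
        })


def _count_occurrences(haystack: str, needle: str) -> int:
    """Overlapping exact-match count."""
    count = start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def count_decoy_hits(primer_seq: str, decoys: Iterable[str]) -> int:
    """Exact matches of the primer (both orientations) across decoy sequences."""
    rc = revcomp(primer_seq)
    total = 0
    for decoy in decoys:
        decoy = decoy.upper()
        total += _count_occurrences(decoy, primer_seq)
        if rc != primer_seq:
            total += _count_occurrences(decoy, rc)
    return total


def circular_site(ref: CircularReference, position_1based: int, length: int) -> str:
    """The plus-strand sequence of a hybridization site, wrapping the origin."""
    start = position_1based - 1
    return ref.doubled_sequence[start:start + length]


def _circular_gaps(positions: Sequence[int], L: int) -> list[int]:
    ordered = sorted(p - 1 for p in positions)
    if not ordered:
        return []
    gaps = [b - a for a, b in zip(ordered, ordered[1:])]
    gaps.append(L - ordered[-1] + ordered[0])
    return gaps


def evaluate_panel(
    primers: Sequence[Primer],
    ref: CircularReference,
    decoys: Sequence[str] = (),
    decoy_hit_threshold: int = 0,
) -> PanelReport:
    """Verify and score a primer panel against the circle and decoys.

    Each primer must occur at its stated position and strand (an error names
    the first that does not); primers with more than ``decoy_hit_threshold``
    exact decoy matches are flagged for exclusion.
    """
    L = ref.length
    length_violations = []
    for p in primers:
        if not 1 <= p.circ_position <= L:
            raise ValueError(f"primer {p.name}: position {p.circ_position} outside [1, {L}]")
        if not MIN_PRIMER_LEN <= len(p.sequence) <= MAX_PRIMER_LEN:
            length_violations.append(p.name)
        site = circular_site(ref, p.circ_position, len(p.sequence))
        expected = p.sequence if p.strand == "+" else revcomp(p.sequence)
        if site != expected:
            raise ValueError(
                f"primer {p.name} not found at position {p.circ_position} "
                f"on strand {p.strand}"
            )

    plus = sum(1 for p in primers if p.strand == "+")
    minus = len(primers) - plus
    gaps = _circular_gaps([p.circ_position for p in primers], L)
    if gaps:
        mean_gap = float(np.mean(gaps))
        gap_cv = float(np.std(gaps) / mean_gap) if mean_gap > 0 else float("nan")
    else:
        gap_cv = float("nan")

    decoy_hits = {p.name: count_decoy_hits(p.sequence, decoys) for p in primers}
    flagged = [name for name, hits in decoy_hits.items() if hits > decoy_hit_threshold]

    return PanelReport(
        n_primers=len(primers),
        per_strand_counts=(plus, minus),
        strand_balanced=plus == minus,
        gaps=gaps,
        gap_cv=gap_cv,
        decoy_hits=decoy_hits,
        flagged=flagged,
        length_violations=length_violations,
    )


def _is_unique_on_circle(ref: CircularReference, site: str) -> bool:
    """Exactly one occurrence on the circle, counting both strands."""
    circle = ref.sequence + ref.sequence[:len(site) - 1]
    n = _count_occurrences(circle, site)
    rc = revcomp(site)
    if rc != site:
        n += _count_occurrences(circle, rc)
    return n == 1


def design_panel(
    ref: CircularReference,
    n_primers: int,
    primer_length: int = 12,
    decoys: Sequence[str] = (),
    search_radius: int = 200,
) -> list[Primer]:
    """Greedy panel design realising the design rules.

    Places ``n_primers`` target sites equally spaced around the circle,
    alternating strands for balance; at each target the nearest
    ``primer_length``-mer (then 11/13/10/14-mers) that is unique on the
    circle and absent from all decoys is chosen.  Raises when a target has
    no admissible k-mer within the search radius.
    """
    if n_primers % 2 != 0:
        raise ValueError("n_primers must be even for strand balance")
    L = ref.length
    if L <= n_primers * MAX_PRIMER_LEN:
        raise ValueError("genome too short for the requested panel")
    k_order = sorted(range(MIN_PRIMER_LEN, MAX_PRIMER_LEN + 1),
                     key=lambda k: (abs(k - primer_length), k))
    primers: list[Primer] = []
    for i in range(n_primers):
        target = round(i * L / n_primers)
        strand = "+" if i % 2 == 0 else "-"
        chosen = None
        for offset in sorted(range(-search_radius, search_radius + 1), key=abs):
            start = (target + offset) % L
            for k in k_order:
                site = circular_site(ref, start + 1, k)
                if "N" in site or not _is_unique_on_circle(ref, site):
                    continue
                seq = site if strand == "+" else revcomp(site)
                if count_decoy_hits(seq, decoys) > 0:
                    continue
                chosen = Primer(
                    name=f"mda_{i + 1:02d}{strand}",
                    sequence=seq,
                    strand=strand,
                    circ_position=start + 1,
                )
                break
            if chosen:
                break
        if chosen is None:
            raise ValueError(f"no admissible primer near target position {target + 1}")
        primers.append(chosen)
    return primers


def read_primer_tsv(path) -> list[Primer]:
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "sequence": str, "strand": str})
    return [
        Primer(
            name=row["name"], sequence=row["sequence"], strand=row["strand"],
            circ_position=int(row["position"]),
            phosphorothioate_tail=bool(row.get("phosphorothioate_tail", True)),
        )
        for _, row in df.iterrows()
    ]


def write_primer_tsv(primers: Sequence[Primer], path) -> None:
    pd.DataFrame([
        {
            "name": p.name, "sequence": p.sequence, "strand": p.strand,
            "position": p.circ_position,
            "phosphorothioate_tail": p.phosphorothioate_tail,
        }
        for p in primers
    ]).to_csv(path, sep="\t", index=False)
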