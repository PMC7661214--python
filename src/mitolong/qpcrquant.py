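"""qPCR Cq validation and mtDNA/nuDNA enrichment quantification.

Enrichment is quantified by a delta-Cq scheme: per condition, the geometric
mean of the mean Cq over three mitochondrial amplicons and three nuclear
amplicons, a relative mtDNA/nuDNA ratio of 2^(gm_nu - gm_mt) (amplification
efficiency fixed at 2, i.e. 100%), and fold changes as ratios of these
relative ratios between conditions.  Duplicate Cq measurements are valid
when they differ by less than 0.5 cycles; "undetermined" wells are set to
Cq 40 before that check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

UNDETERMINED = "undetermined"
UNDETERMINED_CQ = 40.0
MAX_VALID_DIFF = 0.5


@dataclass
class CqMeasurement:
    amplicon: str
    target_class: str  # "mt" | "nu"
    cq1: float | str
    cq2: float | str
    condition: str = ""
    sample: str = ""

    def __post_init__(self):
        if self.target_class not in ("mt", "nu"):
            raise ValueError(f"target_class must be mt or nu, got {self.target_class!r}")


@dataclass
class EnrichmentResult:
    gm_cq_mt: float
    gm_cq_nu: float
    relative_ratio: float  # 2^(gm_nu - gm_mt)
    condition: str = ""


def _resolve(value: float | str) -> float:
    if isinstance(value, str):
        if value.strip().lower() in (UNDETERMINED, "na", "undet", ""):
            return UNDETERMINED_CQ
        value = float(value)
    if math.isnan(value):
        return UNDETERMINED_CQ
    if not 0.0 < value <= 40.0:
        raise ValueError("Cq out of range")
    return float(value)


def validate_cq(duplicate_cqs: Sequence[float | str]) -> tuple[bool, float | None]:
    """Validate a pair of technical-replicate Cq values.

    Undetermined wells count as Cq 40 before the difference check; the pair
    is valid iff the values differ by less than 0.5 cycles, in which case the
    arithmetic mean is returned.
    """
    if len(duplicate_cqs) != 2:
        raise ValueError("exactly two technical replicates expected")
    a, b = (_resolve(v) for v in duplicate_cqs)
    if abs(a - b) < MAX_VALID_DIFF:
        return True, (a + b) / 2.0
    return False, None


def _geometric_mean(values: Sequence[float]) -> float:
    return math.exp(sum(math.log(v) for v in values) / len(values))


def enrichment_ratio(
    mt_measurements: Sequence[CqMeasurement],
    nu_measurements: Sequence[CqMeasurement],
    mean: str = "geometric",
) -> EnrichmentResult:
    """Relative mtDNA/nuDNA amount for one condition.

    Per class, the three per-amplicon mean Cqs are aggregated (geometric mean
    by default; "arithmetic" is the conventional alternative) and the ratio
    is 2^(gm_nu - gm_mt).  Any invalid duplicate pair raises an error naming
    the offending amplicon.
    """
    if mean not in ("geometric", "arithmetic"):
        raise ValueError("mean must be geometric or arithmetic")

    def class_mean(measurements: Sequence[CqMeasurement]) -> float:
        cqs = []
        for m in measurements:
            valid, value = validate_cq((m.cq1, m.cq2))
            if not valid:
                raise ValueError(f"invalid duplicate Cq for amplicon {m.amplicon}")
            cqs.append(value)
        return _geometric_mean(cqs) if mean == "geometric" else sum(cqs) / len(cqs)

    gm_mt = class_mean(mt_measurements)
    gm_nu = class_mean(nu_measurements)
    condition = mt_measurements[0].condition if mt_measurements else ""
    return EnrichmentResult(
        gm_cq_mt=gm_mt,
        gm_cq_nu=gm_nu,
        relative_ratio=2.0 ** (gm_nu - gm_mt),
        condition=condition,
    )


def fold_change(treated: EnrichmentResult, control: EnrichmentResult) -> float:
    """Enrichment of one condition relative to another."""
    if control.relative_ratio == 0:
        raise ValueError("control ratio is zero")
    return treated.relative_ratio / control.relative_ratio


def read_cq_table(path) -> list[CqMeasurement]:
    """TSV of (sample, condition, amplicon, target_class, Cq1, Cq2);
    "NA" marks undetermined wells."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample", "condition", "amplicon", "target_class", "Cq1", "Cq2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Cq table missing columns: {sorted(missing)}")
    return [
        CqMeasurement(
            amplicon=row["amplicon"], target_class=row["target_class"],
            cq1=row["Cq1"], cq2=row["Cq2"],
            condition=row["condition"], sample=row["sample"],
        )
        for _, row in df.iterrows()
    ]


def enrichment_table(
    measurements: Iterable[CqMeasurement],
    control_condition: str | None = None,
    mean: str = "geometric",
) -> pd.DataFrame:
    """Per-condition relative ratios, with fold changes versus a control."""
    by_condition: dict[str, dict[str, list[CqMeasurement]]] = {}
    for m in measurements:
        by_condition.setdefault(m.condition, {"mt": [], "nu": []})[m.target_class].append(m)
    rows = []
    results: dict[str, EnrichmentResult] = {}
    for cond, classes in by_condition.items():
        results[cond] = enrichment_ratio(classes["mt"], classes["nu"], mean=mean)
    for cond, res in results.items():
        row = {
            "condition": cond,
            "gm_cq_mt": res.gm_cq_mt,
            "gm_cq_nu": res.gm_cq_nu,
            "relative_ratio": res.relative_ratio,
        }
        if control_condition is not None:
            row["fold_change_vs_control"] = fold_change(res, results[control_condition])
        rows.append(row)
    return pd.DataFrame(rows)
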