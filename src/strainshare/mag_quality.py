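"""Quality scoring, retention filtering, and tiering of metagenome-assembled genomes.

A MAG (metagenome-assembled genome) is kept in the catalog when its composite
quality score

    quality = completeness - 5 * contamination + log(N50)

reaches 50 and both completeness (>= 50%) and contamination (<= 10%) pass on
their own.  Retained MAGs are tiered into high / medium / low classes on
completeness and contamination alone.  Completeness and contamination are
CheckM-style percentages; N50 is in base pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import pandas as pd

__all__ = [
    "MagRecord",
    "quality_score",
    "passes_retention",
    "tier",
    "summarize_tiers",
    "score_table",
]

#: Retention thresholds.
MIN_QUALITY = 50.0
MIN_COMPLETENESS = 50.0
MAX_CONTAMINATION = 10.0

LogBase = Literal["e", "10"]


def quality_score(
    completeness: float, contamination: float, n50: float, log_base: LogBase = "e"
) -> float:
    """Composite genome quality: completeness - 5*contamination + log(N50).

    Parameters
    ----------
    completeness, contamination
        CheckM-style percentages; completeness in [0, 100], contamination >= 0.
    n50
        Assembly N50 in base pairs; must be >= 1.
    log_base
        Base of the N50 log term.  Natural log by default; base 10 shifts the
        N50 contribution by a constant factor and is offered because the
        convention differs between tools.
    """
    if not 0 <= completeness <= 100:
        raise ValueError(f"completeness must be in [0, 100], got {completeness}")
    if contamination < 0:
        raise ValueError(f"contamination must be >= 0, got {contamination}")
    if n50 < 1:
        raise ValueError(f"n50 must be >= 1 bp, got {n50}")
    log_n50 = math.log(n50) if log_base == "e" else math.log10(n50)
    return completeness - 5.0 * contamination + log_n50


@dataclass
class MagRecord:
    """One genome bin with its CheckM estimates and assembly statistics."""

    mag_id: str
    completeness: float
    contamination: float
    n50: float
    taxonomy: dict[str, str] = field(default_factory=dict)
    quality: float | None = None

    def __post_init__(self) -> None:
        if self.quality is None:
            self.quality = quality_score(self.completeness, self.contamination, self.n50)


def passes_retention(record: MagRecord) -> bool:
    """True iff quality >= 50, contamination <= 10 and completeness >= 50.

    All three bounds are inclusive.
    """
    assert record.quality is not None
    return (
        record.quality >= MIN_QUALITY
        and record.contamination <= MAX_CONTAMINATION
        and record.completeness >= MIN_COMPLETENESS
    )


def tier(record: MagRecord) -> str:
    """Assign a retained MAG to the ``high`` / ``medium`` / ``low`` quality tier.

    high:   completeness >= 90 and contamination <= 5
    medium: not high, completeness >= 70 and contamination <= 10
    low:    any other retained MAG

    The rules are applied with high -> medium -> low precedence so the three
    tiers partition the retained catalog.
    """
    if not passes_retention(record):
        raise ValueError(f"tier() requires a retained record; {record.mag_id} fails retention")
    if record.completeness >= 90 and record.contamination <= 5:
        return "high"
    if record.completeness >= 70 and record.contamination <= 10:
        return "medium"
    return "low"


def summarize_tiers(records: Iterable[MagRecord]) -> dict:
    """Count retained MAGs per quality tier.

    Returns a JSON-serializable dict with per-tier counts and their total.
    """
    counts = {"high": 0, "medium": 0, "low": 0}
    for rec in records:
        counts[tier(rec)] += 1
    return {**counts, "total": sum(counts.values())}


def score_table(mags: pd.DataFrame, log_base: LogBase = "e") -> pd.DataFrame:
    """Score a MAG table and annotate retention and tier.

    Expects columns ``mag_id``, ``completeness``, ``contamination``, ``n50``
    (extra columns pass through).  Returns a copy with ``quality``,
    ``retained`` and ``tier`` columns added; ``tier`` is empty for dropped
    records.
    """
    required = {"mag_id", "completeness", "contamination", "n50"}
    missing = required - set(mags.columns)
    if missing:
        raise ValueError(f"MAG table is missing columns: {sorted(missing)}")
    out = mags.copy()
    records = [
        MagRecord(
            mag_id=str(r.mag_id),
            completeness=float(r.completeness),
            contamination=float(r.contamination),
            n50=float(r.n50),
            quality=quality_score(
                float(r.completeness), float(r.contamination), float(r.n50), log_base
            ),
        )
        for r in out.itertuples()
    ]
    out["quality"] = [rec.quality for rec in records]
    out["retained"] = [passes_retention(rec) for rec in records]
    out["tier"] = [tier(rec) if passes_retention(rec) else "" for rec in records]
    return out
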