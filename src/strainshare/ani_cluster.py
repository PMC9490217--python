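"""ANI-based dereplication and novelty classification of genomes.

Genomes are collapsed into strain-level (99% ANI) or species-level (95% ANI)
clusters by greedy centroid clustering on a pairwise ANI table: genomes are
visited in order of descending priority (genome quality by default) and each
unassigned genome becomes a cluster representative, absorbing every remaining
genome whose ANI to it reaches the threshold.  This reproduces the
"best genome wins" semantics of dRep-style dereplication while operating on a
precomputed ANI table instead of sequences.

Queries are classified against a reference set as ``known`` (best hit
>= 99% ANI), ``novel_strain`` (95-99%), or ``novel_species`` (< 95% or no hit
with sufficient aligned fraction, >= 65% by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AniRecord",
    "ClusterAssignment",
    "greedy_cluster",
    "novelty_classify",
    "classify_queries",
    "STRAIN_ANI",
    "SPECIES_ANI",
    "MIN_ALIGNED_FRACTION",
]

STRAIN_ANI = 99.0
SPECIES_ANI = 95.0
MIN_ALIGNED_FRACTION = 65.0


@dataclass(frozen=True)
class AniRecord:
    """One pairwise genome comparison: ANI and aligned fraction, both in percent."""

    query_id: str
    target_id: str
    ani: float
    aligned_fraction: float = 100.0

    def __post_init__(self) -> None:
        if not 0 <= self.ani <= 100:
            raise ValueError(f"ani must be in [0, 100], got {self.ani}")
        if not 0 <= self.aligned_fraction <= 100:
            raise ValueError(
                f"aligned_fraction must be in [0, 100], got {self.aligned_fraction}"
            )


@dataclass(frozen=True)
class ClusterAssignment:
    genome_id: str
    cluster_id: str
    is_representative: bool


def _ani_lookup(records: Iterable[AniRecord], genomes: set[str]) -> dict[tuple[str, str], float]:
    """Symmetric (a, b) -> ANI map; keeps the max when both directions are given."""
    ani: dict[tuple[str, str], float] = {}
    for rec in records:
        if rec.query_id not in genomes or rec.target_id not in genomes:
            raise ValueError(
                f"ANI record references unknown genome: {rec.query_id} / {rec.target_id}"
            )
        for key in ((rec.query_id, rec.target_id), (rec.target_id, rec.query_id)):
            ani[key] = max(ani.get(key, 0.0), rec.ani)
    return ani


def greedy_cluster(
    ani_records: Iterable[AniRecord],
    threshold: float,
    priority: Mapping[str, float],
) -> list[ClusterAssignment]:
    """Greedy centroid clustering at an ANI threshold.

    Parameters
    ----------
    ani_records
        Pairwise comparisons; missing pairs are treated as below threshold.
        The table is symmetrized (max of the two directions).
    threshold
        ANI percent at which a genome joins a representative's cluster
        (inclusive: ANI >= threshold joins).
    priority
        Score per genome (higher first); must cover every genome.  Ties break
        lexicographically on genome id, so the result is deterministic.
    """
    genomes = set(priority)
    ani = _ani_lookup(ani_records, genomes)
    order = sorted(genomes, key=lambda g: (-priority[g], g))
    assigned: dict[str, str] = {}
    assignments: list[ClusterAssignment] = []
    for rep in order:
        if rep in assigned:
            continue
        assigned[rep] = rep
        assignments.append(ClusterAssignment(rep, rep, True))
        for member in order:
            if member in assigned:
                continue
            if ani.get((rep, member), 0.0) >= threshold:
                assigned[member] = rep
                assignments.append(ClusterAssignment(member, rep, False))
    return assignments


def novelty_classify(best_hit: AniRecord | None) -> str:
    """Classify a query genome from its best qualifying reference hit.

    ``best_hit`` is the reference comparison with maximal ANI among those with
    sufficient aligned fraction, or None when no comparison qualifies.
    No hit or ANI < 95 -> ``novel_species``; 95 <= ANI < 99 -> ``novel_strain``;
    ANI >= 99 -> ``known``.
    """
    if best_hit is None or best_hit.ani < SPECIES_ANI:
        return "novel_species"
    if best_hit.ani < STRAIN_ANI:
        return "novel_strain"
    return "known"


def classify_queries(
    ani_records: Iterable[AniRecord],
    queries: Sequence[str],
    min_aligned_fraction: float = MIN_ALIGNED_FRACTION,
) -> pd.DataFrame:
    """Classify each query genome against reference hits in an ANI table.

    For every query, hits with aligned_fraction < ``min_aligned_fraction`` are
    discarded, the maximal-ANI survivor is taken as the best hit, and
    :func:`novelty_classify` is applied.  Returns a table with columns
    ``genome_id``, ``best_ani``, ``best_target``, ``classification``.
    """
    best: dict[str, AniRecord] = {}
    for rec in ani_records:
        if rec.aligned_fraction < min_aligned_fraction:
            continue
        cur = best.get(rec.query_id)
        if cur is None or rec.ani > cur.ani:
            best[rec.query_id] = rec
    rows = []
    for q in queries:
        hit = best.get(q)
        rows.append(
            {
                "genome_id": q,
                "best_ani": hit.ani if hit else float("nan"),
                "best_target": hit.target_id if hit else "",
                "classification": novelty_classify(hit),
            }
        )
    return pd.DataFrame(rows, columns=["genome_id", "best_ani", "best_target", "classification"])
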