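"""Per-strain, per-sample SNV allele profiles from pileup tables.

A strain's profile in a sample is the set of alleles (position, base) observed
with adequate read support, together with the positions that are evaluable at
all.  An allele is called when at least two reads of base quality Phred >= 15
support it; a position counts as covered (evaluable) when the qualifying reads
across its alleles total at least two.  Strains are considered present in a
sample only with breadth >= 10% and mean depth >= 0.15x; samples passing this
presence filter are the "screening samples" over which each allele's
incidence f(i) — the fraction of screening samples carrying it — is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "StrainProfile",
    "build_profiles",
    "call_alleles",
    "presence_filter",
    "incidence",
    "MIN_SUPPORT_READS",
    "MIN_BREADTH",
    "MIN_DEPTH",
]

#: Minimum qualifying (Phred >= 15) reads for an allele call, and for a
#: position to count as covered.
MIN_SUPPORT_READS = 2
#: Strain presence thresholds (inclusive).
MIN_BREADTH = 0.10
MIN_DEPTH = 0.15

PILEUP_COLUMNS = [
    "strain_id",
    "sample_id",
    "position",
    "allele",
    "read_count",
    "min_phred_passing_count",
]


@dataclass(frozen=True)
class StrainProfile:
    """Observed alleles and evaluable positions of one strain in one sample."""

    strain_id: str
    sample_id: str
    breadth: float
    depth: float
    alleles: frozenset = field(default_factory=frozenset)
    covered_positions: frozenset = field(default_factory=frozenset)


def call_alleles(
    pileup: pd.DataFrame, breadth: float = 1.0, depth: float = 1.0
) -> StrainProfile:
    """Build the profile of a single (strain, sample) from its pileup rows.

    ``pileup`` must carry the standard pileup columns for exactly one strain
    and sample; ``min_phred_passing_count`` is the number of reads supporting
    the allele at Phred >= 15.  Alleles with fewer than two qualifying reads
    are dropped; positions whose qualifying depth (summed over alleles) is
    below two are not evaluable.
    """
    if (pileup["read_count"] < 0).any() or (pileup["min_phred_passing_count"] < 0).any():
        raise ValueError("negative read counts in pileup")
    strains = pileup["strain_id"].unique()
    samples = pileup["sample_id"].unique()
    if len(strains) > 1 or len(samples) > 1:
        raise ValueError("call_alleles expects rows for a single strain and sample")
    called = pileup[pileup["min_phred_passing_count"] >= MIN_SUPPORT_READS]
    alleles = frozenset(zip(called["position"].tolist(), called["allele"].tolist()))
    pos_depth = pileup.groupby("position")["min_phred_passing_count"].sum()
    covered = frozenset(pos_depth.index[pos_depth >= MIN_SUPPORT_READS].tolist())
    strain_id = str(strains[0]) if len(strains) else ""
    sample_id = str(samples[0]) if len(samples) else ""
    return StrainProfile(strain_id, sample_id, breadth, depth, alleles, covered)


def build_profiles(pileup: pd.DataFrame, coverage: pd.DataFrame) -> list[StrainProfile]:
    """Profiles for every (strain, sample) in a pileup table.

    ``coverage`` supplies ``breadth`` and ``depth`` per (strain_id, sample_id);
    pairs present in the coverage table but absent from the pileup yield empty
    profiles (no alleles, no covered positions).
    """
    if (pileup["read_count"] < 0).any() or (pileup["min_phred_passing_count"] < 0).any():
        raise ValueError("negative read counts in pileup")

    called = pileup[pileup["min_phred_passing_count"] >= MIN_SUPPORT_READS]
    allele_sets: dict[tuple, set] = {}
    for (strain, sample), grp in called.groupby(["strain_id", "sample_id"], sort=False):
        allele_sets[(strain, sample)] = set(
            zip(grp["position"].tolist(), grp["allele"].tolist())
        )
    pos_depth = pileup.groupby(["strain_id", "sample_id", "position"], sort=False)[
        "min_phred_passing_count"
    ].sum()
    covered_sets: dict[tuple, set] = {}
    ok = pos_depth[pos_depth >= MIN_SUPPORT_READS]
    for (strain, sample, pos) in ok.index:
        covered_sets.setdefault((strain, sample), set()).add(pos)

    profiles = []
    for row in coverage.itertuples():
        key = (row.strain_id, row.sample_id)
        profiles.append(
            StrainProfile(
                strain_id=str(row.strain_id),
                sample_id=str(row.sample_id),
                breadth=float(row.breadth),
                depth=float(row.depth),
                alleles=frozenset(allele_sets.get(key, ())),
                covered_positions=frozenset(covered_sets.get(key, ())),
            )
        )
    return profiles


def presence_filter(
    profiles: list[StrainProfile],
    min_breadth: float = MIN_BREADTH,
    min_depth: float = MIN_DEPTH,
) -> tuple[list[StrainProfile], dict]:
    """Keep profiles whose strain is present: breadth and depth at or above
    the thresholds (both inclusive).

    Returns the surviving profiles and a ``{"kept": k, "dropped": d}`` report.
    """
    kept = [p for p in profiles if p.breadth >= min_breadth and p.depth >= min_depth]
    return kept, {"kept": len(kept), "dropped": len(profiles) - len(kept)}


def incidence(
    profiles: list[StrainProfile], coverage_aware: bool = True
) -> pd.DataFrame:
    """Allele incidence f(i) across one strain's screening samples.

    ``profiles`` are the screened (presence-filtered) profiles of a single
    strain.  For each allele observed in at least one sample,
    f = (# samples carrying the allele) / denominator, where the denominator
    is by default the number of samples whose covered positions include the
    allele's position (coverage-aware), or the full screening-sample count
    with ``coverage_aware=False``.

    Returns a table with columns ``strain_id``, ``position``, ``allele``,
    ``n_present``, ``n_covering``, ``f`` plus an ``n_screen`` attribute column.
    """
    if not profiles:
        raise ValueError("incidence requires at least one screened profile")
    strain_ids = {p.strain_id for p in profiles}
    if len(strain_ids) > 1:
        raise ValueError(f"profiles span multiple strains: {sorted(strain_ids)}")
    n_screen = len(profiles)

    present: dict[tuple, int] = {}
    for p in profiles:
        for al in p.alleles:
            present[al] = present.get(al, 0) + 1
    covering: dict = {}
    for p in profiles:
        for pos in p.covered_positions:
            covering[pos] = covering.get(pos, 0) + 1

    rows = []
    for (pos, base), n_present in sorted(present.items()):
        n_cov = covering.get(pos, 0)
        denom = n_cov if coverage_aware else n_screen
        rows.append(
            {
                "strain_id": next(iter(strain_ids)),
                "position": pos,
                "allele": base,
                "n_present": n_present,
                "n_covering": n_cov,
                "f": n_present / denom if denom else float("nan"),
                "n_screen": n_screen,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["strain_id", "position", "allele", "n_present", "n_covering", "f", "n_screen"],
    )
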