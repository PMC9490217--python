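"""CPM normalization, MAG abundance aggregation, and composition summaries.

Per-contig read counts are normalized to contigs-per-million (CPM, per-sample
totals scaled to 1e6); the abundance of a MAG in a sample is the median CPM
over its contigs.  Downstream community analyses use phylum-level relative
abundances, the Firmicutes/Bacteroidota ratio, and Shannon/richness alpha
diversity.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import entropy

__all__ = [
    "cpm",
    "mag_abundance",
    "phylum_relative_abundance",
    "fb_ratio",
    "alpha_diversity",
    "relative_abundance",
]

CPM_SCALE = 1_000_000.0


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Normalize a contig x sample count matrix to contigs per million.

    Each sample (column) is scaled so its total is 1e6.  Counts must be
    non-negative and every sample needs at least one positive count.
    """
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=0)
    dead = totals[totals <= 0]
    if len(dead):
        raise ValueError(f"all-zero sample(s): {', '.join(map(str, dead.index))}")
    return counts / totals * CPM_SCALE


def mag_abundance(contig_cpm: pd.DataFrame, contig_to_mag: Mapping[str, str]) -> pd.DataFrame:
    """Aggregate contig CPM to MAG abundance as the per-MAG median.

    ``contig_to_mag`` maps contig id -> MAG id; every mapped contig must be a
    row of ``contig_cpm``.  Medians over an even number of contigs take the
    midpoint of the two central values (numpy convention).
    """
    mapped = pd.Series(dict(contig_to_mag), name="mag_id")
    missing = set(mapped.index) - set(contig_cpm.index)
    if missing:
        raise ValueError(f"contigs missing from CPM table: {sorted(missing)[:5]}")
    groups = contig_cpm.loc[mapped.index].groupby(mapped)
    out = groups.median()
    out.index.name = "mag_id"
    return out


def phylum_relative_abundance(
    abundance: pd.DataFrame, taxonomy: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse a MAG x sample abundance matrix to phylum x sample fractions.

    MAGs without a taxonomy entry fall under ``unclassified``.  Per-sample
    fractions sum to 1.
    """
    phyla = pd.Series(
        [taxonomy.get(m, "unclassified") or "unclassified" for m in abundance.index],
        index=abundance.index,
    )
    sums = abundance.groupby(phyla).sum()
    totals = sums.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("sample with zero total abundance")
    return sums / totals


def fb_ratio(phylum_fractions: pd.DataFrame) -> pd.Series:
    """Firmicutes-to-Bacteroidota ratio per sample.

    The numerator pools every phylum whose name starts with ``Firmicutes``
    (GTDB splits the phylum into Firmicutes, Firmicutes_A, ...).  Samples with
    zero Bacteroidota get NaN: the ratio is undefined there.
    """
    firmi = phylum_fractions.loc[
        [p for p in phylum_fractions.index if str(p).startswith("Firmicutes")]
    ].sum(axis=0)
    if "Bacteroidota" in phylum_fractions.index:
        bacteroidota = phylum_fractions.loc["Bacteroidota"]
    else:
        bacteroidota = pd.Series(0.0, index=phylum_fractions.columns)
    ratio = firmi / bacteroidota.where(bacteroidota > 0)
    ratio.name = "fb_ratio"
    return ratio


def alpha_diversity(abundance: pd.DataFrame) -> pd.DataFrame:
    """Shannon index (natural log) and richness per sample.

    Richness counts strains with positive abundance; Shannon is
    H = -sum(q_i ln q_i) over the positive relative abundances q_i.
    """
    if (abundance.values < 0).any():
        raise ValueError("abundances must be non-negative")
    totals = abundance.sum(axis=0)
    if (totals <= 0).any():
        dead = totals.index[totals <= 0]
        raise ValueError(f"all-zero sample(s): {', '.join(map(str, dead))}")
    shannon = {s: entropy(abundance[s].values[abundance[s].values > 0]) for s in abundance}
    richness = (abundance > 0).sum(axis=0)
    return pd.DataFrame({"shannon": pd.Series(shannon), "richness": richness})


def relative_abundance(abundance: pd.DataFrame) -> pd.DataFrame:
    """Renormalize a MAG x sample matrix so each sample sums to 1.

    Used to make median-CPM MAG abundances comparable across samples for
    Bray-Curtis analyses.
    """
    totals = abundance.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("cannot renormalize sample with zero total")
    return abundance / totals
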