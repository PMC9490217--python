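"""Strain transmission scoring from SNV-profile agreement between samples.

For a strain observed in two samples, every allele i whose position is
evaluable in both samples falls in one of four agreement classes: present in
both (1,1), absent in both (0,0), or present in exactly one (1,0) / (0,1).
Under the null model that the two samples draw alleles independently from the
strain's population, the class probabilities follow from the allele's
incidence f(i) across screening samples:

    p11 = f^2        p00 = (1-f)^2        p10 = p01 = f(1-f)

The observed-agreement log score sums log-probabilities of the agreement
classes and subtracts those of the disagreement classes,

    L_obs = [sum_(1,1) ln p11 + sum_(0,0) ln p00]
          - [sum_(1,0) ln p10 + sum_(0,1) ln p01]

and is compared with the least likely all-agreement configuration,
L_min = sum_i min(ln p11, ln p00).  Their ratio P_raw = L_obs / L_min is
standardized per strain into a Z score across all evaluated sample pairs,

    S_T = (P_raw - mu_raw) / sigma_raw,

so pairs whose profiles agree far beyond chance stand out against the
strain's background pairs.  Pairs of cohoused hosts (and rumen-cecum pairs
within a goat) with S_T above a threshold are called transmission events and
classified as intra-species, inter-species, or foregut-hindgut.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .snv_profiles import StrainProfile, presence_filter

__all__ = [
    "PairComparison",
    "TransmissionEvent",
    "pair_probabilities",
    "clamp_incidence",
    "overlap_likelihood",
    "raw_score",
    "standardize",
    "classify_event",
    "evaluated_pairs",
    "transmission_scores",
    "detect_events",
    "summarize_events",
    "transmitted_abundance_fraction",
    "DEFAULT_THRESHOLD",
    "DEFAULT_MIN_ALLELES",
    "DEFAULT_MIN_PAIRS",
]

DEFAULT_THRESHOLD = 2.0
DEFAULT_MIN_ALLELES = 20
DEFAULT_MIN_PAIRS = 3

SCORE_COLUMNS = [
    "strain_id",
    "sample_a",
    "sample_b",
    "pair_role",
    "n_alleles",
    "L_obs",
    "L_min",
    "P_raw",
    "S_T",
]


@dataclass
class PairComparison:
    """Scored comparison of one strain between two samples."""

    strain_id: str
    sample_a: str
    sample_b: str
    n_alleles: int
    L_obs: float
    L_min: float
    P_raw: float
    S_T: float = float("nan")


@dataclass(frozen=True)
class TransmissionEvent:
    strain_id: str
    sample_a: str
    sample_b: str
    S_T: float
    event_type: str  # intra_species | inter_species | foregut_hindgut


def clamp_incidence(f: float | np.ndarray, n_screen: int) -> float | np.ndarray:
    """Pull incidences away from 0 and 1 by the add-half pseudocount bound.

    f is clamped into [1/(2 n_screen), 1 - 1/(2 n_screen)] so that fixed
    alleles (f = 0 or 1) do not produce infinite log terms.
    """
    if n_screen < 1:
        raise ValueError("n_screen must be >= 1")
    eps = 1.0 / (2.0 * n_screen)
    return np.clip(f, eps, 1.0 - eps)


def pair_probabilities(
    f: float, f2: float | None = None, formula: str = "product"
) -> tuple[float, float, float, float]:
    """Agreement-class probabilities (p11, p00, p10, p01) for one allele.

    The default ``product`` model treats the two samples as independent draws
    with the same incidence f: p11 = f^2, p00 = (1-f)^2, p10 = p01 = f(1-f);
    the four sum to 1.  ``formula="literal"`` instead evaluates the subtractive
    difference forms (p11 = f1 - f2, ...), which are not valid probabilities
    and are provided for inspection only; ``f2`` defaults to ``f``.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"incidence must be in [0, 1], got {f}")
    g = f if f2 is None else f2
    if not 0.0 <= g <= 1.0:
        raise ValueError(f"incidence must be in [0, 1], got {g}")
    if formula == "product":
        return f * g, (1 - f) * (1 - g), f * (1 - g), (1 - f) * g
    if formula == "literal":
        return f - g, (1 - f) - (1 - g), f - (1 - g), (1 - f) - g
    raise ValueError(f"unknown formula {formula!r}")


def overlap_likelihood(
    agreement_classes: Iterable[tuple[int, int]],
    incidences: Iterable[float],
) -> tuple[float, float]:
    """L_obs and L_min over one pair's evaluated alleles.

    ``agreement_classes[k]`` is the (a, b) presence pattern of allele k in the
    two samples; ``incidences[k]`` its clamped incidence.  Natural logs.
    """
    l_obs = 0.0
    l_min = 0.0
    n = 0
    for (a, b), f in zip(agreement_classes, incidences):
        p11, p00, p10, p01 = pair_probabilities(f)
        if (a, b) == (1, 1):
            l_obs += math.log(p11)
        elif (a, b) == (0, 0):
            l_obs += math.log(p00)
        elif (a, b) == (1, 0):
            l_obs -= math.log(p10)
        elif (a, b) == (0, 1):
            l_obs -= math.log(p01)
        else:
            raise ValueError(f"invalid agreement class {(a, b)}")
        l_min += min(math.log(p11), math.log(p00))
        n += 1
    if n == 0:
        raise ValueError("no evaluated alleles")
    return l_obs, l_min


def raw_score(l_obs: float, l_min: float) -> float:
    """P_raw = L_obs / L_min; requires L_min < 0."""
    if l_min >= 0:
        raise ValueError(f"L_min must be negative, got {l_min}")
    return l_obs / l_min


def standardize(p_raw: np.ndarray) -> np.ndarray:
    """Z-standardize one strain's P_raw values (sample sd, n-1 denominator).

    Returns NaN for every pair when the standard deviation is zero (the
    scores are then undefined).
    """
    vals = np.asarray(p_raw, dtype=float)
    if vals.size < 2:
        return np.full(vals.shape, np.nan)
    mu = vals.mean()
    sigma = vals.std(ddof=1)
    if sigma == 0:
        return np.full(vals.shape, np.nan)
    return (vals - mu) / sigma


def classify_event(meta_a: Mapping, meta_b: Mapping) -> str:
    """Transmission event type from the two samples' metadata.

    Same host with rumen and cecum sites -> ``foregut_hindgut``; different
    hosts of one species -> ``intra_species``; different species ->
    ``inter_species``.  A same-host, same-site pair is not an eligible pair.
    """
    if meta_a["host_id"] == meta_b["host_id"]:
        sites = {meta_a["gut_site"], meta_b["gut_site"]}
        if sites == {"rumen", "cecum"}:
            return "foregut_hindgut"
        raise ValueError(
            f"samples from the same host and gut site are not an eligible pair: "
            f"{meta_a['host_id']}/{sites}"
        )
    if meta_a["host_species"] == meta_b["host_species"]:
        return "intra_species"
    return "inter_species"


def evaluated_pairs(metadata: pd.DataFrame) -> pd.DataFrame:
    """Enumerate the sample pairs a strain can be scored on.

    Within each timepoint: every cross-host pair of samples in the same group
    (cohoused pairs are candidate transmission pairs, control pairs provide
    the null background for standardization), plus the rumen-cecum pair within
    each host sampled at both sites.  Returns columns ``sample_a``,
    ``sample_b`` (lexicographic order), ``pair_role`` in
    {``eligible``, ``background``}.
    """
    md = metadata.set_index("sample_id")
    rows = []
    for _, tp_md in md.groupby("timepoint"):
        samples = list(tp_md.index)
        for i, sa in enumerate(samples):
            for sb in samples[i + 1 :]:
                a, b = tp_md.loc[sa], tp_md.loc[sb]
                if a["host_id"] == b["host_id"]:
                    if {a["gut_site"], b["gut_site"]} == {"rumen", "cecum"}:
                        role = "eligible"  # foregut-hindgut candidate
                    else:
                        continue
                elif a["group"] == b["group"]:
                    role = "eligible" if a["group"] == "cohoused" else "background"
                else:
                    continue  # cross-group pairs are neither callable nor null
                sa_, sb_ = sorted((sa, sb))
                rows.append({"sample_a": sa_, "sample_b": sb_, "pair_role": role})
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "pair_role"])


def _pairwise_matrices(
    presence: np.ndarray, covered: np.ndarray, log_f: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense all-pairs L_obs / L_min / allele-count matrices for one strain.

    ``presence`` (samples x alleles) marks called alleles, ``covered`` marks
    alleles whose position is evaluable in the sample; called implies covered.
    ``log_f`` holds the per-allele log probabilities lp11, lp00, lp10.
    """
    P = presence.astype(float)
    Q = (covered & ~presence).astype(float)
    C = covered.astype(float)
    l_obs = (
        (P * log_f["lp11"]) @ P.T
        + (Q * log_f["lp00"]) @ Q.T
        - (P * log_f["lp10"]) @ Q.T
        - (Q * log_f["lp10"]) @ P.T
    )
    l_min = (C * log_f["lmin"]) @ C.T
    n_alleles = C @ C.T
    return l_obs, l_min, n_alleles


def transmission_scores(
    profiles: list[StrainProfile],
    metadata: pd.DataFrame,
    min_alleles: int = DEFAULT_MIN_ALLELES,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    coverage_aware: bool = True,
) -> pd.DataFrame:
    """Score every evaluated sample pair for every strain.

    ``profiles`` may be unfiltered; the strain presence filter is applied
    first, and allele incidences are computed across each strain's screening
    samples.  Pairs with fewer than ``min_alleles`` evaluable alleles are
    skipped, and strains with fewer than ``min_pairs`` scored pairs (or zero
    spread in P_raw) get NaN S_T.

    Returns a table with one row per scored pair: strain_id, sample_a,
    sample_b, pair_role, n_alleles, L_obs, L_min, P_raw, S_T.
    """
    from .snv_profiles import incidence as incidence_table

    screened, _ = presence_filter(profiles)
    pairs = evaluated_pairs(metadata)
    pair_index = list(zip(pairs["sample_a"], pairs["sample_b"]))
    role_of = dict(zip(pair_index, pairs["pair_role"]))

    by_strain: dict[str, list[StrainProfile]] = {}
    for p in screened:
        by_strain.setdefault(p.strain_id, []).append(p)

    records: list[dict] = []
    for strain_id in sorted(by_strain):
        strain_profiles = sorted(by_strain[strain_id], key=lambda p: p.sample_id)
        if len(strain_profiles) < 2:
            continue
        inc = incidence_table(strain_profiles, coverage_aware=coverage_aware)
        if inc.empty:
            continue
        n_screen = len(strain_profiles)
        f = clamp_incidence(inc["f"].to_numpy(float), n_screen)
        lp11 = np.log(f * f)
        lp00 = np.log((1 - f) * (1 - f))
        lp10 = np.log(f * (1 - f))
        log_f = {"lp11": lp11, "lp00": lp00, "lp10": lp10, "lmin": np.minimum(lp11, lp00)}

        alleles = list(zip(inc["position"].tolist(), inc["allele"].tolist()))
        allele_idx = {al: k for k, al in enumerate(alleles)}
        pos_of_allele = inc["position"].to_numpy()
        samples = [p.sample_id for p in strain_profiles]
        sample_idx = {s: i for i, s in enumerate(samples)}
        n, m = len(samples), len(alleles)
        presence = np.zeros((n, m), dtype=bool)
        covered = np.zeros((n, m), dtype=bool)
        for i, p in enumerate(strain_profiles):
            for al in p.alleles:
                k = allele_idx.get(al)
                if k is not None:
                    presence[i, k] = True
            cov = p.covered_positions
            covered[i] = [pos in cov for pos in pos_of_allele]

        l_obs_m, l_min_m, n_all_m = _pairwise_matrices(presence, covered, log_f)

        strain_rows: list[dict] = []
        for (sa, sb), role in role_of.items():
            ia, ib = sample_idx.get(sa), sample_idx.get(sb)
            if ia is None or ib is None:
                continue
            n_al = int(round(n_all_m[ia, ib]))
            if n_al < min_alleles:
                continue
            l_obs, l_min = float(l_obs_m[ia, ib]), float(l_min_m[ia, ib])
            strain_rows.append(
                {
                    "strain_id": strain_id,
                    "sample_a": sa,
                    "sample_b": sb,
                    "pair_role": role,
                    "n_alleles": n_al,
                    "L_obs": l_obs,
                    "L_min": l_min,
                    "P_raw": raw_score(l_obs, l_min),
                }
            )
        if not strain_rows:
            continue
        p_raw = np.array([r["P_raw"] for r in strain_rows])
        if len(strain_rows) >= min_pairs:
            s_t = standardize(p_raw)
        else:
            s_t = np.full(len(strain_rows), np.nan)
        for r, z in zip(strain_rows, s_t):
            r["S_T"] = float(z)
        records.extend(strain_rows)

    return pd.DataFrame(records, columns=SCORE_COLUMNS)


def detect_events(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Call transmission events: eligible pairs with S_T >= threshold.

    Eligible pairs are cross-host pairs within the cohoused group plus
    rumen-cecum pairs within a host (as flagged by ``pair_role``); background
    pairs only anchor the standardization and are never called.  Each event is
    typed intra_species / inter_species / foregut_hindgut from the metadata.
    """
    md = metadata.set_index("sample_id")
    hits = scores[
        (scores["pair_role"] == "eligible")
        & scores["S_T"].notna()
        & (scores["S_T"] >= threshold)
    ]
    rows = [
        {
            "strain_id": r.strain_id,
            "sample_a": r.sample_a,
            "sample_b": r.sample_b,
            "S_T": r.S_T,
            "event_type": classify_event(md.loc[r.sample_a], md.loc[r.sample_b]),
        }
        for r in hits.itertuples()
    ]
    return pd.DataFrame(
        rows, columns=["strain_id", "sample_a", "sample_b", "S_T", "event_type"]
    )


def summarize_events(
    events: pd.DataFrame,
    total_strains: int,
    strain_phyla: Mapping[str, str] | None = None,
) -> dict:
    """Summarize called events at the strain level.

    Reports the number of distinct transmitted strains, their percentage of
    the catalog (2 decimals), the partition of transmitted strains into
    single-type groups ("only intra-species", ...) versus "multiple types"
    with percentages over the transmitted strains, and optionally a phylum
    breakdown.
    """
    if total_strains < events["strain_id"].nunique():
        raise ValueError("total_strains smaller than the number of strains with events")
    types_by_strain: dict[str, set] = {}
    for r in events.itertuples():
        types_by_strain.setdefault(r.strain_id, set()).add(r.event_type)
    n_transmitted = len(types_by_strain)

    def pct(k: int, n: int) -> float:
        return round(100.0 * k / n, 2) if n else 0.0

    only = {"intra_species": 0, "inter_species": 0, "foregut_hindgut": 0}
    multiple = 0
    for types in types_by_strain.values():
        if len(types) == 1:
            only[next(iter(types))] += 1
        else:
            multiple += 1
    summary = {
        "transmitted_strains": n_transmitted,
        "total_strains": total_strains,
        "transmitted_pct": pct(n_transmitted, total_strains),
        "n_events": int(len(events)),
        "only_intra_species": only["intra_species"],
        "only_intra_species_pct": pct(only["intra_species"], n_transmitted),
        "only_inter_species": only["inter_species"],
        "only_inter_species_pct": pct(only["inter_species"], n_transmitted),
        "only_foregut_hindgut": only["foregut_hindgut"],
        "only_foregut_hindgut_pct": pct(only["foregut_hindgut"], n_transmitted),
        "multiple_types": multiple,
        "multiple_types_pct": pct(multiple, n_transmitted),
    }
    if strain_phyla is not None:
        phyla_counts: dict[str, int] = {}
        for strain in types_by_strain:
            ph = strain_phyla.get(strain, "unclassified")
            phyla_counts[ph] = phyla_counts.get(ph, 0) + 1
        summary["phylum_pct"] = {
            ph: pct(k, n_transmitted) for ph, k in sorted(phyla_counts.items())
        }
    return summary


def transmitted_abundance_fraction(
    events: pd.DataFrame, abundance: pd.DataFrame
) -> pd.Series:
    """Per-sample fraction of total abundance held by transmitted strains.

    ``abundance`` is a strain x sample matrix covering all samples of
    interest; a strain is transmitted when it appears in at least one event.
    """
    transmitted = [s for s in abundance.index if s in set(events["strain_id"])]
    totals = abundance.sum(axis=0)
    frac = abundance.loc[transmitted].sum(axis=0) / totals.where(totals > 0)
    frac.name = "transmitted_fraction"
    return frac.fillna(0.0)
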