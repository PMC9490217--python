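"""Synthetic cohousing study generator with planted transmission events.

Emulates a two-species cohousing experiment: goats (sampled in rumen and
cecum) and pigs (cecum only), a cohoused group sharing a pen and a control
group in separate pens, sampled at several timepoints.  Strains occupy one or
more of the three habitats (goat rumen, goat cecum, pig cecum) with
habitat-specific log-normal abundances; cohoused samples' compositions are
pulled toward the common cohoused mean by a mixing coefficient.  Each strain
carries a binary (reference/alternate) haplotype over its polymorphic
positions in every host gut site; sequencing is simulated as Poisson
per-position depth with base-call errors and Phred-quality thinning.

Transmission is planted as haplotype copying: for every eligible cohoused
host-site pair of a strain, an independent Bernoulli(transmission_rate) draw
decides whether the donor's haplotype replaces the recipient's (with a small
per-position mutation probability); rumen-to-cecum copying within each goat
is planted at ``foregut_hindgut_rate``.  Copies always read the pristine
pre-planting haplotype, and each recipient keeps the last copy applied, so
haplotype identity (tracked through lineage labels) stays interpretable.  The
returned truth object records both the raw planted events and the final set
of sample pairs that actually share a haplotype lineage — the ground truth
that event detection is measured against.

All randomness flows from a single integer seed through independent named
streams, so outputs are bit-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .snv_profiles import StrainProfile

__all__ = ["SimConfig", "SyntheticTruth", "generate_study", "generate_genome_tables",
           "corrupt_profile", "strain_habitats", "eligible_cohoused_pairs",
           "eligible_foregut_hindgut"]

HABITATS = ("goat_rumen", "goat_cecum", "pig_cecum")

#: Habitat occupancy classes cycled over the strain catalog, with weights.
#: Single-habitat specialists, goat generalists (rumen+cecum), cross-species
#: cecum strains, and full generalists.
_CLASS_HABITATS = {
    "goat_rumen": ("goat_rumen",),
    "goat_cecum": ("goat_cecum",),
    "pig_cecum": ("pig_cecum",),
    "goat_both": ("goat_rumen", "goat_cecum"),
    "cross_cecum": ("goat_cecum", "pig_cecum"),
    "generalist": HABITATS,
}
_CLASS_WEIGHTS = {
    "goat_rumen": 0.2,
    "goat_cecum": 0.2,
    "pig_cecum": 0.2,
    "goat_both": 0.2,
    "cross_cecum": 0.1,
    "generalist": 0.1,
}

#: Phylum label pool with catalog proportions shaped like a ruminant/pig gut
#: (Firmicutes_A and Bacteroidota dominate).
_PHYLA = ("Firmicutes_A", "Bacteroidota", "Proteobacteria", "Firmicutes",
          "Verrucomicrobiota", "Spirochaetota", "Thermoplasmatota", "unclassified")
_PHYLUM_WEIGHTS = (0.36, 0.36, 0.06, 0.05, 0.05, 0.04, 0.03, 0.05)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic study; the defaults are the study design
    the generator is meant to emulate (15 goats and 15 pigs, six of each
    cohoused, three sampling timepoints)."""

    n_strains: int = 40
    n_goats: int = 15
    n_pigs: int = 15
    n_cohoused_goats: int = 6
    n_cohoused_pigs: int = 6
    timepoints: tuple[str, ...] = ("0m", "3m", "12m")
    n_positions_per_strain: int = 150
    mean_depth: float = 5.0
    breadth_range: tuple[float, float] = (0.6, 0.95)
    seq_error_rate: float = 0.005
    base_quality_mean: float = 30.0
    transmission_rate: float = 0.3
    foregut_hindgut_rate: float = 0.2
    haplotype_mutation_rate: float = 0.005
    mixing_coefficient: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("seq_error_rate", "transmission_rate", "foregut_hindgut_rate",
                     "haplotype_mutation_rate", "mixing_coefficient"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_strains", "n_goats", "n_pigs", "n_cohoused_goats",
                     "n_cohoused_pigs", "n_positions_per_strain"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_cohoused_goats > self.n_goats:
            raise ValueError("n_cohoused_goats exceeds n_goats")
        if self.n_cohoused_pigs > self.n_pigs:
            raise ValueError("n_cohoused_pigs exceeds n_pigs")
        if not (0 <= self.breadth_range[0] <= self.breadth_range[1] <= 1):
            raise ValueError(f"invalid breadth_range {self.breadth_range}")
        if not self.timepoints:
            raise ValueError("timepoints must be non-empty")


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic study.

    ``planted_events`` lists the Bernoulli-success copy operations (one row
    per success, samples referenced at the last timepoint).  Because later
    copies can overwrite earlier ones, ``shared_pairs`` is the authoritative
    truth for detection: every eligible same-timepoint sample pair whose two
    samples carry the same haplotype lineage after all planting.
    """

    planted_events: pd.DataFrame
    shared_pairs: pd.DataFrame
    strain_phyla: dict[str, str]
    haplotypes: dict[tuple[str, str, str], np.ndarray] = field(repr=False, default_factory=dict)
    n_eligible_cohoused: int = 0

    def to_json(self, path) -> None:
        payload = {
            "planted_events": self.planted_events.to_dict(orient="records"),
            "shared_pairs": self.shared_pairs.to_dict(orient="records"),
            "strain_phyla": self.strain_phyla,
            "n_eligible_cohoused": self.n_eligible_cohoused,
            "haplotypes": {
                "|".join(k): "".join("1" if b else "0" for b in v)
                for k, v in self.haplotypes.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _strain_ids(n: int) -> list[str]:
    return [f"s{i:03d}" for i in range(n)]


def strain_habitats(config: SimConfig) -> dict[str, tuple[str, ...]]:
    """Deterministic habitat occupancy per strain (no randomness involved)."""
    classes = list(_CLASS_HABITATS)
    # proportional allocation, remainder to the earliest classes
    counts = {c: int(_CLASS_WEIGHTS[c] * config.n_strains) for c in classes}
    i = 0
    while sum(counts.values()) < config.n_strains:
        counts[classes[i % len(classes)]] += 1
        i += 1
    occupancy = {}
    sid = iter(_strain_ids(config.n_strains))
    for c in classes:
        for _ in range(counts[c]):
            occupancy[next(sid)] = _CLASS_HABITATS[c]
    return occupancy


def _hosts(config: SimConfig) -> pd.DataFrame:
    rows = []
    for i in range(config.n_goats):
        rows.append({"host_id": f"g{i + 1:02d}", "host_species": "goat",
                     "group": "cohoused" if i < config.n_cohoused_goats else "control"})
    for i in range(config.n_pigs):
        rows.append({"host_id": f"p{i + 1:02d}", "host_species": "pig",
                     "group": "cohoused" if i < config.n_cohoused_pigs else "control"})
    return pd.DataFrame(rows)


def _slots(config: SimConfig) -> pd.DataFrame:
    """One row per (host, gut site): the sampling slots."""
    hosts = _hosts(config)
    rows = []
    for h in hosts.itertuples():
        sites = ("rumen", "cecum") if h.host_species == "goat" else ("cecum",)
        for site in sites:
            rows.append({
                "slot_id": f"{h.host_id}_{site}",
                "host_id": h.host_id,
                "host_species": h.host_species,
                "gut_site": site,
                "group": h.group,
                "habitat": f"{h.host_species}_{site}",
            })
    return pd.DataFrame(rows)


def eligible_cohoused_pairs(config: SimConfig) -> list[tuple[str, str, str]]:
    """Eligible (strain, donor_slot, recipient_slot) triples for cohoused
    transmission, in the deterministic order the Bernoulli stream is drawn.

    A cohoused cross-host slot pair is eligible for a strain when the strain
    occupies both slots' habitats.  Slots are ordered lexicographically; the
    first slot of each pair acts as donor.
    """
    occupancy = strain_habitats(config)
    slots = _slots(config)
    cohoused = slots[slots["group"] == "cohoused"]
    triples = []
    for strain in _strain_ids(config.n_strains):
        habs = set(occupancy[strain])
        mine = cohoused[cohoused["habitat"].isin(habs)].sort_values("slot_id")
        host_of = dict(zip(mine["slot_id"], mine["host_id"]))
        for a, b in combinations(sorted(mine["slot_id"]), 2):
            if host_of[a] != host_of[b]:
                triples.append((strain, a, b))
    return triples


def eligible_foregut_hindgut(config: SimConfig) -> list[tuple[str, str, str]]:
    """Eligible (strain, rumen_slot, cecum_slot) triples for within-goat
    foregut-to-hindgut transmission (strains occupying both goat habitats),
    in Bernoulli-stream order."""
    occupancy = strain_habitats(config)
    goats = _hosts(config)
    goats = goats[goats["host_species"] == "goat"]
    triples = []
    for strain in _strain_ids(config.n_strains):
        if {"goat_rumen", "goat_cecum"} <= set(occupancy[strain]):
            for host in sorted(goats["host_id"]):
                triples.append((strain, f"{host}_rumen", f"{host}_cecum"))
    return triples


def _phred_pass_probability(mean: float, sd: float = 3.0, lo: float = 2.0,
                            hi: float = 41.0, cutoff: float = 15.0) -> float:
    """P(rounded truncated-normal Phred >= cutoff) for quality thinning."""
    a, b = norm.cdf(lo - 0.5, mean, sd), norm.cdf(hi + 0.5, mean, sd)
    tail = norm.cdf(hi + 0.5, mean, sd) - norm.cdf(cutoff - 0.5, mean, sd)
    total = b - a
    return float(np.clip(tail / total, 0.0, 1.0)) if total > 0 else 0.0


def generate_study(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate one synthetic study.

    Returns ``(metadata, abundance, coverage, pileup, truth)``:
    metadata with one row per sample; a strain x sample CPM abundance matrix;
    a per-(strain, sample) breadth/depth coverage table; a long-format pileup
    table with per-allele read counts and Phred-qualified counts; and the
    :class:`SyntheticTruth`.
    """
    strains = _strain_ids(config.n_strains)
    occupancy = strain_habitats(config)
    slots = _slots(config)
    n_pos = config.n_positions_per_strain

    rng_catalog = np.random.default_rng([config.seed, 0])
    rng_abund = np.random.default_rng([config.seed, 1])
    rng_cohoused = np.random.default_rng([config.seed, 2])
    rng_fh = np.random.default_rng([config.seed, 3])
    rng_mut = np.random.default_rng([config.seed, 4])
    rng_seq = np.random.default_rng([config.seed, 5])

    phyla = dict(zip(strains, rng_catalog.choice(_PHYLA, size=len(strains),
                                                 p=_PHYLUM_WEIGHTS)))
    # population alternate-allele frequency per position, then one binary
    # haplotype per (strain, slot)
    pop_freq = {s: rng_catalog.uniform(0.1, 0.9, size=n_pos) for s in strains}
    base_hap: dict[tuple[str, str], np.ndarray] = {}
    for s in strains:
        for slot in slots["slot_id"]:
            base_hap[(s, slot)] = rng_catalog.random(n_pos) < pop_freq[s]

    # ---- metadata -------------------------------------------------------
    meta_rows = []
    for tp in config.timepoints:
        for r in slots.itertuples():
            meta_rows.append({
                "sample_id": f"{r.slot_id}_{tp}",
                "host_id": r.host_id,
                "host_species": r.host_species,
                "gut_site": r.gut_site,
                "group": r.group,
                "timepoint": tp,
            })
    metadata = pd.DataFrame(meta_rows)

    # ---- abundance (log-normal per strain x habitat, cohoused mixing) ---
    log_mu = {(s, h): rng_abund.normal(0.0, 1.0)
              for s in strains for h in occupancy[s]}
    rel_cols = {}
    for tp in config.timepoints:
        for r in slots.itertuples():
            w = np.zeros(len(strains))
            for k, s in enumerate(strains):
                if r.habitat in occupancy[s]:
                    w[k] = np.exp(log_mu[(s, r.habitat)] + rng_abund.normal(0.0, 0.4))
            rel_cols[f"{r.slot_id}_{tp}"] = w / w.sum()
    rel = pd.DataFrame(rel_cols, index=strains)
    m = config.mixing_coefficient
    if m > 0:
        # Shared-pen homogenization: cohoused compositions are pulled toward
        # the cross-species cohoused mean.  Habitat filtering still applies —
        # a strain gains abundance only in habitats it can occupy; reaching a
        # new habitat is the role of the transmission model, not of mixing.
        cohoused = slots.loc[slots["group"] == "cohoused"]
        habitat_mask = {
            h: np.array([h in occupancy[s] for s in strains]) for h in HABITATS
        }
        for tp in config.timepoints:
            cols = [f"{r.slot_id}_{tp}" for r in cohoused.itertuples()]
            mean_comp = rel[cols].mean(axis=1).to_numpy()
            for r in cohoused.itertuples():
                c = f"{r.slot_id}_{tp}"
                mixed = (1 - m) * rel[c].to_numpy() + m * mean_comp
                mixed = np.where(habitat_mask[r.habitat], mixed, 0.0)
                rel[c] = mixed / mixed.sum()
    abundance = rel * 1_000_000.0
    abundance.index.name = "strain_id"

    # ---- planted transmission ------------------------------------------
    fh_triples = eligible_foregut_hindgut(config)
    fh_hits = [t for t, u in zip(fh_triples, rng_fh.random(len(fh_triples)))
               if u < config.foregut_hindgut_rate]
    co_triples = eligible_cohoused_pairs(config)
    co_draws = rng_cohoused.random(len(co_triples)) if co_triples else np.empty(0)
    co_hits = [t for t, u in zip(co_triples, co_draws)
               if u < config.transmission_rate]

    slot_meta = slots.set_index("slot_id")
    lineage: dict[tuple[str, str], str] = {(s, slot): slot
                                           for s in strains for slot in slots["slot_id"]}
    final_hap = dict(base_hap)

    def classify_slots(a: str, b: str) -> str:
        ma, mb = slot_meta.loc[a], slot_meta.loc[b]
        if ma["host_id"] == mb["host_id"]:
            return "foregut_hindgut"
        return "intra_species" if ma["host_species"] == mb["host_species"] else "inter_species"

    event_rows = []
    last_tp = config.timepoints[-1]
    for strain, donor, recipient in fh_hits + co_hits:
        flips = rng_mut.random(n_pos) < config.haplotype_mutation_rate
        final_hap[(strain, recipient)] = base_hap[(strain, donor)] ^ flips
        lineage[(strain, recipient)] = donor
        event_rows.append({
            "strain_id": strain,
            "donor_sample": f"{donor}_{last_tp}",
            "recipient_sample": f"{recipient}_{last_tp}",
            "donor_slot": donor,
            "recipient_slot": recipient,
            "event_type": classify_slots(donor, recipient),
        })
    planted_events = pd.DataFrame(
        event_rows, columns=["strain_id", "donor_sample", "recipient_sample",
                             "donor_slot", "recipient_slot", "event_type"])

    # ---- truth: sample pairs sharing a lineage after all copying --------
    shared_rows = []
    cohoused_ids = set(slots.loc[slots["group"] == "cohoused", "slot_id"])
    for strain in strains:
        groups: dict[str, list[str]] = {}
        for slot in slots["slot_id"]:
            groups.setdefault(lineage[(strain, slot)], []).append(slot)
        for members in groups.values():
            for a, b in combinations(sorted(members), 2):
                ma, mb = slot_meta.loc[a], slot_meta.loc[b]
                same_host = ma["host_id"] == mb["host_id"]
                if same_host:
                    ok = {ma["gut_site"], mb["gut_site"]} == {"rumen", "cecum"}
                else:
                    ok = a in cohoused_ids and b in cohoused_ids
                if not ok:
                    continue
                etype = classify_slots(a, b)
                for tp in config.timepoints:
                    sa, sb = sorted((f"{a}_{tp}", f"{b}_{tp}"))
                    shared_rows.append({"strain_id": strain, "sample_a": sa,
                                        "sample_b": sb, "event_type": etype})
    shared_pairs = pd.DataFrame(
        shared_rows, columns=["strain_id", "sample_a", "sample_b", "event_type"])

    # ---- sequencing: coverage + pileup ---------------------------------
    p_pass = _phred_pass_probability(config.base_quality_mean, cutoff=15.0)
    positions = np.arange(n_pos)
    cov_rows = []
    pile: dict[str, list] = {k: [] for k in PILEUP_KEYS}
    for s in strains:
        for col in abundance.columns:
            rel_ab = abundance.at[s, col] / 1_000_000.0
            depth_factor = rel_ab * config.n_strains
            if depth_factor < 0.01:
                continue
            slot = col.rsplit("_", 1)[0]
            hap = final_hap[(s, slot)]
            b = rng_seq.uniform(*config.breadth_range)
            n_cov = max(1, int(round(b * n_pos)))
            covered = np.sort(rng_seq.choice(positions, size=n_cov, replace=False))
            depth = rng_seq.poisson(config.mean_depth * depth_factor, size=n_cov)
            nz = depth > 0
            covered, depth = covered[nz], depth[nz]
            if covered.size == 0:
                continue
            err = rng_seq.binomial(depth, config.seq_error_rate)
            true_is_alt = hap[covered]
            alt_reads = np.where(true_is_alt, depth - err, err)
            ref_reads = depth - alt_reads
            alt_pass = rng_seq.binomial(alt_reads, p_pass)
            ref_pass = rng_seq.binomial(ref_reads, p_pass)
            for allele, reads, passing in (("ref", ref_reads, ref_pass),
                                           ("alt", alt_reads, alt_pass)):
                keep = reads > 0
                k = int(keep.sum())
                if not k:
                    continue
                pile["strain_id"].append(np.repeat(s, k))
                pile["sample_id"].append(np.repeat(col, k))
                pile["position"].append(covered[keep])
                pile["allele"].append(np.repeat(allele, k))
                pile["read_count"].append(reads[keep])
                pile["min_phred_passing_count"].append(passing[keep])
            cov_rows.append({
                "strain_id": s,
                "sample_id": col,
                "breadth": covered.size / n_pos,
                "depth": float(depth.sum()) / n_pos,
            })
    coverage = pd.DataFrame(cov_rows, columns=["strain_id", "sample_id", "breadth", "depth"])
    pileup = pd.DataFrame({k: np.concatenate(v) if v else np.array([])
                           for k, v in pile.items()})
    pileup = pileup.astype({"position": int, "read_count": int,
                            "min_phred_passing_count": int})
    pileup = pileup.sort_values(["strain_id", "sample_id", "position", "allele"],
                                kind="mergesort").reset_index(drop=True)

    truth = SyntheticTruth(
        planted_events=planted_events,
        shared_pairs=shared_pairs,
        strain_phyla=phyla,
        haplotypes={(s, *slot.rsplit("_", 1)): final_hap[(s, slot)]
                    for s in strains for slot in slots["slot_id"]},
        n_eligible_cohoused=len(co_triples),
    )
    return metadata, abundance, coverage, pileup, truth


PILEUP_KEYS = ["strain_id", "sample_id", "position", "allele",
               "read_count", "min_phred_passing_count"]


def generate_genome_tables(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthetic genome-level side tables for the QC and dereplication stages.

    Returns ``(mags, ani, ref_ani)``: a MAG quality table with one record per
    strain (completeness/contamination/N50 spanning the retention boundary,
    phylum taxonomy), a pairwise ANI table in which ~10% of consecutive
    strain pairs are near-duplicates (ANI >= 99) and strains of a shared
    phylum sit at species-level distances, and a reference-hit table that
    spreads strains across the known / novel-strain / novel-species classes.
    """
    rng = np.random.default_rng([config.seed, 6])
    strains = _strain_ids(config.n_strains)
    phyla_rng = np.random.default_rng([config.seed, 0])
    phyla = dict(zip(strains, phyla_rng.choice(_PHYLA, size=len(strains),
                                               p=_PHYLUM_WEIGHTS)))
    mags = pd.DataFrame({
        "mag_id": strains,
        "completeness": np.round(rng.uniform(45.0, 100.0, len(strains)), 2),
        "contamination": np.round(rng.uniform(0.0, 12.0, len(strains)), 2),
        "n50": rng.integers(5_000, 500_000, len(strains)),
        "phylum": [phyla[s] for s in strains],
    })
    ani_rows = []
    for i, a in enumerate(strains):
        for j, b in enumerate(strains[i + 1:], start=i + 1):
            if j == i + 1 and rng.random() < 0.1:
                ani = rng.uniform(99.0, 100.0)  # near-duplicate bin pair
            elif phyla[a] == phyla[b]:
                # spans the species boundary: some same-phylum pairs collapse
                # at 95% but not at 99%
                ani = rng.uniform(88.0, 96.5)
            else:
                ani = rng.uniform(70.0, 80.0)
            ani_rows.append({"query_id": a, "target_id": b,
                             "ani": round(ani, 3),
                             "aligned_fraction": round(rng.uniform(60.0, 95.0), 2)})
    ani = pd.DataFrame(ani_rows, columns=["query_id", "target_id", "ani", "aligned_fraction"])
    ref_rows = []
    for s in strains:
        u = rng.random()
        if u < 0.3:
            hit_ani = rng.uniform(99.0, 100.0)   # known
        elif u < 0.6:
            hit_ani = rng.uniform(95.0, 99.0)    # novel strain
        else:
            hit_ani = rng.uniform(75.0, 95.0)    # novel species
        ref_rows.append({"query_id": s, "target_id": f"ref_{s}",
                         "ani": round(hit_ani, 3),
                         "aligned_fraction": round(rng.uniform(50.0, 95.0), 2)})
    ref_ani = pd.DataFrame(ref_rows, columns=["query_id", "target_id", "ani", "aligned_fraction"])
    return mags, ani, ref_ani


def corrupt_profile(profile: StrainProfile, dropout_rate: float, seed: int) -> StrainProfile:
    """Remove each observed allele independently with probability
    ``dropout_rate``; coverage and depth are untouched.  Used for robustness
    checks of the scoring stage."""
    if not 0.0 <= dropout_rate <= 1.0:
        raise ValueError(f"dropout_rate must be in [0, 1], got {dropout_rate}")
    rng = np.random.default_rng(seed)
    kept = frozenset(al for al in sorted(profile.alleles)
                     if rng.random() >= dropout_rate)
    return replace(profile, alleles=kept)
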