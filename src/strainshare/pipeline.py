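"""End-to-end orchestration: simulate -> qc -> derep -> abundance -> snv ->
transmit -> stats, with a machine-readable report.

Every stage reads and writes plain TSV tables under one output directory;
stages whose outputs already exist are skipped unless forced, and the final
``report.json`` collects every summary statistic together with the resolved
configuration and seeds, so each number is recomputable from the stage
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as ab
from . import ani_cluster as ac
from . import community_stats as cs
from . import mag_quality as mq
from . import snv_profiles as sp
from . import transmission as tr
from .simulate import SimConfig, generate_study, generate_genome_tables

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]

log = logging.getLogger("strainshare")

DEFAULT_TERMS = ["group", "timepoint"]


@dataclasses.dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    outdir: str = "strainshare_run"
    seed: int = 0
    force: bool = False
    sim: dict = dataclasses.field(default_factory=dict)
    threshold: float = tr.DEFAULT_THRESHOLD
    min_alleles: int = tr.DEFAULT_MIN_ALLELES
    min_pairs: int = tr.DEFAULT_MIN_PAIRS
    n_permutations: int = 999
    permanova_terms: list = dataclasses.field(default_factory=lambda: list(DEFAULT_TERMS))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def validate_inputs(metadata: pd.DataFrame, abundance: pd.DataFrame) -> list[dict]:
    """Sanity-check a metadata table against an abundance matrix.

    Returns findings as ``{"level": "error"|"warning", "message": ...}``
    dicts instead of raising, so callers can report them all at once.
    """
    findings = []
    required = ["sample_id", "host_id", "host_species", "gut_site", "group", "timepoint"]
    for col in required:
        if col not in metadata.columns:
            findings.append({"level": "error", "message": f"metadata missing column {col!r}"})
    if (abundance.values < 0).any():
        bad = abundance.columns[(abundance < 0).any(axis=0)]
        findings.append({
            "level": "error",
            "message": f"negative abundance in sample(s): {', '.join(map(str, bad))}",
        })
    if "sample_id" in metadata.columns:
        missing = set(abundance.columns) - set(metadata["sample_id"])
        for s in sorted(missing):
            findings.append({
                "level": "error",
                "message": f"sample {s!r} in abundance is absent from metadata",
            })
        extra = set(metadata["sample_id"]) - set(abundance.columns)
        for s in sorted(extra):
            findings.append({
                "level": "warning",
                "message": f"sample {s!r} in metadata has no abundance column",
            })
    if "group" in metadata.columns and metadata["group"].nunique() < 2:
        findings.append({"level": "warning", "message": "metadata has a single group level"})
    return findings


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def _habitat_label(md_row) -> str:
    return f"{md_row['host_species']} {md_row['gut_site']}"


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a synthetic study and return the report dict.

    Existing stage outputs under ``config.outdir`` are reused unless
    ``config.force`` is set; the report is also written to ``report.json``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "stages": []}

    def stage_done(*names: str) -> bool:
        return not config.force and all((out / n).exists() for n in names)

    # -- simulate --------------------------------------------------------
    sim_files = ["metadata.tsv", "abundance.tsv", "coverage.tsv", "pileup.tsv",
                 "truth.json", "mags.tsv", "ani.tsv", "ref_ani.tsv"]
    sim_cfg = SimConfig(**{"seed": config.seed, **config.sim})
    if stage_done(*sim_files):
        log.info("[simulate] outputs exist, skipping")
    else:
        log.info("[simulate] generating synthetic study")
        metadata, abund, coverage, pileup, truth = generate_study(sim_cfg)
        mags, ani, ref_ani = generate_genome_tables(sim_cfg)
        _write(metadata, out / "metadata.tsv")
        _write(abund.reset_index(), out / "abundance.tsv")
        _write(coverage, out / "coverage.tsv")
        _write(pileup, out / "pileup.tsv")
        truth.to_json(out / "truth.json")
        _write(mags, out / "mags.tsv")
        _write(ani, out / "ani.tsv")
        _write(ref_ani, out / "ref_ani.tsv")
    report["stages"].append("simulate")

    metadata = pd.read_csv(out / "metadata.tsv", sep="\t")
    abund = pd.read_csv(out / "abundance.tsv", sep="\t", index_col="strain_id")
    coverage = pd.read_csv(out / "coverage.tsv", sep="\t")
    pileup = pd.read_csv(out / "pileup.tsv", sep="\t")
    with open(out / "truth.json") as fh:
        truth_json = json.load(fh)
    strain_phyla = truth_json["strain_phyla"]

    findings = validate_inputs(metadata, abund)
    report["validation"] = findings
    if any(f["level"] == "error" for f in findings):
        raise RuntimeError(f"input validation failed: {findings}")

    # -- qc --------------------------------------------------------------
    mags = pd.read_csv(out / "mags.tsv", sep="\t")
    qc = mq.score_table(mags)
    _write(qc, out / "mags.qc.tsv")
    retained = qc[qc["retained"]]
    records = [mq.MagRecord(r.mag_id, r.completeness, r.contamination, r.n50)
               for r in retained.itertuples()]
    report["tier_summary"] = mq.summarize_tiers(records)
    report["stages"].append("qc")

    # -- derep + novelty -------------------------------------------------
    ani_df = pd.read_csv(out / "ani.tsv", sep="\t")
    ani_records = [ac.AniRecord(r.query_id, r.target_id, r.ani, r.aligned_fraction)
                   for r in ani_df.itertuples()]
    priority = dict(zip(qc["mag_id"], qc["quality"]))
    derep = {}
    for thr, name in ((ac.STRAIN_ANI, "strain_99"), (ac.SPECIES_ANI, "species_95")):
        assignments = ac.greedy_cluster(ani_records, thr, priority)
        cl = pd.DataFrame([dataclasses.asdict(a) for a in assignments])
        _write(cl, out / f"clusters_{name}.tsv")
        derep[name] = {"n_clusters": int(cl["cluster_id"].nunique()),
                       "n_genomes": int(len(cl))}
    report["dereplication"] = derep
    ref_df = pd.read_csv(out / "ref_ani.tsv", sep="\t")
    ref_records = [ac.AniRecord(r.query_id, r.target_id, r.ani, r.aligned_fraction)
                   for r in ref_df.itertuples()]
    novelty = ac.classify_queries(ref_records, list(qc["mag_id"]))
    _write(novelty, out / "novelty.tsv")
    report["novelty"] = novelty["classification"].value_counts().to_dict()
    report["stages"].append("derep")

    # -- abundance summaries ---------------------------------------------
    phylum_fracs = ab.phylum_relative_abundance(abund, strain_phyla)
    _write(phylum_fracs.reset_index(names="phylum"), out / "phylum_fractions.tsv")
    alpha = ab.alpha_diversity(abund)
    _write(alpha.reset_index(names="sample_id"), out / "alpha.tsv")
    fb = ab.fb_ratio(phylum_fracs)
    md_idx = metadata.set_index("sample_id")
    report["fb_ratio_by_habitat"] = {
        hab: round(float(vals.mean()), 4)
        for hab, vals in fb.groupby(md_idx.loc[fb.index].apply(_habitat_label, axis=1))
        if np.isfinite(vals.mean())
    }
    report["stages"].append("abundance")

    # -- snv profiles ----------------------------------------------------
    profiles = sp.build_profiles(pileup, coverage)
    screened, screen_report = sp.presence_filter(profiles)
    prof_df = pd.DataFrame([
        {"strain_id": p.strain_id, "sample_id": p.sample_id, "breadth": p.breadth,
         "depth": p.depth, "n_alleles": len(p.alleles),
         "n_covered_positions": len(p.covered_positions)}
        for p in screened
    ])
    _write(prof_df, out / "profiles.tsv")
    by_strain: dict[str, list] = {}
    for p in screened:
        by_strain.setdefault(p.strain_id, []).append(p)
    inc_tables = [sp.incidence(v) for v in by_strain.values() if v]
    _write(pd.concat(inc_tables, ignore_index=True) if inc_tables else pd.DataFrame(),
           out / "incidence.tsv")
    report["presence_filter"] = screen_report
    report["stages"].append("snv")

    # -- transmission ----------------------------------------------------
    scores = tr.transmission_scores(
        profiles, metadata, min_alleles=config.min_alleles, min_pairs=config.min_pairs)
    _write(scores, out / "scores.tsv")
    events = tr.detect_events(scores, metadata, threshold=config.threshold)
    _write(events, out / "events.tsv")
    report["event_summary"] = tr.summarize_events(
        events, total_strains=sim_cfg.n_strains, strain_phyla=strain_phyla)
    trans_frac = tr.transmitted_abundance_fraction(events, abund)
    _write(trans_frac.rename_axis("sample_id").reset_index(), out / "transmitted_fraction.tsv")
    report["stages"].append("transmit")

    # -- community statistics --------------------------------------------
    rel = ab.relative_abundance(abund)
    dm = cs.bray_curtis(rel)
    _write(dm, out / "distances.tsv", index=True)
    permanova_rows = []
    wilcoxon_rows = []
    corr_rows = []
    for habitat, hab_md in md_idx.groupby(md_idx.apply(_habitat_label, axis=1)):
        samples = [s for s in dm.index if s in set(hab_md.index)]
        if len(samples) < 4:
            continue
        sub_dm = dm.loc[samples, samples]
        sub_md = md_idx.loc[samples]
        terms = [t for t in config.permanova_terms if sub_md[t].nunique() > 1]
        if terms:
            res = cs.permanova(sub_dm, sub_md, terms,
                               n_perm=config.n_permutations, seed=config.seed)
            res.insert(0, "habitat", habitat)
            permanova_rows.append(res)
        # within-group Bray-Curtis spread: control vs cohoused pairs
        dists = {}
        for grp, grp_md in sub_md.groupby("group"):
            ids = list(grp_md.index)
            dists[grp] = [sub_dm.at[a, b] for i, a in enumerate(ids) for b in ids[i + 1:]]
        if len(dists) == 2 and all(len(v) > 1 for v in dists.values()):
            u, p = cs.wilcoxon_rank_sum(dists["control"], dists["cohoused"])
            wilcoxon_rows.append({
                "habitat": habitat, "comparison": "within_group_bray_curtis",
                "U": u, "p_value": p,
                "median_control": float(np.median(dists["control"])),
                "median_cohoused": float(np.median(dists["cohoused"])),
            })
        # transmitted-abundance correlations with richness and composition
        axis = cs.composition_axis(sub_dm)
        for grp, grp_md in sub_md.groupby("group"):
            ids = list(grp_md.index)
            if len(ids) < 3:
                continue
            tf = trans_frac.loc[ids].to_numpy()
            for other_name, other in (("richness", alpha.loc[ids, "richness"].to_numpy()),
                                      ("composition", axis.loc[ids].to_numpy())):
                rho = cs.spearman(tf, other) if np.ptp(tf) > 0 and np.ptp(other) > 0 else float("nan")
                corr_rows.append({"habitat": habitat, "group": grp,
                                  "variable": other_name, "rho": rho})
    permanova_df = (pd.concat(permanova_rows, ignore_index=True)
                    if permanova_rows else pd.DataFrame())
    _write(permanova_df, out / "permanova.tsv")
    _write(pd.DataFrame(corr_rows), out / "correlations.tsv")
    report["permanova"] = permanova_df.to_dict(orient="records")
    report["bray_curtis_wilcoxon"] = wilcoxon_rows
    report["correlations"] = corr_rows
    report["stages"].append("stats")

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating, float)):
            return None if not np.isfinite(obj) else float(obj)
        return obj

    report = _clean(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    log.info("[report] wrote %s", out / "report.json")
    return report
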