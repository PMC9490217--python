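# strainshare

Strain-level analysis of gut-microbiome transmission between cohoused hosts.

When animals of different species share a pen, microbes move between them.
Composition-level comparisons (Bray–Curtis, PERMANOVA) can show that cohoused
communities become more similar, but they cannot tell whether the *same
strain* is present in two hosts. `strainshare` implements a strain-resolution
transmission test on single-nucleotide-variant (SNV) profiles, together with
the supporting stages of a MAG-based metagenomic workflow, for a two-species
cohousing design: goats sampled in rumen and cecum, pigs in cecum, with a
cohoused group and separate-pen controls.

## The transmission score

For a strain observed in two samples, every allele *i* whose genomic position
is evaluable in both samples falls into one of four agreement classes —
present in both (1,1), absent in both (0,0), or present in exactly one (1,0)
/ (0,1). Under the null that the two samples draw alleles independently from
the strain's population, the class probabilities follow from the allele's
incidence *f(i)* across screening samples:

    p₁,₁ = f²    p₀,₀ = (1−f)²    p₁,₀ = p₀,₁ = f(1−f)

The observed agreement log-score rewards agreement and penalizes
disagreement,

    L_obs = [Σ₍₁,₁₎ ln p₁,₁ + Σ₍₀,₀₎ ln p₀,₀] − [Σ₍₁,₀₎ ln p₁,₀ + Σ₍₀,₁₎ ln p₀,₁]

and is normalized by the least likely all-agreement configuration
L_min = Σᵢ min(ln p₁,₁, ln p₀,₀). The ratio P_raw = L_obs / L_min is
Z-standardized per strain over all evaluated sample pairs (control-group
pairs provide the null background):

    S_T = (P_raw − μ_raw) / σ_raw

Cohoused cross-host pairs — and rumen–cecum pairs within a goat — with
S_T ≥ 2 are called transmission events and classified as **intra-species**,
**inter-species**, or **foregut–hindgut**.

Around the score, the package provides:

- `mag_quality` — MAG retention (`quality = completeness − 5·contamination +
  log(N50)` ≥ 50, contamination ≤ 10%, completeness ≥ 50%) and
  high/medium/low tiering;
- `ani_cluster` — greedy centroid dereplication on a pairwise ANI table
  (99% strain level, 95% species level) and novelty classification of query
  genomes (known / novel strain / novel species);
- `abundance` — contigs-per-million normalization, MAG abundance as median
  contig CPM, phylum fractions, Firmicutes/Bacteroidota ratio, Shannon and
  richness indices;
- `snv_profiles` — allele calling (≥ 2 reads at Phred ≥ 15), the strain
  presence filter (breadth ≥ 10%, depth ≥ 0.15x) and allele incidences;
- `community_stats` — Bray–Curtis, sequential (adonis2-style) PERMANOVA with
  Monte Carlo p-values, Wilcoxon rank-sum, Spearman, and a first
  principal-coordinate summary of composition;
- `simulate` — a synthetic cohousing study generator with planted
  transmission events and a ground-truth table, so the whole chain is
  validated end to end without external data;
- `pipeline` / the `strainshare` CLI — one-command orchestration with a
  machine-readable `report.json`.

## Worked example

```python
import json
from strainshare.simulate import SimConfig, generate_study
from strainshare import snv_profiles as sp, transmission as tr

cfg = SimConfig(n_strains=20, n_goats=8, n_pigs=8, n_cohoused_goats=4,
                n_cohoused_pigs=4, timepoints=("3m", "12m"), seed=42)
metadata, abundance, coverage, pileup, truth = generate_study(cfg)
profiles = sp.build_profiles(pileup, coverage)
scores = tr.transmission_scores(profiles, metadata)
events = tr.detect_events(scores, metadata, threshold=2.0)
summary = tr.summarize_events(events, total_strains=cfg.n_strains,
                              strain_phyla=truth.strain_phyla)
print(f"scored pairs: {len(scores)}, events: {len(events)}")
print(json.dumps({k: v for k, v in summary.items() if not isinstance(v, dict)},
                 indent=2))
```

prints

```
scored pairs: 1440, events: 86
{
  "transmitted_strains": 17,
  "total_strains": 20,
  "transmitted_pct": 85.0,
  "n_events": 86,
  "only_intra_species": 12,
  "only_intra_species_pct": 70.59,
  "only_inter_species": 0,
  "only_inter_species_pct": 0.0,
  "only_foregut_hindgut": 0,
  "only_foregut_hindgut_pct": 0.0,
  "multiple_types": 5,
  "multiple_types_pct": 29.41
}
```

1,440 strain/sample-pair comparisons passed the evaluability gates; 86 pairs
scored S_T ≥ 2 and were called as events, involving 17 of the 20 simulated
strains (85%). Twelve strains transmitted only within a species, five showed
several event types. (This small demonstration plants transmission densely;
the percentage is a property of the simulation settings, not of any real
community.) The same analysis runs from the shell:

```sh
strainshare simulate --out demo --seed 42
strainshare transmit --pileup demo/pileup.tsv --coverage demo/coverage.tsv \
    --metadata demo/metadata.tsv --threshold 2.0 --out demo
strainshare run --out full_run --seed 7        # entire pipeline + report.json
```

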