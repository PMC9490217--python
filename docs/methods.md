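# Methods

## The transmission model

The unit of analysis is a (strain, sample pair). A strain is considered
present in a sample when its horizontal coverage (breadth, fraction of
genome positions covered) is at least 10% and its mean vertical coverage
(depth) at least 0.15x; both bounds are inclusive. Samples passing this
presence filter for a strain are its *screening samples*. An allele — a
(position, base) pair in a biallelic reference/alternate representation — is
called in a sample when at least two reads of base quality Phred ≥ 15
support it, and a position is *evaluable* when its qualifying reads across
both alleles total at least two. Since a call needs two supporting reads,
called alleles are always a subset of evaluable positions.

The incidence f(i) of allele *i* is the fraction of screening samples
carrying it. The denominator is coverage-aware by default: only screening
samples whose evaluable positions include i's position are counted.
The naive global denominator (all screening samples) deflates f at poorly
covered positions and is available behind a flag. Screening samples are all
samples passing the presence filter for the strain, in both the cohoused
and control groups.

For a pair of samples, alleles evaluable in both samples are classified as
(1,1), (0,0), (1,0) or (0,1) by presence. Under independent draws with the
same incidence, the class probabilities are the products p₁,₁ = f²,
p₀,₀ = (1−f)², p₁,₀ = p₀,₁ = f(1−f), which sum to one. The difference forms
sometimes written for these four cases (e.g. p₁,₁ = f₁ − f₂) can be negative
and do not form a probability distribution; the product interpretation is
the one reading consistent with their description as joint
presence/absence probabilities, and the difference forms remain available
(`formula="literal"`) for inspection only. Before taking logs, f is clamped
into [1/(2n), 1 − 1/(2n)] for n screening samples — the add-half pseudocount
convention — so fixed alleles cannot produce infinite terms.

L_obs sums the log-probabilities of the agreement classes and *subtracts*
those of the disagreement classes; L_min = Σ min(ln p₁,₁, ln p₀,₀) is the
log-likelihood of the least likely all-agreement configuration, so
P_raw = L_obs/L_min is 1 for a pair agreeing everywhere in the least likely
way, near 0 for chance-level agreement, and negative when disagreement
dominates. P_raw is Z-standardized per strain (mean and n−1 standard
deviation) across all of that strain's evaluated pairs; the evaluated set
includes the control-group cross-host pairs, which provide the null
reference distribution. Strains with fewer than 3 evaluated pairs, pairs
with fewer than 20 evaluable alleles, and strains with zero P_raw spread
yield no score (gates configurable; they prevent degenerate standardization).

Evaluated pairs are restricted to samples from the same timepoint: cross-host
pairs within a group, plus the rumen–cecum pair within each goat.
Cross-timepoint pairs would mix developmental-stage differences into the
null. Events are called where S_T ≥ 2.0 on a callable pair (cohoused
cross-host, or within-goat rumen–cecum) and typed purely from sample
metadata: same host and both gut sites → foregut–hindgut; different hosts of
one species → intra-species; different species → inter-species. The default
threshold of 2.0 corresponds to roughly the 97.7th percentile under a normal
null; no universal cutoff exists for this score, and it is exposed as a
parameter. Event summaries count a strain that shows several event types
under "multiple types", not under any single type. Transmission
directionality is not identified — an event is an unordered sample pair.

## Supporting stages

**MAG quality.** quality = completeness − 5·contamination + log(N50), with
the natural log by default; the log base is configurable (e or 10) since the
convention varies between tools and only shifts the N50 term. Retention
requires quality ≥ 50, contamination ≤ 10% and completeness ≥ 50%, all
inclusive. Tiers: high (completeness ≥ 90, contamination ≤ 5), else medium
(completeness ≥ 70, contamination ≤ 10), else low. The rules are applied
with precedence so the three tiers partition the retained set — commonly
printed tier definitions overlap and leave gaps, while published tier counts
sum to catalog totals, which implies a partition.

**ANI dereplication.** Greedy centroid clustering on a precomputed pairwise
ANI table: genomes in descending priority order (genome quality by default,
ties broken lexicographically) become representatives and absorb all
unassigned genomes at ANI ≥ threshold. This reproduces the best-genome-wins
semantics of dRep-style dereplication without re-deriving ANI from sequence.
Novelty against a reference set uses the maximal-ANI hit among hits with
aligned fraction ≥ 65% (applied to both the strain- and species-level calls):
ANI ≥ 99 → known, ≥ 95 → novel strain, otherwise novel species; the novelty
bounds are strict (`< 99`, `< 95`) as conventionally printed.

**Abundance.** Contig counts are normalized per sample to contigs-per-million
(plain count proportions — no length normalization); MAG abundance is the
median CPM over the MAG's contigs (midpoint convention for even counts). For
community analyses MAG abundances are renormalized per sample to sum to 1,
since Bray–Curtis requires comparable totals. Shannon diversity uses the
natural log. Strains absent from a sample enter Bray–Curtis as zeros.

**PERMANOVA.** The squared distance matrix is Gower-centered and partitioned
sequentially (Type I, matching `adonis2` defaults) through projection
matrices of the cumulative design; pseudo-F uses the residual mean square;
significance comes from unrestricted permutations of sample labels
(999 by default) with the Monte Carlo correction
p = (1 + #{F* ≥ F}) / (1 + n_perm). Note that the achievable p floor depends
on the design: with two groups of 4, the group-preserving relabelings alone
tie with the observed statistic for ~3% of permutations, so p ≤ 0.01 is
unattainable; calibration and planted-effect checks therefore use two groups
of 7–8. The Wilcoxon rank-sum test is exact for group sizes ≤ 8 without
ties, otherwise normal with tie and continuity corrections; an all-tied
degenerate input returns p = 1. "Community composition" as a scalar per
sample is operationalized as the first principal coordinate of the
Bray–Curtis matrix (classical metric scaling, sign fixed so the first
nonzero coordinate is positive); this is one defensible choice among
several, and outputs flag it as such.

## The synthetic study generator

The generator emulates the cohousing design it is meant to validate: 15
goats and 15 pigs, six of each sharing one pen (cohoused) and the rest in
separate pens (control), goats sampled at rumen and cecum, pigs at cecum,
at three timepoints (0, 3, 12 months). Defaults: 40 strains, 150 polymorphic
positions per strain, mean depth 5 reads/position, breadth drawn uniformly
from [0.6, 0.95], sequencing error 0.005/read, base quality
Normal(30, 3) truncated to [2, 41], transmission probability 0.3 per
eligible cohoused pair-strain, foregut–hindgut probability 0.2 per
goat-strain, haplotype mutation probability 0.005 per position on transfer,
and mixing coefficient 0.3. All randomness derives from one seed through
named streams; outputs are bit-identical under a fixed seed.

Strains occupy one or more of three habitats (goat rumen, goat cecum, pig
cecum) in fixed class proportions — 20% each of the three single-habitat
specialists, 20% goat generalists, 10% cross-species cecum strains, 10% full
generalists. Abundances are log-normal per strain × habitat with per-sample
noise; cohoused compositions are pulled linearly toward the cross-species
cohoused mean by the mixing coefficient. Mixing is habitat-filtered: a
strain gains mixed abundance only in habitats it occupies. Unfiltered
mixing would seed strains into foreign habitats above the lenient presence
filter while carrying haplotypes unrelated to any donor — an artifact that
inflates the null comparison pool with pairs that cannot be true
transmissions. Reaching a new habitat is the role of the transmission model.

Haplotypes are binary vectors over the polymorphic positions, drawn per
(strain, host, gut site) from per-position population frequencies uniform in
[0.1, 0.9]. Keying haplotypes by gut site as well as host is necessary:
with one haplotype per host, rumen and cecum would trivially agree and
foregut–hindgut transmission could not be planted as a distinct event.
Transmission is planted as haplotype copying with an independent Bernoulli
draw per eligible (strain, cohoused cross-host slot pair), plus
rumen → cecum copies within each goat. Copies read the pristine pre-planting
haplotype and the last copy per recipient wins, so a slot always carries a
single well-defined lineage. Because later copies can overwrite earlier
ones, the truth object records both the raw planted-event list and — as the
authoritative recovery target — the set of sample pairs whose slots share a
lineage after all copying. Sequencing is simulated per present
(strain, sample): per-position Poisson depth scaled by relative abundance,
binomial base-call errors, and binomial Phred ≥ 15 thinning (equivalent in
distribution to drawing per-read qualities).

What the generator does *not* emulate: read-level sequence (no FASTQ),
assembly or binning noise, phylogenetic correlation among strains, within-
sample strain mixtures (each sample carries one haplotype per strain), gene
content, or temporal dynamics (haplotypes are constant across timepoints and
abundances have no timepoint effect). Passing recovery tests therefore shows
that the scoring pipeline detects haplotype sharing under realistic coverage,
error and abundance structure — not that it is robust to strain admixture
within samples or to assembly artifacts.

## Calibration results and problem sizes

With the default configuration the chain recovers planted cohoused
transmissions with mean sensitivity ≈ 0.93–0.96 and precision ≈ 0.99 over
five seeds at threshold 2.0, and calls ≈ 1% of eligible cross-host pairs
when no transmission is planted. PERMANOVA's empirical type-I error at
α = 0.05 is ≈ 0.05 over 500 null simulations (14 samples, 199 permutations),
and a strong planted group effect (two groups of 8) yields the permutation
floor p = 0.001. These are the quantities `scripts/acceptance.py` recomputes;
the test suite uses a scaled-down study (12 strains, 6+6 hosts, 2 timepoints,
80 positions) for everything except the recovery and calibration checks,
which run at the default study size.

## Known limitations

- The score is symmetric: it identifies sharing, not direction of transfer.
- A single incidence f per allele is used for both samples of a pair; per-
  sample incidences would require defining sample subpopulations the design
  does not provide.
- Greedy ANI clustering depends on the completeness of the input ANI table;
  missing pairs are treated as below threshold.
- The first-PCoA-axis summary of composition captures only the leading
  gradient; correlations against it should be read accordingly.
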