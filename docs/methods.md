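# Methods

This note documents the statistical models, estimator conventions,
simulator design and numerical choices behind `altiscan`, in the spirit of
the methods documentation of mature population-genetics packages.

## Data model

All statistics operate on unphased ALT-allele dosages (0/1/2, missing
allowed) over biallelic SNPs; phase in input VCFs is ignored because every
implemented estimator is a function of allele frequencies, heterozygote
counts, or dosage correlations. Missing genotypes are handled by per-site
non-missing allele counts everywhere — there is no imputation. Internal
interval arithmetic is 0-based half-open; every user-facing coordinate
(windows, regions, VCF, tables) is 1-based inclusive, and emitted tables
say so in a header comment.

## Site filters

The hard filters mirror common short-read genotype-call practice:
QD ≥ 20, FS ≤ 10, ReadPosRankSum ≥ −8, biallelic only, minor-allele
frequency ≥ 0.05, and QUAL strictly above the mean QUAL of the sites that
survive the other filters. All thresholds are inclusive (≥/≤). The
"QUAL above average" rule is ambiguous in common usage; we interpret
"average" as the mean over sites surviving the other filters and make the
rule togglable. MAF is computed over all samples' non-missing alleles (a
per-group alternative would change the filtered set; the pooled choice is
documented rather than silently assumed). Each removed site is charged to
the first rule it fails, so the per-rule removal counts and the survivor
count partition the input exactly. A filter whose annotation is absent at
a site fails the run by default (`on_missing="fail"`), or passes the site
under `on_missing="skip"`.

LD pruning follows the PLINK `--indep-pairwise w s r²` scheme: sliding
blocks of `w` variants advanced by `s`; while any retained pair within a
block has squared dosage correlation above the ceiling (default 0.5), the
lexicographically first offending pair is resolved by dropping its
lower-MAF member (tie: the later position). This makes the retained set
deterministic. r² uses pairwise-complete samples.

## Windows

Windows are anchored at coordinate 1 on each contig (start 1, 1+step, …),
with only fully contained windows kept by default; both choices are flags
because window anchoring is rarely reported in scans and affects nothing
but the exact window boundaries. A site at position p belongs to every
window whose inclusive span contains p. Windows with fewer than
`min_snps` (default 10) assigned sites are excluded from outlier ranking
rather than contributing unstable statistics.

## Statistics

**π** — per site 2·n_ref·n_alt/(n(n−1)) with n the non-missing allele
count; the window value is the sum over sites divided by the window span
in bp (not the SNP count), so sweeps reduce it through both lower
per-site diversity and fewer segregating sites.

**θπ ratio** — window π of the lowland group over window π of the
high-altitude group; undefined (and excluded from ranking) when the
denominator is zero.

**Hp / ZHp** — pooled heterozygosity from summed per-site major and minor
allele counts within the analysed group (major/minor orientation per site
within that group, not genome-wide), Z-standardised across the windows of
all contigs jointly with the sample (n−1) standard deviation. The scan
uses the high-altitude group's ZHp and flags its lower tail, since a sweep
depresses heterozygosity in the selected population; the tail is a flag
for users who prefer the opposite convention.

**F<sub>ST</sub>** — the Weir & Cockerham (1984) two-population estimator
from variance components a (among populations), b (among individuals
within populations) and c (within individuals), computed per site from
non-missing sample sizes, allele frequencies and observed heterozygote
proportions. Windowed values are Σa/Σ(a+b+c) (the "weighted" or
ratio-of-sums combination). Negative per-site estimates are retained, not
clamped; sites monomorphic across both populations, or with fewer than
three called individuals in total, are skipped. The lowland contrast
group pools the two lowland populations, as the emulating study pools
its lowland breeds; the resulting Wahlund effect is part of the emulated
design, not an artefact.

**Tajima's D** — the standard constants a1…e2 from the haplotype count n.
With missing data n varies by site; by default the window's modal
non-missing count is used and sites with a different count are dropped
(`n_mode="mean"` keeps all segregating sites and evaluates the constants
at the rounded mean count — an approximation, provided as a flag). For
n = 2 the numerator and the variance are both identically zero and D is
defined as 0.

**Patterson's D / f3** — per-site ABBA/BABA products of four frequency
tracks (D) and (p_C−p_A)(p_C−p_B) products (f3), combined as ratio of
sums (D) or mean (f3) and given Z-scores by a delete-one jackknife over
contiguous blocks of equal SNP count (default 1000 SNPs; the replicate
study uses 200 so a ~2.5k-SNP desk chromosome yields about a dozen blocks
and the Z statistic has usable degrees of freedom). The f3 correction
(on by default) subtracts the finite-sample bias of the target
population's frequency estimate, h_C/n_C with
h_C = n_C/(n_C−1)·p̂_C(1−p̂_C), so an unadmixed target has expectation
equal to its drift-induced (non-negative) value and a 50/50 mixture of
diverged sources tests negative, which the suite verifies by simulation.

## Outlier calling and candidate regions

For each test the top quantile (default 5 %) of eligible windows is
flagged in the statistic's characteristic tail. With k = ⌊q·n⌋, a window
is flagged iff its value lies strictly beyond the (k+1)-th extreme order
statistic: exactly k windows when boundary values are distinct, none when
all values tie (a constant track carries no outlier information).
Quantiles are computed across all contigs jointly. Windows flagged by all
three tests are intersected window-by-window; overlapping or bookended
joint windows merge into maximal candidate regions, which are annotated
with genes overlapping by at least 1 bp and fine-mapped: per-SNP
F<sub>ST</sub> across the region ± flank (default 500 kb), SNPs above the
0.3 per-SNP threshold highlighted, and non-overlapping 20 kb π-ratio and
Tajima's D tracks for both groups. The reported top SNP is the argmax of
per-SNP F<sub>ST</sub> within the candidate region proper; the flanks
only provide context, since on a short simulated chromosome (and a long
real one) distant background sites are not candidates for the causal
variant of this region.

## Association

The frequency–altitude test is a Pearson correlation of population-level
allele frequencies with altitude (two-sided p from the t transform with
n−2 df; Spearman by flag) — the study-level test is unnamed in the
emulated design, and a correlation across ≥ 3 populations is the minimal
model consistent with it. Genotype–phenotype association uses a one-way
ANOVA with genotype as a factor (the three-genotype comparison shown in
such studies; additive coding is available through the allele-substitution
fit). β comes from ordinary least squares of phenotype on intercept +
dosage + sex indicator — the fixed-effect-model step of FarmCPU-style
pipelines with sex as the fixed covariate; the full iterative FarmCPU
procedure is deliberately out of scope, and β is therefore an
allele-substitution effect under a purely fixed-effect model.
VAR(%) = 2pqβ²/S²·100 uses p, q from the observed allele counts of the
analysed samples and the sample phenotypic variance S²; values above
100 % are reported with a warning, never clamped.

## The simulator

A discrete-generation forward Wright–Fisher engine: haplotypes are rows of
a uint8 matrix over segregating integer positions (infinite sites;
a mutation landing on an occupied position is redrawn; positions freed by
loss or global fixation become reusable). Each generation, in order:
every gamete draws its parent deme from the migration row of its deme
(m[i][j] = probability a lineage in i has its parent in j), then a parent
individual (fitness-weighted 1 : 1+hs : 1+s at the selected site in the
high-altitude deme once selection is on), then a gamete is formed with a
Poisson(r·L) number of crossovers, then Poisson(μ·L) new mutations.
Burn-in runs 10·N generations in the ancestral deme (heterozygosity
equilibrates on the 2N timescale, so this is ≥ 5 time constants), after
which the population trifurcates simultaneously into QT, NC and SW.

Defaults define a desk-scale study in which a strong recent hard sweep is
present and detectable, scaled from the emulated real-world setting by
holding the key dimensionless quantities at comparable values rather than
any absolute rate:

| parameter | default | rationale |
| --- | --- | --- |
| deme size N | 100 diploids ×(ancestral+3) | desk scale |
| split T | 150 generations | T/2N = 0.75: moderately diverged demes, as in a few-thousand-year divergence of large populations |
| μ | 1e-6 /bp/gen | θ = 4Nμ = 4e-4 → ~2.4k SNPs on 1 Mb, ~10² SNPs per 100 kb window |
| r | 2e-6 /bp/gen | ρ/θ = 2; sweep footprint of order the window size |
| s | 4.0 (h = 0.5) | 2Ns = 800, matching the order of a strong real-scale sweep; fixation in ~15–25 generations |
| onset | T − 60 | a recent sweep: fixed shortly before sampling, little post-sweep recovery |
| f0 | 1/(2N), recurrent | a de novo beneficial mutation (hard sweep); if lost before establishing it recurs the next generation |
| migration | 5e-4 baseline; SW←QT 1e-3, SW←NC 7.5e-4 | asymmetric, largest flows into SW; small enough that the selected allele stays rare in the lowland demes |
| samples | 30 diploids/deme | of the order of the emulated study's per-group sample sizes |

Phenotypes are y = baseline + β·dosage + γ·sex + N(0, σ²), by default
three blood parameters with the sign structure seen in high-altitude
mammals (lower red-cell volume and haemoglobin, higher corpuscular
haemoglobin concentration in carriers), β = ±1, γ = 0.5, σ = 1.

What the simulator emulates: the joint frequency/diversity structure a
three-population split with migration and one recent sweep imposes on
SNP data, and linear genotype–phenotype coupling with a sex covariate.
What it does not emulate: genome-scale window counts (61 windows vs
~10⁵ in a real genome — see below), realistic per-bp rates, multiple
chromosomes, background selection, sequencing error, call-rate structure,
or LD patterns beyond single-contig coalescent-with-recombination noise.
Passing the replicate studies therefore demonstrates the pipeline's
correctness and calibration at desk scale, not genome-scale power.

## Known limitations

The three-test intersection is discreteness-limited at desk scale. With
61 windows, the 5 % rule flags ⌊0.05·61⌋ = 3 windows per test, and a
candidate requires the *same* window to be flagged by all three tests.
A sweep's footprint spans ~7–12 overlapping windows whose internal
ordering differs between statistics (weighted F<sub>ST</sub>
characteristically peaks on the partially swept shoulders of a completed
sweep, while the π-ratio and ZHp peak at its core), so the three 3-window
flag sets frequently fail to share a window even when every test ranks
the sweep region at the top: the measured per-test detection rates are
0.9–1.0 but the joint same-window rate plateaus near 0.6–0.75 across a
wide sweep-parameter range. On a real genome the same sweep sits in the
top 0.01 % of ~10⁵ windows and the intersection is not limiting. The
replicate study (`run_simulation_study`) reports both the per-seed
candidate outcomes and the fine-map distances so this behaviour is
measurable rather than hidden.

Other limitations: single contig; no genotype likelihoods or BCF; no
phased-haplotype statistics (EHH family); empirical quantiles only (no
permutation or FDR machinery, matching the emulated design); the
frequency–altitude test treats populations as independent points
(no phylogenetic correction).
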