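# Methods

`limadom` re-implements, as a tested pipeline on synthetic data, the
population-genetic analysis of Lima bean (*Phaseolus lunatus*) domestication:
coalescent simulation of two competing domestication histories, approximate
Bayesian computation (ABC) for choosing between them and estimating their
parameters, founder-effect and linkage-disequilibrium summaries, and genome
scans for selection signatures.  This note records the models, the numerical
choices, and what the synthetic data do and do not show.

## Demographic model

Four populations are tracked: wild and domesticated Mesoamerican gene pools I
and II (`MIW`, `MID`, `MIIW`, `MIID`).  One generation = 1 year; sizes are
diploid effective sizes.

* **Scenario 1 — two independent domestications.** `MID` splits from `MIW` at
  time `t2` with a founding bottleneck (size `N2b`, duration `db1`
  generations, placed immediately after the split going forward in time);
  `MIID` splits from `MIIW` at `t1` with bottleneck (`N3b`, `db2`).  The wild
  pools share an ancestor at `t3`.
* **Scenario 2 — single domestication plus admixture.** `MID` originates as
  above; `MIID` forms at `t1` as an admixed population drawing a fraction
  `ra` of its ancestry from `MID` and `1 - ra` from `MIIW` (so `ra` near 1
  means the MII landraces are mostly migrant domesticated MI stock).

Priors are independent uniforms: `N1..N4` ~ U(10, 2·10⁶); `N2b`, `N3b` ~
U(10, 5·10³); `t1`, `t2` ~ U(2·10³, 10⁴); `t3` ~ U(3·10⁵, 10⁶); `db1`, `db2`
~ U(10³, 3·10³); `ra` ~ U(0.001, 0.999).  Timeline well-formedness requires
`t3 > max(t1, t2)`, `t2 > db1`, plus `t1 > db2` (scenario 1) and `t2 > t1`
(scenario 2); draws violating these are rejected and redrawn.  The ancestral
population after `t3` takes size `N4` — the wild MII pool is the larger and
more diverse one — as a configurable modelling choice.

## Coalescent SNP simulator

Each locus is an independent genealogy of the sampled gene copies, simulated
backwards in time with exponential waiting times inside each epoch
(coalescence rate `k(k-1)/(4N)` per generation for `k` lineages in a
population of diploid size `N`); demographic events are epoch boundaries.
One mutation per locus is placed uniformly on the total branch length (the
fixed-segregating-sites scheme used by SNP-mode ABC simulators), so every
locus is biallelic; no recombination within loci, loci unlinked, no recurrent
mutation.  Loci whose pooled minor-allele frequency falls below the
configured floor (default 0.05, mirroring the data filter) are rejected and
the whole genealogy re-simulated — re-placing only the mutation would
condition the tree distribution incorrectly.

Diploids are formed by random union of each individual's two simulated genes
(the DIYABC convention for SNP genotypes); the derived-homozygote
count per population is drawn from the exact random-pairing distribution of
the carrier genes, which is valid because leaves within a population are
exchangeable.  An `autogamous` option instead makes each individual a doubled
haploid (observed heterozygosity exactly 0, as in this strictly selfing
species).  Allele-frequency-based statistics are unaffected by the choice;
observed-heterozygosity-based ones (the Weir–Cockerham correction terms)
change slightly.

The per-locus engine is a numba kernel (~25–40 µs per 214-gene genealogy);
reference tables of 2·10⁴ datasets × 500 loci build in ~10–15 minutes on one
core.  Verification: mean pairwise coalescence time within 3 Monte-Carlo SE
of `2N` in constant-size controls; total branch length matching `4N·H_{n-1}`;
mean/variance of TMRCA and branch length matching msprime on single-population
and two-population split models.

## Summary statistics and ABC

Eleven statistics summarize a dataset: mean expected heterozygosity of each
population (`H_E = 2p(1-p)` averaged over loci), the six pairwise multi-locus
Weir & Cockerham (1984) θ values (ratio-of-sums combining), and an admixture
coefficient — the least-squares solution of
`p_MIID ≈ ra·p_MID + (1-ra)·p_MIIW` over loci, clipped to [0, 1].  The
admixture statistic is computed for every dataset under both scenarios (it is
a statistic, not a model parameter); otherwise distances across scenarios
would not be comparable.

The statistic vector is total: a population pair with no FST-informative
locus (both populations monomorphic for the same allele everywhere — it
happens for degenerate prior corners such as a wild size of 10) gets pairwise
FST 0, "no measurable divergence", rather than an undefined value that would
corrupt table-wide distances.

Distances are Euclidean after dividing each statistic by its reference-table
MAD (mean/SD standardization available).  Model choice:

* *direct*: the scenario composition of the `n_closest` rows (default 500,
  the full-scale count; at reduced table sizes the evaluation keeps the
  full-scale acceptance *fraction* of 0.25%, since a looser fraction smooths
  the scenario posterior toward the prior and inflates error rates), with
  Wilson binomial intervals;
* *logistic*: weighted logistic regression of scenario label on the
  standardized observed-minus-simulated differences among the closest rows
  (default 10,000), Epanechnikov weights `1 - (d/d_max)²`, evaluated at zero
  difference; bootstrap CI over the selected rows.

Confidence is assessed with pseudo-observed datasets (pods): type I error of
a scenario is the share of its own pods where it is not the strict argmax
(ties count as errors — conservative); type II is the share of the other
scenario's pods where it is.  Parameter posteriors take the closest 1% of
the chosen scenario's rows and apply a local-linear regression adjustment:
parameters are logit-transformed to their prior range, regressed on the
standardized statistic differences with Epanechnikov weights, residual-
adjusted to zero difference and back-transformed; point and interval
summaries are weighted; the mode uses a weighted Gaussian KDE (Silverman
bandwidth).  Zero-spread statistics are excluded from distance and design;
a singular design falls back to the unadjusted rejection posterior with a
warning.  Model checking projects the observed statistics into the PCA of
the (standardized) table statistics and reports a Mahalanobis depth
percentile plus per-statistic tail probabilities, optionally repeated under
posterior re-simulation.

## Diversity, founder effects, LD

Allele frequencies use pairwise deletion.  Per locus: `H_E = 1 - Σp²`
(unbiased `2n/(2n-1)` correction optional; the plain form reproduces the
fixation-index pattern `F ≈ 1` of a selfing species with `H_O = 0`),
`N_E = 1/Σp²`, Shannon `I = -Σ p ln p`, `F = (H_E - H_O)/H_E` where defined.
The founder-effect reduction is `%r = 100·(H_EW - H_ED)/H_EW`, globally on
mean heterozygosities and locus-by-locus with classification into loss /
gain / no-change; loci with `H_EW = 0` are unclassifiable (their %r is
undefined or −∞) and counted separately.

LD is the composite r² — squared Pearson correlation of genotype codes over
samples non-missing at both loci (≥4 shared samples required) — which equals
haplotype r² when `H_O = 0`.  Chromosome-wise means average the off-diagonal
defined entries.

## Selection scans

**FST outliers.**  The null is a hierarchical island model: two groups
(wild, domesticated) of exchangeable demes (default 100 per group, deme size
100, per-lineage migration rate 0.05), with a fraction β of migrations
crossing groups.  β is calibrated by log-scale bisection so the mean
multi-locus FST of a calibration batch matches the observed value within
0.005 (the lower bracket is 10⁻⁴, which already yields FST ≈ 0.97; smaller β
only multiplies migration events).  Per-locus (heterozygosity, FST) points —
heterozygosity capped at 0.5 as for any biallelic locus — form the null
cloud.  Observed loci are flagged against per-heterozygosity-bin envelopes
(20 equal-count bins, under-populated bins merged): a locus flags high when
`(1 + #{null ≥ obs})/(n_null + 1) ≤ (1-ci)/2` within its bin.  Because
per-locus FST is discrete with heavy ties (a plain quantile envelope is
badly calibrated under ties), exact ties are broken by an O(10⁻⁹) uniform
dither applied identically to null and observed values — far below any real
FST difference — making the rank rule's size exact.  Calibration to ~1%
flags at `ci = 0.99` requires roughly ≥500 null points per bin (a 10⁴-locus
cloud); as `ci → 1` the rule flags nothing, reflecting the cloud's finite
resolution.

**LD-difference scan.**  Windows of loci (default 50, sliding step 1) are
scored by `Σᵢ |λ_A(i) - λ_B(i)|` over the descending-ordered eigenvalues of
the two populations' within-window r² matrices (undefined entries set to 0,
diagonal 1; windows with >50% undefined pairs skipped).  Scores are
standardized genome-wide; the top 5% are significant; overlapping significant
windows merge into regions.  Window-level permutation p-values (labels
shuffled between populations) are available but off by default — the top-
fraction threshold is the primary criterion.  Genes overlap regions by ≥1 bp
on half-open, 0-based (BED) intervals.

## Genotype I/O and filtering

VCF 4.x is read through cyvcf2 (multiallelic records skipped and counted;
unmapped samples labelled OTHER with a warning) and written as minimal VCF
4.2.  Filtering order is fixed: site filters (missingness > 0.10, MAF
< 0.05, monomorphic, QUAL ≤ 40, mean depth < 10 when depth is present), then
samples with > 0.10 missing, then the site filters once more — removing
samples changes site statistics, so one re-pass is made and all removal
counts are reported.  MAF uses non-missing genotypes only.  The quality
threshold applies to site QUAL (the upstream variant caller's per-site
score); genotype-level recalling is out of scope.

## Synthetic data: what it shows and what it does not

The generator reproduces the survey's data configurations — sample sizes 30/30/30/17
(ABC matrix) and a 270 × 4,779 full matrix over 11 chromosomes, MAF ≥ 0.05,
`H_O ≈ 0` under the autogamy option — and the block-LD fixtures plant known
LD differences for power checks.  It does not emulate genotyping error,
missingness structure from reduced-representation sequencing, physical
linkage within chromosomes (loci are unlinked, so chromosome-wise r² in
synthetic data reflects drift and sampling, not linkage maps), population
substructure beyond the four modelled pools, or selection.  Passing tests
therefore demonstrate the correctness and calibration of the estimators and
the distinguishability of the modelled scenarios — not properties of any
particular real dataset.

## Problem sizes

Reduced scales keep the pipeline practical on one core while leaving
Monte-Carlo error well inside the asserted tolerances: the scenario-
confidence evaluation uses a 20,000-row reference table at 500 loci with
200 pods per scenario (type I error of the admixture scenario ≈ 0.057, SE
≈ 0.016); parameter recovery uses the same table's scenario-2 half; the
outlier-null calibration uses a 12,000-locus cloud with 20 demes per group;
planted-LD power uses 50 replicates.  The analysis drivers under `analysis/`
run smaller versions (1,000-row tables, 250 loci) to stay interactive.

## Known limitations

* The coalescent engine samples one mutation per locus; it cannot produce
  invariant loci or multi-SNP haplotypes within a locus.
* The admixture coefficient is a frequency-moment estimator; with strong
  drift after admixture it is biased toward its nearest parent.
* The island-model null assumes equilibrium migration–drift balance, not a
  domestication bottleneck; it is the classical envelope null, used here as
  in the original analysis.
* The logistic model-choice CI is a bootstrap over selected rows; it ignores
  reference-table Monte-Carlo error, which matters for tables much smaller
  than 10⁴ rows.
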