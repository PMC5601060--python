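# limadom

Coalescent and ABC analysis of Lima bean (*Phaseolus lunatus*) domestication
— a tested re-implementation of the population-genetic pipeline behind the
question *how many times was the Lima bean domesticated in Mesoamerica?*,
runnable end to end on synthetic data generated by the package itself.

The package is for population geneticists who want to reproduce, probe, or
extend the analysis: a backwards-time coalescent simulator of two competing
domestication histories, approximate Bayesian computation for model choice
and parameter estimation, founder-effect and linkage-disequilibrium
statistics, and FST-outlier / LD-difference genome scans.

## The models and statistics

Two demographic scenarios are compared for the wild (W) and domesticated (D)
Mesoamerican gene pools MI and MII:

* **Scenario 1** — independent domestications: MID splits from MIW at *t2*,
  MIID from MIIW at *t1*, each through a founding bottleneck (*N2b* for
  *db1* generations; *N3b* for *db2*); the wild pools diverged at *t3*.
* **Scenario 2** — a single domestication (MID from MIW, bottleneck *N2b*,
  *db1*) followed by admixture: MIID forms at *t1* with a proportion *ra* of
  its ancestry from MID and 1 − *ra* from MIIW.

Each simulated dataset is a matrix of unlinked biallelic SNPs (one mutation
per genealogy, pooled MAF ≥ 0.05).  Eleven summary statistics — per-pool
mean expected heterozygosity H_E, six pairwise Weir–Cockerham F_ST values,
and a least-squares admixture coefficient — feed an ABC reference table.
Scenario posteriors come from the scenario composition of the closest
simulated datasets (direct approach) and from a weighted logistic regression
on observed-minus-simulated statistic differences; parameter posteriors from
the closest 1% with a local-linear regression adjustment.  Founder effects
are measured as %r = (H_EW − H_ED)/H_EW; selection signatures by an
island-model F_ST-outlier envelope and a windowed eigenvalue-difference
comparison of r² matrices between wild and domesticated samples.  Details
and numerical choices: [docs/methods.md](docs/methods.md).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data, writing tables to `results/`:

```sh
python analysis/01_simulate_data.py       # survey-shaped datasets
python analysis/02_diversity_founder_effects.py
python analysis/03_abc_model_choice.py    # ~3 min: 1,000-row reference table
python analysis/04_parameter_estimation.py
python analysis/05_selection_scans.py
```

Script 01 simulates, under scenario 2 with an admixture proportion
ra = 0.953 and a severe MI bottleneck (N2b = 498 founders for db1 = 2,870
generations, intensity k ≈ 0.17), the two survey-shaped matrices (107 × 2,527
autogamous ABC matrix; 270 × 4,779 full matrix) plus LD-block panels with a
true LD difference planted in block 3 of 5.  Script 02 then prints

```
MI founder effect: H_E wild 0.170 -> dom 0.014; global %r = 91.7%
  loci with diversity loss: 96.1% (mean loss 97%), gain: 3.9% (mean gain 162%)
```

— the domesticated MI pool has lost most of the wild pool's diversity: a
bottleneck this intense, run forward in pure simulation, erases even more
variation than the ~31% reduction such histories are invoked to explain.
Script 03 chooses between the scenarios (1,000-row table, 250 loci, ~30 s):

```
scenario posterior probabilities (truth: scenario 2, ra = 0.953):
                              scenario  direct_prob  logistic_prob
         1. independent domestications          0.0            0.0
2. single domestication with admixture          1.0            1.0

direct-approach error rates from 100 pods:
   type1  type2
1   0.00   0.12
2   0.12   0.00
```

— the admixture scenario is recovered with certainty at this strong planted
signal, and the pod-based error rates show the residual confusion sits
entirely in the admixture scenario, whose small-*ra* corner is genuinely
indistinguishable from independent domestication.  Script 04 estimates the
scenario-2 posterior (ra median 0.984 for a truth of 0.953; N2b median 129)
and derives the headline scalars (bottleneck intensity k = N2b/db1, map
density 123 Kb/SNP for 4,779 SNPs on a 587 Mb genome); its validation table
shows the ABC estimator beating the prior-only baseline on relative RMSE for
every parameter (e.g. 0.14 vs 3.8 for ra).  Script 05 runs both genome
scans: the F_ST outlier scan flags 1.4% of loci on this selection-free
simulation (a false-positive control at the 99% envelope), and the
LD-difference scan recovers exactly the planted block —

```
chrom  start_idx  end_idx  start_bp  end_bp  n_windows  max_std
    1         50       80     51000   80000          2     2.40
```

with 3 synthetic genes counted inside the significant region.

## Layout

```
src/limadom/     library: genotype I/O, popgen statistics, demography,
                 coalescent engine, fixtures, abc, scans, pipeline, CLI
analysis/        numbered narrative drivers (write to results/)
scripts/         acceptance.py
tests/           pytest suite (unit, property, and end-to-end checks)
docs/methods.md  models, assumptions, numerical choices, limitations
```

A `limadom` console command exposes the same steps
(`limadom simulate|filter|stats|abc|scan|report`); see `limadom --help`.
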