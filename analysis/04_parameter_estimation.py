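"""Posterior parameter estimation, model checking, and derived scalars.

Loads the reference table and observed statistics from script 03, estimates
the demographic parameter posteriors under each scenario (closest 2% of that
scenario's rows, local-linear adjustment), runs the predictive model check,
validates estimator bias/coverage with 50 pods, and derives the bottleneck
intensity k = N2b/db1 and the genome-wide SNP map density.  Writes
results/tables/posterior_scenario{1,2}.tsv, validation.tsv and derived.json.
"""

import json
from pathlib import Path

import numpy as np

from limadom import abc as A
from limadom.pipeline import derived_quantities

OUT = Path("results/tables")
SEED = 271_828


def main() -> None:
    table = A.ReferenceTable.load(OUT / "reference_table.tsv")
    with open(OUT / "observed_stats.json") as fh:
        loaded = json.load(fh)
    obs = np.array([loaded[s] for s in A.STAT_NAMES])

    posts = {}
    for scenario in (1, 2):
        post = A.estimate_parameters(table, obs, scenario, fraction=0.2)
        post.table.round(4).to_csv(OUT / f"posterior_scenario{scenario}.tsv", sep="\t")
        posts[scenario] = post
    t2 = posts[2].table
    print("scenario-2 posterior (selected parameters):")
    print(t2.loc[["N1", "N2b", "t1", "t2", "db1", "ra"],
                 ["mean", "median", "q025", "q975"]].round(3).to_string())

    check = A.model_check(table, obs, posterior=posts[2], n_pp=100,
                          rng=np.random.default_rng(SEED))
    print(f"\nmodel check: observed depth percentile (prior predictive) = "
          f"{check['prior']['depth_percentile']:.2f}; "
          f"flagged stats: {list(check['prior']['flagged_stats']) or 'none'}")

    validation = A.validate_estimation(
        table, table.priors, table.config, scenario=2, n_pods=50,
        rng=np.random.default_rng(SEED + 1), fraction=0.2,
    )
    validation.round(3).to_csv(OUT / "validation.tsv", sep="\t")
    print("\nestimator validation (50 pods; ABC vs prior-only):")
    print(validation.loc[["N1", "N2b", "ra"]].round(3).to_string())

    derived = derived_quantities(
        N2b=t2.loc["N2b", "mean"], db1=t2.loc["db1", "mean"],
        N1=t2.loc["N1", "mean"], genome_size_bp=587e6, n_snps=4_779,
    )
    with open(OUT / "derived.json", "w") as fh:
        json.dump(derived, fh, indent=2)
    print(f"\nderived: bottleneck intensity k = {derived['bottleneck_intensity']:.2f}; "
          f"map density = {derived['map_density_kb']:.0f} Kb/SNP; "
          f"founder size reduction = {derived['percent_size_reduction']:.1f}%")


if __name__ == "__main__":
    main()
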