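"""Simulate the survey-shaped synthetic datasets every later step consumes.

Emulates three data configurations:
  (a) the ABC matrix — 107 accessions (30 wild MI, 30 dom MI, 30 wild MII,
      17 dom MII) x 2,527 unlinked SNPs with pooled MAF >= 0.05 and zero
      observed heterozygosity (autogamous species);
  (b) a full-matrix analogue — 270 accessions x 4,779 SNPs spread over 11
      chromosomes;
  (c) LD-block haplotype panels for the LD-difference scan, with a true
      difference planted in one known block.

Writes VCFs, population maps and truth sidecars under results/data/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from limadom.coalescent import simulate_snp_dataset
from limadom.demography import DemographicParameters, SampleConfig
from limadom.fixtures import simulate_ld_haplotypes
from limadom.genotype import write_popmap, write_vcf

OUT = Path("results/data")
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20_260_920

# a plausible admixture history: values near the scenario-2 posterior means
TRUTH = DemographicParameters(
    N1=204_000, N2=1_370_000, N3=592_000, N4=346_000, N2b=498, N3b=2505,
    t1=6_540, t2=7_670, t3=581_000, db1=2_870, db2=2_000, ra=0.953, scenario=2,
)


def main() -> None:
    rng = np.random.default_rng(SEED)

    # (a) ABC matrix: autogamous, MAF-filtered by construction
    abc_cfg = SampleConfig(n_loci=2_527, autogamous=True)
    gm_abc = simulate_snp_dataset(TRUTH, abc_cfg, rng)
    write_vcf(gm_abc, OUT / "abc_matrix.vcf")
    write_popmap(dict(zip(gm_abc.samples["sample"], gm_abc.samples["population"])),
                 OUT / "abc_matrix.popmap.tsv")
    het = (gm_abc.genotypes == 1).mean()
    print(f"(a) ABC matrix: {gm_abc.n_samples} x {gm_abc.n_loci}, H_O = {het:.4f}")

    # (b) full-matrix analogue: 270 samples, 4,779 SNPs over 11 chromosomes
    full_cfg = SampleConfig(n_MIW=80, n_MID=75, n_MIIW=60, n_MIID=55,
                            n_loci=4_779, autogamous=True)
    gm_full = simulate_snp_dataset(TRUTH, full_cfg, rng)
    chroms = np.array([f"Chr{1 + i % 11:02d}" for i in range(gm_full.n_loci)])
    chroms.sort()
    gm_full.loci["chrom"] = chroms
    gm_full.loci["pos"] = np.concatenate(
        [np.arange(1, (chroms == c).sum() + 1) * 1000 for c in pd.unique(chroms)]
    )
    write_vcf(gm_full, OUT / "full_matrix.vcf")
    write_popmap(dict(zip(gm_full.samples["sample"], gm_full.samples["population"])),
                 OUT / "full_matrix.popmap.tsv")
    print(f"(b) full matrix: {gm_full.n_samples} x {gm_full.n_loci} on 11 chromosomes")

    # (c) LD-block panels with a planted difference in block 2 (0-based)
    gm_wild, gm_dom = simulate_ld_haplotypes(
        [(25, 1.0)] * 5, n_per_pop=60, divergence=0.9, diverged_blocks=(2,), rng=rng
    )
    write_vcf(gm_wild, OUT / "ld_wild.vcf")
    write_vcf(gm_dom, OUT / "ld_dom.vcf")
    print("(c) LD panels: 125 loci in 5 blocks; true LD difference in block 3 of 5")

    with open(OUT / "truth.json", "w") as fh:
        json.dump({"seed": SEED, "params": TRUTH.as_dict(),
                   "ld_diverged_block": 2}, fh, indent=2)


if __name__ == "__main__":
    main()
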