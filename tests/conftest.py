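import numpy as np
import pandas as pd
import pytest

from limadom.genotype import GenotypeMatrix


def make_matrix(genotypes, populations, chrom=None, pos=None, qual=None):
    """Small GenotypeMatrix from a nested list of codes and per-sample labels."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_loci = g.shape
    if chrom is None:
        chrom = ["1"] * n_loci
    if pos is None:
        pos = list(range(1, n_loci + 1))
    samples = pd.DataFrame(
        {"sample": [f"s{i}" for i in range(n_samples)], "population": populations}
    )
    loci = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": ["A"] * n_loci, "alt": ["T"] * n_loci}
    )
    return GenotypeMatrix(genotypes=g, loci=loci, samples=samples,
                          qual=None if qual is None else np.asarray(qual, float))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def toy_vcf(tmp_path):
    """3-sample, 2-site VCF with a heterozygote and a missing genotype."""
    text = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\n"
        "1\t100\t.\tA\tT\t50\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        "1\t200\t.\tG\tC\t60\tPASS\t.\tGT\t1/1\t./.\t0/0\n"
    )
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    return path
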