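"""Parametric fixture generators: frequency-planted genotypes and LD blocks.

These complement the coalescent engine with directly-controlled synthetic
data: :func:`simulate_fixture_dataset` draws genotypes binomially from stated
per-population allele frequencies (for unit-testing estimators against known
truth), and :func:`simulate_ld_haplotypes` builds block-structured haplotypes
with tunable within-block LD and a divergence knob that plants true LD
differences between two populations at known windows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix


def _matrix(g, pops_per_sample, chrom=None, pos=None) -> GenotypeMatrix:
    n_samples, n_loci = g.shape
    if chrom is None:
        chrom = np.repeat("1", n_loci)
    if pos is None:
        pos = np.arange(1, n_loci + 1) * 1000
    counts: dict[str, int] = {}
    names = []
    for p in pops_per_sample:
        counts[p] = counts.get(p, 0) + 1
        names.append(f"{p}_{counts[p]:03d}")
    return GenotypeMatrix(
        genotypes=g.astype(np.int8),
        loci=pd.DataFrame(
            {"chrom": chrom, "pos": pos, "ref": np.repeat("A", n_loci), "alt": np.repeat("T", n_loci)}
        ),
        samples=pd.DataFrame({"sample": names, "population": pops_per_sample}),
    )


def simulate_fixture_dataset(
    freqs: dict[str, np.ndarray],
    n_per_pop: dict[str, int],
    autogamous: bool = False,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Genotypes drawn binomially from per-population allele frequencies.

    ``freqs`` maps population label -> per-locus alternate-allele frequency
    (all vectors the same length).  Under ``autogamous`` each individual is a
    doubled haploid draw (observed heterozygosity exactly 0); otherwise
    genotypes are Binomial(2, p).  ``missing_rate`` plants missing genotypes
    independently at that rate.
    """
    rng = rng or np.random.default_rng()
    pops = list(freqs)
    n_loci = len(next(iter(freqs.values())))
    blocks = []
    labels: list[str] = []
    for pop in pops:
        p = np.asarray(freqs[pop], dtype=float)
        if p.shape != (n_loci,):
            raise ValueError("all frequency vectors must have the same length")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        n = n_per_pop[pop]
        if autogamous:
            g = 2 * rng.binomial(1, p, size=(n, n_loci))
        else:
            g = rng.binomial(2, p, size=(n, n_loci))
        blocks.append(g)
        labels.extend([pop] * n)
    g = np.concatenate(blocks, axis=0).astype(np.int8)
    if missing_rate > 0:
        g[rng.random(g.shape) < missing_rate] = MISSING
    return _matrix(g, labels)


def simulate_ld_haplotypes(
    block_spec: list[tuple[int, float]],
    n_per_pop: int,
    divergence: float = 0.0,
    diverged_blocks: tuple[int, ...] = (),
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Two block-structured haplotype populations with plantable LD differences.

    Haplotypes are built by a copying process.  Each block has a founder
    haplotype ``h`` and its complement ``1 - h``; an individual copies one of
    the two (uniformly) with probability equal to the block's r^2 target
    ``rho`` and otherwise draws its block alleles independently.  With
    ``rho = 1`` every within-block locus pair is perfectly correlated
    (r^2 = 1); blocks are copied independently, so between-block LD is ~0.

    ``divergence`` in (0, 1] perturbs population B inside ``diverged_blocks``:
    with that probability per individual the block is replaced by independent
    noise, degrading B's within-block LD and creating a true LD difference at
    those (known) windows.  Individuals are doubled haploids (codes 0/2), as
    in a selfing species.
    """
    rng = rng or np.random.default_rng()
    n_loci = sum(n for n, _ in block_spec)
    founder = rng.integers(0, 2, size=n_loci)
    out = []
    for pop_idx in range(2):
        hap = np.empty((n_per_pop, n_loci), dtype=np.int64)
        start = 0
        for b, (blen, rho) in enumerate(block_spec):
            if not 0.0 <= rho <= 1.0:
                raise ValueError("within-block r2 target must lie in [0, 1]")
            sl = slice(start, start + blen)
            for i in range(n_per_pop):
                if rng.random() < rho:
                    if rng.random() < 0.5:
                        hap[i, sl] = founder[sl]
                    else:
                        hap[i, sl] = 1 - founder[sl]
                else:
                    hap[i, sl] = rng.integers(0, 2, size=blen)
                if (
                    pop_idx == 1
                    and b in diverged_blocks
                    and rng.random() < divergence
                ):
                    hap[i, sl] = rng.integers(0, 2, size=blen)
            start += blen
        g = 2 * hap
        out.append(_matrix(g, ["W" if pop_idx == 0 else "D"] * n_per_pop))
    return out[0], out[1]
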