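"""Backwards-time coalescent simulation of unlinked SNP loci.

Each locus is an independent genealogy of the sampled gene copies under the
scenario's piecewise-constant demography: within a population of current
diploid size ``N`` each pair of lineages coalesces at rate ``1/(2N)`` per
generation (total rate ``k(k-1)/(4N)``); demographic events (resizes, merges,
admixture splits) are epoch boundaries, with exponential waiting times inside
each epoch.  One mutation per locus is placed uniformly on the total branch
length (fixed-segregating-sites SNP scheme), so every locus is biallelic by
construction; loci whose pooled minor-allele frequency falls below the
configured threshold are rejected and re-simulated (bounded retries),
mirroring the MAF filter applied to the observed data.

Diploid genotypes are formed by random union of the two simulated genes of
each individual; under the ``autogamous`` option each individual instead
carries two identical copies of a single simulated gene, giving observed
heterozygosity exactly zero as in a strictly selfing species.

The per-locus engine is a numba kernel; a generator-seeded wrapper exposes it
through :func:`simulate_snp_dataset`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numba import njit

from .demography import (
    DemographicParameters,
    SampleConfig,
    POP_NAMES,
    build_event_table,
)
from .genotype import GenotypeMatrix

_BIG = 1.0e300


@njit(cache=True, fastmath=True)
def _sim_tree(gene_counts, sizes0, times, kinds, ev_a, ev_b, ev_c, ev_par,
              birth, death, counts, mem, kpop, sizes):
    """Simulate one genealogy; fills edge records, returns (root, n_edges, tmrca).

    Per-population coalescence rates k(k-1)/(4N) are maintained incrementally
    (only the population touched by an event changes) with a full re-sync
    whenever float drift makes the running total inconsistent.
    """
    npop = gene_counts.shape[0]
    inv4N = np.empty(npop)
    rate = np.empty(npop)
    n_total = 0
    for p in range(npop):
        n_total += gene_counts[p]
        sizes[p] = sizes0[p]
        inv4N[p] = 0.25 / sizes0[p]
        kpop[p] = 0
    lid = 0
    for p in range(npop):
        for _ in range(gene_counts[p]):
            birth[lid] = 0.0
            for q in range(npop):
                counts[lid, q] = 0
            counts[lid, p] = 1
            mem[p, kpop[p]] = lid
            kpop[p] += 1
            lid += 1
    R = 0.0
    for p in range(npop):
        k = kpop[p]
        rate[p] = k * (k - 1.0) * inv4N[p]
        R += rate[p]
    t = 0.0
    ev_idx = 0
    n_ev = times.shape[0]
    n_active = n_total
    while n_active > 1 and ev_idx < n_ev:
        t_ev = times[ev_idx]
        if R <= 0.0:
            t_next = _BIG
        else:
            t_next = t + np.random.exponential(1.0 / R)
        if t_next >= t_ev:
            t = t_ev
            kind = kinds[ev_idx]
            a = ev_a[ev_idx]
            b = ev_b[ev_idx]
            c = ev_c[ev_idx]
            par = ev_par[ev_idx]
            if kind == 0:  # resize
                sizes[a] = par
                inv4N[a] = 0.25 / par
            elif kind == 1:  # merge a -> b
                for i in range(kpop[a]):
                    mem[b, kpop[b]] = mem[a, i]
                    kpop[b] += 1
                kpop[a] = 0
            else:  # admix: each lineage of a -> b w.p. par, else -> c
                for i in range(kpop[a]):
                    lin = mem[a, i]
                    if np.random.random() < par:
                        mem[b, kpop[b]] = lin
                        kpop[b] += 1
                    else:
                        mem[c, kpop[c]] = lin
                        kpop[c] += 1
                kpop[a] = 0
            ev_idx += 1
            R = 0.0
            for p in range(npop):
                k = kpop[p]
                rate[p] = k * (k - 1.0) * inv4N[p]
                R += rate[p]
            continue
        t = t_next
        u = np.random.random() * R
        acc = 0.0
        psel = -1
        for p in range(npop):
            acc += rate[p]
            if u < acc:
                psel = p
                break
        if psel < 0 or kpop[psel] < 2:  # float drift: re-sync and retry pick
            R = 0.0
            psel = -1
            for p in range(npop):
                k = kpop[p]
                rate[p] = k * (k - 1.0) * inv4N[p]
                R += rate[p]
            for p in range(npop):
                if kpop[p] > 1:
                    psel = p
        k = kpop[psel]
        i = np.random.randint(0, k)
        j = np.random.randint(0, k - 1)
        if j >= i:
            j += 1
        la = mem[psel, i]
        lb = mem[psel, j]
        death[la] = t
        death[lb] = t
        birth[lid] = t
        for q in range(npop):
            counts[lid, q] = counts[la, q] + counts[lb, q]
        if i > j:
            i, j = j, i
        mem[psel, i] = lid
        mem[psel, j] = mem[psel, k - 1]
        kpop[psel] = k - 1
        R -= rate[psel]
        rate[psel] = (k - 1.0) * (k - 2.0) * inv4N[psel]
        R += rate[psel]
        lid += 1
        n_active -= 1
    # final phase: past every demographic event, a single panmictic population
    if n_active > 1:
        psel = -1
        for p in range(npop):
            if kpop[p] > 0:
                if psel >= 0:
                    raise RuntimeError("lineages cannot coalesce: malformed event table")
                psel = p
        i4 = inv4N[psel]
        k = kpop[psel]
        while k > 1:
            t += np.random.exponential(1.0 / (k * (k - 1.0) * i4))
            idx = int(np.random.random() * k * (k - 1))
            i = idx // (k - 1)
            j = idx % (k - 1)
            if j >= i:
                j += 1
            la = mem[psel, i]
            lb = mem[psel, j]
            death[la] = t
            death[lb] = t
            birth[lid] = t
            for q in range(npop):
                counts[lid, q] = counts[la, q] + counts[lb, q]
            if i > j:
                i, j = j, i
            mem[psel, i] = lid
            mem[psel, j] = mem[psel, k - 1]
            k -= 1
            lid += 1
        kpop[psel] = 1
        n_active = 1
    root = -1
    for p in range(npop):
        if kpop[p] > 0:
            root = mem[p, 0]
    return root, lid, t


@njit(cache=True)
def _simulate_dataset_counts(seed, n_loci, gene_counts, sizes0, times, kinds,
                             ev_a, ev_b, ev_c, ev_par, maf_min, max_tries):
    """Derived-allele counts per (locus, population); one mutation per tree.

    Returns (counts array, n_rejected); n_rejected = -1 signals that the MAF
    retry cap was exhausted at some locus.
    """
    np.random.seed(seed)
    npop = gene_counts.shape[0]
    n_total = 0
    for p in range(npop):
        n_total += gene_counts[p]
    m = 2 * n_total
    birth = np.empty(m)
    death = np.empty(m)
    counts = np.empty((m, npop), np.int32)
    mem = np.empty((npop, n_total), np.int32)
    kpop = np.empty(npop, np.int64)
    sizes = np.empty(npop)
    out = np.zeros((n_loci, npop), np.int64)
    n_rejected = 0
    min_minor = maf_min * n_total
    for l in range(n_loci):
        ok = False
        for _ in range(max_tries):
            root, lid, _ = _sim_tree(gene_counts, sizes0, times, kinds,
                                     ev_a, ev_b, ev_c, ev_par,
                                     birth, death, counts, mem, kpop, sizes)
            total_len = 0.0
            for e in range(lid):
                if e != root:
                    total_len += death[e] - birth[e]
            u = np.random.random() * total_len
            acc = 0.0
            sel = -1
            for e in range(lid):
                if e == root:
                    continue
                acc += death[e] - birth[e]
                if u < acc:
                    sel = e
                    break
            if sel < 0:  # float round-off: take the last closed edge
                sel = lid - 1 if lid - 1 != root else lid - 2
            d = 0
            for q in range(npop):
                d += counts[sel, q]
            minor = d if d < n_total - d else n_total - d
            if minor >= min_minor:
                for q in range(npop):
                    out[l, q] = counts[sel, q]
                ok = True
                break
            n_rejected += 1
        if not ok:
            return out, -1
    return out, n_rejected


@njit(cache=True)
def _tree_stats(seed, n_loci, gene_counts, sizes0, times, kinds,
                ev_a, ev_b, ev_c, ev_par):
    """Per-locus (tmrca, total branch length) — instrumentation for oracles."""
    np.random.seed(seed)
    npop = gene_counts.shape[0]
    n_total = 0
    for p in range(npop):
        n_total += gene_counts[p]
    m = 2 * n_total
    birth = np.empty(m)
    death = np.empty(m)
    counts = np.empty((m, npop), np.int32)
    mem = np.empty((npop, n_total), np.int32)
    kpop = np.empty(npop, np.int64)
    sizes = np.empty(npop)
    out = np.empty((n_loci, 2))
    for l in range(n_loci):
        root, lid, tmrca = _sim_tree(gene_counts, sizes0, times, kinds,
                                     ev_a, ev_b, ev_c, ev_par,
                                     birth, death, counts, mem, kpop, sizes)
        total_len = 0.0
        for e in range(lid):
            if e != root:
                total_len += death[e] - birth[e]
        out[l, 0] = tmrca
        out[l, 1] = total_len
    return out


@njit(cache=True)
def _sample_hom_counts(seed, derived, diploid_counts, autogamous):
    """Number of derived-homozygous individuals per (locus, population).

    Within each population the carriers of the derived allele are an
    exchangeable random subset of the sampled genes; under random union of
    gametes the number of derived-derived pairs follows the random perfect
    matching distribution, sampled sequentially (each unpaired derived gene
    pairs with a derived partner with probability (d-1)/(g-1) among the g-1
    remaining genes).  Under autogamy every carrier gene yields a
    derived-homozygous individual.  Heterozygote counts follow as
    ``derived - 2 * hom``.
    """
    np.random.seed(seed)
    n_loci = derived.shape[0]
    npop = diploid_counts.shape[0]
    hom = np.zeros((n_loci, npop), np.int64)
    for l in range(n_loci):
        for p in range(npop):
            c = derived[l, p]
            if autogamous:
                hom[l, p] = c
            else:
                rem_d = c
                rem = 2 * diploid_counts[p]
                n_hom = 0
                while rem_d > 0:
                    if np.random.random() * (rem - 1) < rem_d - 1:
                        n_hom += 1
                        rem_d -= 2
                    else:
                        rem_d -= 1
                    rem -= 2
                hom[l, p] = n_hom
    return hom


@njit(cache=True)
def _lay_out_genotypes(seed, derived, hom, diploid_counts, autogamous):
    """Assign genotype codes to individuals (random order within population)."""
    np.random.seed(seed)
    n_loci = derived.shape[0]
    npop = diploid_counts.shape[0]
    n_ind = 0
    for p in range(npop):
        n_ind += diploid_counts[p]
    g = np.zeros((n_ind, n_loci), np.int8)
    for l in range(n_loci):
        off = 0
        for p in range(npop):
            s = diploid_counts[p]
            n_hom = hom[l, p]
            n_het = 0 if autogamous else derived[l, p] - 2 * n_hom
            for i in range(n_hom):
                g[off + i, l] = 2
            for i in range(n_hom, n_hom + n_het):
                g[off + i, l] = 1
            # Fisher-Yates shuffle within the population
            for i in range(s - 1, 0, -1):
                j = np.random.randint(0, i + 1)
                tmp = g[off + i, l]
                g[off + i, l] = g[off + j, l]
                g[off + j, l] = tmp
            off += s
    return g


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def simulate_derived_counts(
    params: DemographicParameters,
    config: SampleConfig,
    rng: np.random.Generator,
    max_tries: int = 1000,
):
    """Derived-allele counts per (locus, population) for one dataset.

    This is the allele-frequency core of :func:`simulate_snp_dataset`; the
    counts refer to the sampled genes (2 per diploid, 1 under autogamy).
    """
    if not params.validate():
        raise ValueError("invalid parameters for scenario")
    sizes0, times, kinds, ev_a, ev_b, ev_c, ev_par = build_event_table(params)
    gene_counts = config.gene_counts()
    out, n_rej = _simulate_dataset_counts(
        _kernel_seed(rng), config.n_loci, gene_counts, sizes0, times, kinds,
        ev_a, ev_b, ev_c, ev_par, config.maf_min, max_tries,
    )
    if n_rej < 0:
        raise RuntimeError(
            f"MAF rejection exceeded {max_tries} retries per locus "
            f"(maf_min={config.maf_min}, n_genes={gene_counts.sum()})"
        )
    return out, n_rej


def _matrix_from_genotypes(g: np.ndarray, config: SampleConfig) -> GenotypeMatrix:
    n_loci = g.shape[1]
    names = []
    pops = []
    for p, n in zip(POP_NAMES, config.diploid_counts):
        for i in range(n):
            names.append(f"{p}_{i:03d}")
            pops.append(p)
    loci = pd.DataFrame(
        {
            "chrom": np.repeat("1", n_loci),
            "pos": np.arange(1, n_loci + 1) * 1000,
            "ref": np.repeat("A", n_loci),
            "alt": np.repeat("T", n_loci),
        }
    )
    return GenotypeMatrix(
        genotypes=g,
        loci=loci,
        samples=pd.DataFrame({"sample": names, "population": pops}),
    )


def simulate_genotype_counts(
    params: DemographicParameters,
    config: SampleConfig,
    rng: np.random.Generator,
    max_tries: int = 1000,
):
    """Per-(locus, population) derived-allele and derived-homozygote counts.

    These two count matrices are sufficient statistics for every per-locus
    quantity used downstream (allele frequency, observed and expected
    heterozygosity); :func:`simulate_snp_dataset` only adds the assignment of
    genotype labels to individuals.
    """
    derived, _ = simulate_derived_counts(params, config, rng, max_tries=max_tries)
    hom = _sample_hom_counts(
        _kernel_seed(rng), derived, config.diploid_counts, config.autogamous
    )
    return derived, hom


def simulate_snp_dataset(
    params: DemographicParameters,
    config: SampleConfig,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> GenotypeMatrix:
    """Simulate one unlinked-SNP genotype matrix under a domestication scenario.

    Loci are placed on a single nominal chromosome at 1 kb spacing (they are
    unlinked by construction — each has an independent genealogy).
    """
    derived, hom = simulate_genotype_counts(params, config, rng, max_tries=max_tries)
    g = _lay_out_genotypes(
        _kernel_seed(rng), derived, hom, config.diploid_counts, config.autogamous
    )
    return _matrix_from_genotypes(g, config)


def simulate_tree_stats(
    params: DemographicParameters,
    config: SampleConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_loci, 2) array of per-locus (TMRCA, total branch length).

    Used to check the engine against coalescent theory and independent
    simulators; no mutations are placed.
    """
    sizes0, times, kinds, ev_a, ev_b, ev_c, ev_par = build_event_table(params)
    return _tree_stats(
        _kernel_seed(rng), config.n_loci, config.gene_counts(), sizes0, times,
        kinds, ev_a, ev_b, ev_c, ev_par,
    )


def simulate_split_tree_stats(
    n_genes_a: int,
    n_genes_b: int,
    size_a: float,
    size_b: float,
    t_split: float,
    size_anc: float,
    n_loci: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Tree stats for a two-population split model (oracle-comparison helper).

    Two populations of diploid sizes ``size_a``/``size_b`` merge ``t_split``
    generations ago into an ancestor of size ``size_anc``.
    """
    gene_counts = np.array([n_genes_a, n_genes_b], dtype=np.int64)
    sizes0 = np.array([float(size_a), float(size_b)])
    times = np.array([t_split, t_split])
    kinds = np.array([1, 0], dtype=np.int64)       # merge B->A, then resize A
    ev_a = np.array([1, 0], dtype=np.int64)
    ev_b = np.array([0, -1], dtype=np.int64)
    ev_c = np.array([-1, -1], dtype=np.int64)
    ev_par = np.array([0.0, float(size_anc)])
    return _tree_stats(
        _kernel_seed(rng), n_loci, gene_counts, sizes0, times, kinds,
        ev_a, ev_b, ev_c, ev_par,
    )


def simulate_constant_size_tree_stats(
    n_genes: int, diploid_size: float, n_loci: int, rng: np.random.Generator
) -> np.ndarray:
    """Tree stats for a single constant-size population (control model)."""
    gene_counts = np.array([n_genes], dtype=np.int64)
    sizes0 = np.array([float(diploid_size)])
    empty_i = np.empty(0, dtype=np.int64)
    empty_f = np.empty(0, dtype=np.float64)
    return _tree_stats(
        _kernel_seed(rng), n_loci, gene_counts, sizes0, empty_f, empty_i,
        empty_i, empty_i, empty_i, empty_f,
    )
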