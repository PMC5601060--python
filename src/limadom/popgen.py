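"""Diversity, founder-effect, FST and linkage-disequilibrium statistics.

All estimators work on unphased biallelic genotype codes.  Allele frequencies
use pairwise deletion (non-missing genotypes only).  Expected heterozygosity
defaults to the plain ``1 - sum(p^2)`` form; an unbiased small-sample
correction ``2n/(2n-1)`` is available as an option.  FST is the Weir &
Cockerham (1984) theta with ratio-of-sums multi-locus combining; Nei's G_ST
is available for sensitivity analyses.  LD is the composite r-squared of
genotype codes, which for a fully homozygous (autogamous) sample equals the
haplotype r-squared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix


def allele_frequencies(gm: GenotypeMatrix, population: str) -> np.ndarray:
    """Per-locus alternate-allele frequency in one population.

    Loci where every genotype is missing are returned as NaN (undefined).
    """
    mask = gm.population_mask(population)
    g = gm.genotypes[mask]
    miss = g == MISSING
    n_nonmiss = (~miss).sum(axis=0)
    alt = np.where(miss, 0, g).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_nonmiss > 0, alt / (2.0 * np.maximum(n_nonmiss, 1)), np.nan)
    return p


def _per_locus_stats(g: np.ndarray, unbiased: bool = False):
    """Per-locus (p, H_E, H_O, n_nonmiss) for a genotype sub-matrix."""
    miss = g == MISSING
    n = (~miss).sum(axis=0).astype(float)
    alt = np.where(miss, 0, g).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)
        he = 1.0 - (p**2 + (1.0 - p) ** 2)
        if unbiased:
            he = np.where(n > 0.5, 2.0 * n / (2.0 * n - 1.0) * he, np.nan)
        ho = np.where(n > 0, (g == 1).sum(axis=0) / np.maximum(n, 1), np.nan)
    return p, he, ho, n


@dataclass
class DiversityPanel:
    """Per-population diversity indices (means over loci) plus per-locus H_E."""

    table: pd.DataFrame          # rows = populations; columns N, P, N_A, N_E, I, H_O, H_E, F
    he_per_locus: pd.DataFrame   # loci x populations expected heterozygosity


def diversity_panel(
    gm: GenotypeMatrix, populations: list[str], unbiased: bool = False
) -> DiversityPanel:
    """Diversity indices per population.

    Per locus: ``H_E = 1 - sum(p^2)``, ``N_E = 1 / sum(p^2)``,
    ``I = -sum(p ln p)`` with ``0 ln 0 := 0``, ``H_O`` = fraction heterozygous
    among non-missing, ``F = (H_E - H_O)/H_E`` where ``H_E > 0``.  Panel
    entries are means over loci; ``P`` is the percentage of loci polymorphic
    (0 < p < 1) within the population.
    """
    if gm.n_loci == 0:
        raise ValueError("empty genotype matrix")
    rows = {}
    he_cols = {}
    for pop in populations:
        g = gm.genotypes[gm.population_mask(pop)]
        p, he, ho, n = _per_locus_stats(g, unbiased=unbiased)
        q = 1.0 - p
        poly = (p > 0) & (p < 1)
        na = np.where(np.isnan(p), np.nan, np.where(poly, 2.0, 1.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            ne = 1.0 / (p**2 + q**2)
            i1 = np.where(p > 0, -p * np.log(np.maximum(p, 1e-300)), 0.0)
            i2 = np.where(q > 0, -q * np.log(np.maximum(q, 1e-300)), 0.0)
            shannon = np.where(np.isnan(p), np.nan, i1 + i2)
            f = np.where(he > 0, (he - ho) / he, np.nan)
        defined = ~np.isnan(p)
        rows[pop] = {
            "N": float(np.nanmean(n)) if np.isfinite(n).any() else np.nan,
            "P": 100.0 * float(poly[defined].mean()) if defined.any() else np.nan,
            "N_A": float(np.nanmean(na)),
            "N_E": float(np.nanmean(ne)),
            "I": float(np.nanmean(shannon)),
            "H_O": float(np.nanmean(ho)),
            "H_E": float(np.nanmean(he)),
            "F": float(np.nanmean(f)) if np.isfinite(f).any() else np.nan,
        }
        he_cols[pop] = he
    table = pd.DataFrame(rows).T[["N", "P", "N_A", "N_E", "I", "H_O", "H_E", "F"]]
    return DiversityPanel(table=table, he_per_locus=pd.DataFrame(he_cols))


def percent_reduction(he_wild: float, he_dom: float) -> float:
    """Founder-effect reduction %r = 100 * (H_EW - H_ED) / H_EW."""
    if he_wild <= 0:
        raise ValueError("wild expected heterozygosity must be positive")
    return 100.0 * (he_wild - he_dom) / he_wild


@dataclass
class ReductionReport:
    global_r: float
    per_locus_r: np.ndarray      # NaN where undefined (H_EW = 0)
    share_positive: float        # % of classified loci with diversity loss
    share_negative: float
    share_zero: float
    mean_reduction_among_positive: float
    mean_increase_among_negative: float
    n_undefined: int             # loci with H_EW = 0 (H_ED > 0 counted here)


def per_locus_reduction(gm: GenotypeMatrix, wild: str, dom: str) -> ReductionReport:
    """Locus-by-locus founder-effect report.

    Loci with H_EW = 0 cannot be classified by %r (the ratio is undefined or
    -inf); they are counted separately in ``n_undefined``.  Shares are
    percentages of the classified loci and sum to 100.
    """
    _, he_w, _, _ = _per_locus_stats(gm.genotypes[gm.population_mask(wild)])
    _, he_d, _, _ = _per_locus_stats(gm.genotypes[gm.population_mask(dom)])
    ok = np.isfinite(he_w) & np.isfinite(he_d)
    classified = ok & (he_w > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(classified, 100.0 * (he_w - he_d) / np.where(he_w > 0, he_w, np.nan), np.nan)
    pos = classified & (r > 0)
    neg = classified & (r < 0)
    zero = classified & (r == 0)
    n_cls = int(classified.sum())
    if n_cls == 0:
        raise ValueError("no classifiable loci (H_EW = 0 everywhere)")
    mean_w = float(he_w[ok].mean())
    mean_d = float(he_d[ok].mean())
    return ReductionReport(
        global_r=percent_reduction(mean_w, mean_d),
        per_locus_r=r,
        share_positive=100.0 * pos.sum() / n_cls,
        share_negative=100.0 * neg.sum() / n_cls,
        share_zero=100.0 * zero.sum() / n_cls,
        mean_reduction_among_positive=float(r[pos].mean()) if pos.any() else np.nan,
        mean_increase_among_negative=float(-r[neg].mean()) if neg.any() else np.nan,
        n_undefined=int((ok & ~classified).sum()),
    )


def wc_components(pA, hA, nA, pB, hB, nB):
    """Weir & Cockerham (1984) two-population per-locus variance components.

    Arguments are per-locus arrays: alternate-allele frequency ``p``, observed
    heterozygote fraction ``h`` and genotyped sample count ``n`` for each
    population.  Returns ``(a, b, c)`` — among-population, among-individual
    and within-individual components — NaN where undefined (<2 samples).
    """
    pA, hA, nA, pB, hB, nB = (np.asarray(x, dtype=float) for x in (pA, hA, nA, pB, hB, nB))
    r = 2.0
    ok = (nA >= 2) & (nB >= 2) & np.isfinite(pA) & np.isfinite(pB)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (nA + nB) / r
        nc = (r * nbar - (nA**2 + nB**2) / (r * nbar)) / (r - 1.0)
        pbar = (nA * pA + nB * pB) / (r * nbar)
        s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (nA * hA + nB * hB) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    for arr in (a, b, c):
        arr[~ok] = np.nan
    return a, b, c


def fst_weir_cockerham(gm: GenotypeMatrix, popA: str, popB: str):
    """Weir & Cockerham theta between two populations.

    Returns ``(multi_locus_fst, per_locus_fst)``.  The multi-locus estimate is
    the ratio of summed variance components; per-locus values may be negative;
    loci monomorphic across both populations (or with <2 genotyped samples in
    either) are undefined (NaN) and skipped in the sums.
    """
    gA = gm.genotypes[gm.population_mask(popA)]
    gB = gm.genotypes[gm.population_mask(popB)]
    pA, _, hA, nA = _per_locus_stats(gA)
    pB, _, hB, nB = _per_locus_stats(gB)
    a, b, c = wc_components(pA, hA, nA, pB, hB, nB)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a + b + c
        per_locus = np.where(np.abs(denom) > 0, a / denom, np.nan)
        per_locus = np.where(np.isnan(denom), np.nan, per_locus)
    ok = np.isfinite(a) & np.isfinite(denom) & (np.abs(denom) > 0)
    if not ok.any():
        return np.nan, per_locus
    multi = float(a[ok].sum() / denom[ok].sum())
    return multi, per_locus


def fst_nei_gst(gm: GenotypeMatrix, popA: str, popB: str):
    """Nei's G_ST (sensitivity alternative to Weir & Cockerham)."""
    pA = allele_frequencies(gm, popA)
    pB = allele_frequencies(gm, popB)
    ok = np.isfinite(pA) & np.isfinite(pB)
    pbar = (pA + pB) / 2.0
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = pA * (1.0 - pA) + pB * (1.0 - pB)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = np.where(ht > 0, (ht - hs) / ht, np.nan)
    use = ok & (ht > 0)
    multi = float((ht[use] - hs[use]).sum() / ht[use].sum()) if use.any() else np.nan
    return multi, per_locus


def ld_r2_matrix(
    gm: GenotypeMatrix, chromosome: str | None = None, population: str = "all",
    min_shared: int = 4,
) -> np.ndarray:
    """Pairwise composite-LD r-squared between loci.

    r-squared is the squared Pearson correlation of genotype-code vectors over
    samples non-missing at both loci.  Pairs with fewer than ``min_shared``
    shared samples or zero variance are NaN; the diagonal is 1 where the locus
    has any variance.
    """
    if chromosome is not None:
        lm = (gm.loci["chrom"] == chromosome).to_numpy()
        if not lm.any():
            raise ValueError(f"chromosome {chromosome!r} absent")
        gm = gm.subset(locus_mask=lm)
    if gm.n_loci < 2:
        raise ValueError("need at least 2 loci for LD")
    g = gm.genotypes[gm.population_mask(population)].astype(float)
    g[g == MISSING] = np.nan
    df = pd.DataFrame(g)
    r = df.corr(min_periods=min_shared).to_numpy()
    r2 = r**2
    np.fill_diagonal(r2, np.where(np.isfinite(np.diag(r2)) | (df.nunique() > 1), 1.0, np.nan))
    return r2


def chromosome_mean_r2(gm: GenotypeMatrix, groups: dict[str, list[str]]) -> pd.DataFrame:
    """Mean off-diagonal r-squared per chromosome for each sample group.

    ``groups`` maps a column name (e.g. "Wild") to the population labels whose
    samples are pooled for that column.  Output mirrors the per-chromosome LD
    comparison table: one row per chromosome, one column per group.
    """
    out = {}
    label_arr = gm.samples["population"].to_numpy()
    for name, labels in groups.items():
        mask = np.isin(label_arr, labels)
        if not mask.any():
            raise ValueError(f"group {name!r} matches no samples")
        sub = gm.subset(sample_mask=mask)
        col = {}
        for chrom in pd.unique(sub.loci["chrom"]):
            n_on_chrom = int((sub.loci["chrom"] == chrom).sum())
            if n_on_chrom < 2:
                col[chrom] = np.nan
                continue
            r2 = ld_r2_matrix(sub, chromosome=chrom)
            iu = np.triu_indices_from(r2, k=1)
            vals = r2[iu]
            col[chrom] = float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan
        out[name] = col
    return pd.DataFrame(out)
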