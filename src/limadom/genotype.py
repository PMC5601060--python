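"""Genotype data model and VCF I/O.

The common currency of every analysis stage is :class:`GenotypeMatrix`, a
samples x loci matrix of biallelic SNP genotype codes (0 = homozygous
reference, 1 = heterozygous, 2 = homozygous alternate, -1 = missing) together
with locus coordinates and a population label per sample.  Populations follow
the Lima bean gene-pool naming: wild/domesticated Mesoamerican I and II
(``MIW``, ``MID``, ``MIIW``, ``MIID``) plus ``OTHER`` for anything unmapped.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

POPULATIONS = ("MIW", "MID", "MIIW", "MIID", "OTHER")


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed; carries a line number when known."""


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes for a set of diploid samples.

    Attributes
    ----------
    genotypes
        int8 array of shape (n_samples, n_loci) with codes
        {0, 1, 2, MISSING = -1}.
    loci
        DataFrame with columns ``chrom`` (str), ``pos`` (1-based int),
        ``ref``, ``alt``; sorted by (chrom, pos), unique positions per
        chromosome.
    samples
        DataFrame with columns ``sample`` (unique ids) and ``population``.
    qual
        Optional per-locus phred QUAL (NaN when absent).
    depth
        Optional (n_samples, n_loci) per-genotype read depth (-1 when absent).
    """

    genotypes: np.ndarray
    loci: pd.DataFrame
    samples: pd.DataFrame
    qual: np.ndarray | None = None
    depth: np.ndarray | None = None
    ploidy: int = field(default=2, init=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x loci)")
        n_samples, n_loci = self.genotypes.shape
        if len(self.samples) != n_samples:
            raise ValueError("sample table does not match genotype rows")
        if len(self.loci) != n_loci:
            raise ValueError("locus table does not match genotype columns")
        codes = np.unique(self.genotypes)
        bad = set(codes.tolist()) - {0, 1, 2, MISSING}
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")
        if self.samples["sample"].duplicated().any():
            raise ValueError("duplicate sample ids")
        self.loci = self.loci.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self._sort_loci()
        if self.loci.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate positions within a chromosome")
        if self.qual is None:
            self.qual = np.full(n_loci, np.nan)
        else:
            self.qual = np.asarray(self.qual, dtype=float)

    def _sort_loci(self) -> None:
        order = self.loci.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
        if not np.array_equal(order, np.arange(len(self.loci))):
            self.loci = self.loci.iloc[order].reset_index(drop=True)
            self.genotypes = self.genotypes[:, order]
            if self.qual is not None:
                self.qual = self.qual[order]
            if self.depth is not None:
                self.depth = self.depth[:, order]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def population_mask(self, population: str) -> np.ndarray:
        if population == "all":
            return np.ones(self.n_samples, dtype=bool)
        mask = (self.samples["population"] == population).to_numpy()
        if not mask.any():
            raise ValueError(f"unknown or empty population {population!r}")
        return mask

    def subset(self, sample_mask=None, locus_mask=None) -> "GenotypeMatrix":
        sm = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask, bool)
        lm = np.ones(self.n_loci, bool) if locus_mask is None else np.asarray(locus_mask, bool)
        return GenotypeMatrix(
            genotypes=self.genotypes[np.ix_(sm, lm)],
            loci=self.loci.loc[lm].reset_index(drop=True),
            samples=self.samples.loc[sm].reset_index(drop=True),
            qual=None if self.qual is None else self.qual[lm],
            depth=None if self.depth is None else self.depth[np.ix_(sm, lm)],
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        """Field-by-field equality of genotypes, coordinates and alleles."""
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and self.loci[["chrom", "pos", "ref", "alt"]].equals(
                other.loci[["chrom", "pos", "ref", "alt"]]
            )
            and self.samples[["sample", "population"]].equals(
                other.samples[["sample", "population"]]
            )
        )


@dataclass(frozen=True)
class FilterSpec:
    """Site/sample retention thresholds (defaults mirror the GBS filtering)."""

    maf_min: float = 0.05
    max_site_missing: float = 0.10
    max_sample_missing: float = 0.10
    min_qual: float = 40.0
    min_depth: float = 10.0
    require_polymorphic: bool = True
    require_biallelic: bool = True

    def __post_init__(self) -> None:
        for name in ("maf_min", "max_site_missing", "max_sample_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.min_qual < 0 or self.min_depth < 0:
            raise ValueError("thresholds must be non-negative")


def read_popmap(path) -> dict[str, str]:
    """Read a 2-column TSV of (sample_id, population label)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"popmap line {i}: expected 2 tab-separated fields")
            out[parts[0]] = parts[1]
    return out


def write_popmap(pop_map: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sample, label in pop_map.items():
            fh.write(f"{sample}\t{label}\n")


def _locate_bad_line(path) -> int | None:
    # best-effort pre-scan for the first structurally broken record
    try:
        with open(path, errors="replace") as fh:
            n_fixed = 8  # CHROM POS ID REF ALT QUAL FILTER INFO
            for i, line in enumerate(fh, 1):
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < n_fixed:
                    return i
                try:
                    int(fields[1])
                except ValueError:
                    return i
    except OSError:
        return None
    return None


def read_vcf(path, pop_map: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF 4.x file into a :class:`GenotypeMatrix`.

    Multiallelic records are skipped (the count is reported via a warning and
    the returned matrix's ``skipped_multiallelic`` attribute on ``loci``).
    Samples absent from ``pop_map`` are labelled ``OTHER`` with a warning.
    """
    from cyvcf2 import VCF

    pop_map = pop_map or {}
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # htslib raises bare Exceptions on bad input
        line = _locate_bad_line(path)
        loc = f" at line {line}" if line else ""
        raise VcfParseError(f"cannot parse VCF {path}{loc}: {exc}") from exc

    vcf_samples = list(vcf.samples)
    if not vcf_samples:
        raise VcfParseError(f"VCF {path} declares no samples")
    unmapped = [s for s in vcf_samples if s not in pop_map]
    if unmapped and pop_map:
        warnings.warn(f"{len(unmapped)} VCF samples not in pop_map; labelled OTHER")
    labels = [pop_map.get(s, "OTHER") for s in vcf_samples]

    chroms, poss, refs, alts, quals = [], [], [], [], []
    gt_cols, dp_cols = [], []
    n_multi = 0
    try:
        for rec in vcf:
            if len(rec.ALT) != 1:
                n_multi += 1
                continue
            chroms.append(rec.CHROM)
            poss.append(rec.POS)
            refs.append(rec.REF)
            alts.append(rec.ALT[0])
            quals.append(np.nan if rec.QUAL is None else float(rec.QUAL))
            gts = np.asarray(rec.gt_types, dtype=np.int8)  # 0/1/2, 3=unknown
            gts[gts == 3] = MISSING
            gt_cols.append(gts)
            try:
                dp = rec.format("DP")
            except Exception:
                dp = None
            if dp is not None:
                dp = dp.astype(np.int32).reshape(-1)
                dp[dp < 0] = -1
            dp_cols.append(dp)
    except Exception as exc:
        line = _locate_bad_line(path)
        loc = f" at line {line}" if line else ""
        raise VcfParseError(f"malformed VCF record in {path}{loc}: {exc}") from exc

    if not chroms:
        raise VcfParseError(f"VCF {path} contains no usable biallelic records")
    if n_multi:
        warnings.warn(f"skipped {n_multi} multiallelic records")

    genotypes = np.column_stack(gt_cols)
    if any(d is not None for d in dp_cols):
        depth = np.column_stack(
            [d if d is not None else np.full(len(vcf_samples), -1, np.int32) for d in dp_cols]
        )
    else:
        depth = None
    gm = GenotypeMatrix(
        genotypes=genotypes,
        loci=pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts}),
        samples=pd.DataFrame({"sample": vcf_samples, "population": labels}),
        qual=np.asarray(quals),
        depth=depth,
    )
    gm.skipped_multiallelic = n_multi
    return gm


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 (GT only; QUAL written when known)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(gm.loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = "\t".join(gm.samples["sample"])
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        chrom_a = gm.loci["chrom"].to_numpy()
        pos_a = gm.loci["pos"].to_numpy()
        ref_a = gm.loci["ref"].to_numpy()
        alt_a = gm.loci["alt"].to_numpy()
        for j in range(gm.n_loci):
            q = gm.qual[j] if gm.qual is not None else np.nan
            qs = "." if np.isnan(q) else f"{q:g}"
            gts = "\t".join(_GT_STR[int(g)] for g in gm.genotypes[:, j])
            fh.write(
                f"{chrom_a[j]}\t{pos_a[j]}\t.\t{ref_a[j]}\t{alt_a[j]}\t{qs}\tPASS\t.\tGT\t{gts}\n"
            )


def _site_filter_mask(gm: GenotypeMatrix, spec: FilterSpec, counts: dict[str, int]) -> np.ndarray:
    """Boolean keep-mask over loci; increments per-filter removal counts."""
    g = gm.genotypes
    miss = g == MISSING
    n_nonmiss = (~miss).sum(axis=0)
    keep = np.ones(gm.n_loci, dtype=bool)

    frac_missing = miss.mean(axis=0)
    drop = frac_missing > spec.max_site_missing
    counts["site_missing"] += int((drop & keep).sum())
    keep &= ~drop

    with np.errstate(invalid="ignore", divide="ignore"):
        alt_count = np.where(miss, 0, g).sum(axis=0)
        p = np.where(n_nonmiss > 0, alt_count / (2.0 * np.maximum(n_nonmiss, 1)), np.nan)
    maf = np.minimum(p, 1.0 - p)
    drop = ~(maf >= spec.maf_min)  # NaN (all-missing) also dropped
    counts["site_maf"] += int((drop & keep).sum())
    keep &= ~drop

    if spec.require_polymorphic:
        drop = (p <= 0.0) | (p >= 1.0) | np.isnan(p)
        counts["site_monomorphic"] += int((drop & keep).sum())
        keep &= ~drop

    if gm.qual is not None and np.isfinite(gm.qual).any():
        drop = np.isfinite(gm.qual) & ~(gm.qual > spec.min_qual)
        counts["site_qual"] += int((drop & keep).sum())
        keep &= ~drop

    if gm.depth is not None:
        dp = gm.depth.astype(float)
        dp[dp < 0] = np.nan
        dp[miss] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_dp = np.nanmean(dp, axis=0)
        drop = np.isfinite(mean_dp) & (mean_dp < spec.min_depth)
        counts["site_depth"] += int((drop & keep).sum())
        keep &= ~drop
    return keep


def apply_filters(gm: GenotypeMatrix, spec: FilterSpec | None = None):
    """Filter sites, then samples, then sites once more.

    The order is sites -> samples -> sites: removing high-missing samples can
    change site MAF/missingness, so site filters are re-applied once.  Returns
    ``(filtered GenotypeMatrix, report dict)`` where the report carries the
    per-filter removal counts.
    """
    spec = spec or FilterSpec()
    if gm.n_loci == 0 or gm.n_samples == 0:
        raise ValueError("empty genotype matrix")
    counts = {
        k: 0
        for k in (
            "site_missing",
            "site_maf",
            "site_monomorphic",
            "site_qual",
            "site_depth",
            "samples_missing",
        )
    }
    keep_sites = _site_filter_mask(gm, spec, counts)
    out = gm.subset(locus_mask=keep_sites)
    if out.n_loci == 0:
        raise ValueError("empty after filtering: all sites removed")

    sample_missing = (out.genotypes == MISSING).mean(axis=1)
    keep_samples = sample_missing <= spec.max_sample_missing
    counts["samples_missing"] = int((~keep_samples).sum())
    out = out.subset(sample_mask=keep_samples)
    if out.n_samples == 0:
        raise ValueError("empty after filtering: all samples removed")

    keep_sites2 = _site_filter_mask(out, spec, counts)
    out = out.subset(locus_mask=keep_sites2)
    if out.n_loci == 0:
        raise ValueError("empty after filtering: all sites removed")

    report = {
        "input_sites": gm.n_loci,
        "output_sites": out.n_loci,
        "input_samples": gm.n_samples,
        "output_samples": out.n_samples,
        "removed": counts,
    }
    return out, report


def write_filter_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
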