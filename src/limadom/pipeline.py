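"""Pipeline orchestration: staged runs, seed management, derived scalars.

A run is a pure function of (config, master seed): the master seed spawns one
child seed per stage deterministically, every artifact is stamped with the
config hash and seed, and a structured log records filter counts and
runtimes.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import abc as abc_mod
from . import popgen, scan
from .demography import PriorSpec, SampleConfig, draw_parameters
from .coalescent import simulate_snp_dataset
from .genotype import FilterSpec, apply_filters, read_popmap, read_vcf, write_vcf

ALL_STAGES = ("simulate", "filter", "stats", "abc", "scan")


def derived_quantities(
    N2b: float | None = None,
    db1: float | None = None,
    N1: float | None = None,
    genome_size_bp: float | None = None,
    n_snps: int | None = None,
) -> dict[str, float]:
    """Headline derived scalars of the domestication analysis.

    * ``bottleneck_intensity``: k = N2b / db1 (founder size over bottleneck
      duration; k << 1 means a severe founder event).
    * ``map_density_kb``: genome size / number of SNPs, in Kb per SNP,
      rounded to the nearest Kb.
    * ``percent_size_reduction``: 100 * (1 - N2b / N1).
    """
    out: dict[str, float] = {}
    if N2b is not None and db1 is not None:
        if db1 == 0:
            raise ZeroDivisionError("db1 must be positive")
        out["bottleneck_intensity"] = N2b / db1
    if genome_size_bp is not None and n_snps is not None:
        if n_snps == 0:
            raise ZeroDivisionError("n_snps must be positive")
        out["map_density_kb"] = round(genome_size_bp / n_snps / 1000.0)
    if N2b is not None and N1 is not None:
        if N1 == 0:
            raise ZeroDivisionError("N1 must be positive")
        out["percent_size_reduction"] = 100.0 * (1.0 - N2b / N1)
    return out


@dataclass
class PipelineConfig:
    out_dir: str = "results/pipeline"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 1
    # simulate
    scenario: int = 2
    n_loci: int = 200
    sample_config: SampleConfig = field(default_factory=lambda: SampleConfig(n_loci=200))
    # filter
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    vcf_in: str | None = None      # when given, the filter stage starts from it
    popmap_in: str | None = None
    # abc
    abc_n_total: int = 400
    abc_n_closest_direct: int = 50
    abc_n_closest_logistic: int = 400
    abc_fraction: float = 0.1
    # scan
    varld_window: int = 25
    varld_top_fraction: float = 0.05

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = set(cls.__dataclass_fields__)
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "sample_config" in raw:
            raw["sample_config"] = SampleConfig(**raw["sample_config"])
        if "filter_spec" in raw:
            raw["filter_spec"] = FilterSpec(**raw["filter_spec"])
        if "stages" in raw:
            unknown = set(raw["stages"]) - set(ALL_STAGES)
            if unknown:
                raise ValueError(f"unknown stages: {sorted(unknown)}")
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _stage_seeds(master: int, n: int = 16) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def run(config: PipelineConfig) -> dict:
    """Execute the requested stages; returns the report bundle (also on disk)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": config.config_hash()}
    seeds = _stage_seeds(config.seed)
    log: list[dict] = []
    bundle: dict = {"stamp": stamp}
    gm = None

    def _log(stage, t0, **info):
        log.append({"stage": stage, "runtime_s": round(time.time() - t0, 3), **info})

    try:
        if "simulate" in config.stages:
            t0 = time.time()
            rng = np.random.default_rng(seeds[0])
            cfg = SampleConfig(
                n_MIW=config.sample_config.n_MIW,
                n_MID=config.sample_config.n_MID,
                n_MIIW=config.sample_config.n_MIIW,
                n_MIID=config.sample_config.n_MIID,
                n_loci=config.n_loci,
                maf_min=config.sample_config.maf_min,
                autogamous=config.sample_config.autogamous,
            )
            params = draw_parameters(PriorSpec(), config.scenario, rng)
            gm = simulate_snp_dataset(params, cfg, rng)
            write_vcf(gm, out_dir / "simulated.vcf")
            with open(out_dir / "simulated.params.json", "w") as fh:
                json.dump({**stamp, "params": params.as_dict()}, fh, indent=2)
            _log("simulate", t0, n_loci=gm.n_loci, n_samples=gm.n_samples)

        if "filter" in config.stages:
            t0 = time.time()
            if config.vcf_in:
                pop_map = read_popmap(config.popmap_in) if config.popmap_in else {}
                gm = read_vcf(config.vcf_in, pop_map)
            if gm is None:
                raise RuntimeError("filter stage needs a simulated or input VCF")
            gm, report = apply_filters(gm, config.filter_spec)
            with open(out_dir / "filter_report.json", "w") as fh:
                json.dump({**stamp, **report}, fh, indent=2)
            write_vcf(gm, out_dir / "filtered.vcf")
            _log("filter", t0, **report["removed"])

        if "stats" in config.stages:
            t0 = time.time()
            if gm is None:
                raise RuntimeError("stats stage needs genotypes from a previous stage")
            pops = [p for p in ("MIW", "MID", "MIIW", "MIID") if (gm.samples["population"] == p).any()]
            panel = popgen.diversity_panel(gm, pops)
            panel.table.to_csv(out_dir / "diversity_panel.tsv", sep="\t")
            if {"MIW", "MID"} <= set(pops):
                red = popgen.per_locus_reduction(gm, "MIW", "MID")
                with open(out_dir / "founder_effect.json", "w") as fh:
                    json.dump(
                        {
                            **stamp,
                            "global_r": red.global_r,
                            "share_positive": red.share_positive,
                            "share_negative": red.share_negative,
                            "share_zero": red.share_zero,
                        },
                        fh,
                        indent=2,
                    )
            _log("stats", t0, populations=pops)

        if "abc" in config.stages:
            t0 = time.time()
            if gm is None:
                raise RuntimeError("abc stage needs genotypes from a previous stage")
            rng = np.random.default_rng(seeds[1])
            cfg = SampleConfig(n_loci=gm.n_loci)
            table = abc_mod.build_reference_table(PriorSpec(), cfg, config.abc_n_total, rng)
            table.save(out_dir / "reference_table.tsv")
            obs = abc_mod.summary_stats(gm)
            direct = abc_mod.direct_posterior(table, obs, n_closest=config.abc_n_closest_direct)
            logistic = abc_mod.logistic_posterior(
                table, obs, n_closest=config.abc_n_closest_logistic, rng=rng
            )
            best = logistic.best() or direct.best() or 2
            post = abc_mod.estimate_parameters(table, obs, best, fraction=config.abc_fraction)
            post.table.to_csv(out_dir / "parameter_posterior.tsv", sep="\t")
            choice = {
                **stamp,
                "direct": {"prob": direct.probabilities, "ci": direct.intervals},
                "logistic": {"prob": logistic.probabilities, "ci": logistic.intervals},
                "best_scenario": best,
            }
            with open(out_dir / "scenario_choice.json", "w") as fh:
                json.dump(choice, fh, indent=2, default=str)
            bundle["abc"] = choice
            _log("abc", t0, n_table=table.n_rows)

        if "scan" in config.stages:
            t0 = time.time()
            if gm is None:
                raise RuntimeError("scan stage needs genotypes from a previous stage")
            wild = gm.subset(sample_mask=gm.samples["population"].isin(["MIW", "MIIW"]).to_numpy())
            dom = gm.subset(sample_mask=gm.samples["population"].isin(["MID", "MIID"]).to_numpy())
            result = scan.varld_scan(
                wild, dom, window=config.varld_window,
                top_fraction=config.varld_top_fraction,
                rng=np.random.default_rng(seeds[2]),
            )
            result.windows.to_csv(out_dir / "varld_windows.tsv", sep="\t", index=False)
            result.regions.to_csv(out_dir / "varld_regions.tsv", sep="\t", index=False)
            _log("scan", t0, n_windows=len(result.windows), n_regions=len(result.regions))
    except Exception as exc:
        stage = log[-1]["stage"] if log else "startup"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    bundle["log"] = log
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=str)
    return bundle
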