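"""Approximate Bayesian computation: scenario choice and parameter estimation.

The reference table holds rows of (scenario, parameters, summary statistics)
simulated from the priors.  Eleven summary statistics describe a dataset: the
mean expected heterozygosity of each of the four populations, the six
pairwise multi-locus Weir & Cockerham FST values, and a least-squares
admixture coefficient for the trio (MID, MIIW -> MIID).  Distances between
statistic vectors are Euclidean after per-statistic MAD standardization.

Scenario choice uses (a) the *direct* approach — the scenario composition of
the ``n_closest`` rows — and (b) a weighted logistic regression of scenario
label on observed-minus-simulated statistic differences among the closest
rows, evaluated at zero difference.  Parameter posteriors come from the
closest fraction of the chosen scenario's rows with a local-linear
regression adjustment on logit-transformed parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import popgen
from .coalescent import simulate_genotype_counts
from .demography import (
    SCENARIO_PARAMS,
    DemographicParameters,
    PriorSpec,
    SampleConfig,
    draw_parameters,
)
from .genotype import GenotypeMatrix

POP_ORDER = ("MIW", "MID", "MIIW", "MIID")
_PAIRS = [(i, j) for i in range(4) for j in range(i + 1, 4)]

STAT_NAMES = tuple(
    [f"he_{p}" for p in POP_ORDER]
    + [f"fst_{POP_ORDER[i]}_{POP_ORDER[j]}" for i, j in _PAIRS]
    + ["adm"]
)

ALL_PARAM_NAMES = ("N1", "N2", "N3", "N4", "N2b", "N3b", "t1", "t2", "t3", "db1", "db2", "ra")


def _admixture_coefficient(p_mid, p_miiw, p_miid) -> float:
    """Least-squares ra in p_MIID ~ ra * p_MID + (1 - ra) * p_MIIW, clipped to [0, 1].

    When the parental frequency vectors coincide the coefficient is
    unidentifiable; 0.5 is returned.
    """
    dx = p_mid - p_miiw
    dy = p_miid - p_miiw
    ok = np.isfinite(dx) & np.isfinite(dy)
    den = float((dx[ok] ** 2).sum())
    if den == 0.0:
        return 0.5
    return float(np.clip((dx[ok] * dy[ok]).sum() / den, 0.0, 1.0))


def _stats_from_per_pop(p, ho, n) -> np.ndarray:
    """11-statistic vector from per-population per-locus (p, H_O, n) arrays.

    ``p``, ``ho``, ``n`` have shape (4, n_loci) in POP_ORDER.
    """
    he = 2.0 * p * (1.0 - p)
    out = np.empty(len(STAT_NAMES))
    for i in range(4):
        out[i] = np.nanmean(he[i])
    for k, (i, j) in enumerate(_PAIRS):
        a, b, c = popgen.wc_components(p[i], ho[i], n[i], p[j], ho[j], n[j])
        denom = a + b + c
        ok = np.isfinite(denom) & (np.abs(denom) > 0)
        # a pair with no informative locus (both populations monomorphic for
        # the same allele everywhere) shows no measurable divergence: 0, not
        # NaN, so the statistic vector stays total for degenerate datasets
        out[4 + k] = a[ok].sum() / denom[ok].sum() if ok.any() else 0.0
    out[10] = _admixture_coefficient(p[1], p[2], p[3])
    return out


def summary_stats(gm: GenotypeMatrix) -> np.ndarray:
    """The 11 ABC summary statistics of a genotype matrix (see STAT_NAMES)."""
    for pop in POP_ORDER:
        gm.population_mask(pop)  # raises if absent
    ps, hos, ns = [], [], []
    for pop in POP_ORDER:
        g = gm.genotypes[gm.population_mask(pop)]
        p, _, ho, n = popgen._per_locus_stats(g)
        ps.append(p)
        hos.append(ho)
        ns.append(n)
    return _stats_from_per_pop(np.array(ps), np.array(hos), np.array(ns))


def stats_from_counts(derived: np.ndarray, hom: np.ndarray, config: SampleConfig) -> np.ndarray:
    """Summary statistics straight from simulator count matrices.

    Algebraically identical to building the genotype matrix and calling
    :func:`summary_stats` (the matrix only adds an exchangeable assignment of
    genotypes to individuals); verified by test.
    """
    dip = config.diploid_counts.astype(float)
    genes = config.gene_counts().astype(float)
    p = derived.T / genes[:, None]
    if config.autogamous:
        ho = np.zeros_like(p)
    else:
        het = derived.T - 2 * hom.T
        ho = het / dip[:, None]
    n = np.broadcast_to(dip[:, None], p.shape)
    return _stats_from_per_pop(p, ho, n)


@dataclass
class ReferenceTable:
    """Simulated (scenario, parameters, statistics) rows plus distance scales."""

    data: pd.DataFrame            # columns: scenario, ALL_PARAM_NAMES, STAT_NAMES
    mads: pd.Series               # per-statistic MAD over all rows
    seed: int | None = None
    priors: PriorSpec = field(default_factory=PriorSpec)
    config: SampleConfig = field(default_factory=SampleConfig)

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def stat_matrix(self) -> np.ndarray:
        return self.data[list(STAT_NAMES)].to_numpy()

    def save(self, path) -> None:
        import json

        header = {
            "seed": self.seed,
            "priors": {k: list(v) for k, v in self.priors.bounds.items()},
            "config": {
                "n_MIW": self.config.n_MIW,
                "n_MID": self.config.n_MID,
                "n_MIIW": self.config.n_MIIW,
                "n_MIID": self.config.n_MIID,
                "n_loci": self.config.n_loci,
                "maf_min": self.config.maf_min,
                "autogamous": self.config.autogamous,
            },
        }
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(header) + "\n")
            self.data.to_csv(fh, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "ReferenceTable":
        import json

        with open(path) as fh:
            header = json.loads(fh.readline().lstrip("#"))
            data = pd.read_csv(fh, sep="\t")
        priors = PriorSpec(bounds={k: tuple(v) for k, v in header["priors"].items()})
        config = SampleConfig(**header["config"])
        return cls(
            data=data, mads=_stat_mads(data), seed=header["seed"], priors=priors, config=config
        )


def _stat_mads(data: pd.DataFrame) -> pd.Series:
    stats = data[list(STAT_NAMES)]
    return (stats - stats.median()).abs().median()


def build_reference_table(
    priors: PriorSpec,
    config: SampleConfig,
    n_total: int,
    rng: np.random.Generator | int,
    progress: bool = False,
) -> ReferenceTable:
    """Simulate ``n_total`` datasets, half per scenario, and collect statistics."""
    if n_total < 100:
        raise ValueError("n_total must be >= 100")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng) if seed is not None else rng
    rows = []
    half = n_total // 2
    for scenario in (1, 2):
        for i in range(half):
            params = draw_parameters(priors, scenario, rng)
            derived, hom = simulate_genotype_counts(params, config, rng)
            stats = stats_from_counts(derived, hom, config)
            row = {"scenario": scenario}
            row.update(params.as_dict())
            row.pop("scenario", None)
            row["scenario"] = scenario
            row.update(dict(zip(STAT_NAMES, stats)))
            rows.append(row)
            if progress and (i + 1) % 500 == 0:
                print(f"scenario {scenario}: {i + 1}/{half} rows", flush=True)
    data = pd.DataFrame(rows)[["scenario", *ALL_PARAM_NAMES, *STAT_NAMES]]
    mads = _stat_mads(data)
    if (mads <= 0).any():
        bad = list(mads.index[mads <= 0])
        warnings.warn(f"zero MAD for statistics {bad}; enlarge the table before using distances")
    return ReferenceTable(data=data, mads=mads, seed=seed, priors=priors, config=config)


def _distances(
    table: ReferenceTable, observed: np.ndarray, standardize: str = "mad"
) -> np.ndarray:
    sims = table.stat_matrix()
    if standardize == "mad":
        scale = table.mads.to_numpy()
    elif standardize == "sd":
        scale = sims.std(axis=0, ddof=1)
    else:
        raise ValueError("standardize must be 'mad' or 'sd'")
    if np.any(scale <= 0):
        bad = [STAT_NAMES[i] for i in np.where(scale <= 0)[0]]
        raise ValueError(f"zero scale for statistics {bad}: enlarge the reference table")
    z = (sims - observed[None, :]) / scale[None, :]
    return np.sqrt((z**2).sum(axis=1))


def _closest(table: ReferenceTable, observed, n_closest, standardize="mad"):
    d = _distances(table, np.asarray(observed, float), standardize)
    order = np.argsort(d, kind="stable")  # stable: ties broken by row index
    sel = order[:n_closest]
    return sel, d


def _wilson(k: int, n: int, z: float = 1.959963984540054):
    if n == 0:
        return (0.0, 1.0)
    p = k / n
    den = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / den
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / den
    return (max(0.0, centre - half), min(1.0, centre + half))


@dataclass
class PosteriorChoice:
    probabilities: dict[int, float]
    intervals: dict[int, tuple[float, float]]
    approach: str
    n_closest: int

    def best(self) -> int | None:
        """Scenario with strictly highest posterior probability; None on a tie."""
        items = sorted(self.probabilities.items(), key=lambda kv: -kv[1])
        if len(items) > 1 and items[0][1] == items[1][1]:
            return None
        return items[0][0]


def direct_posterior(
    table: ReferenceTable, observed, n_closest: int = 500, standardize: str = "mad"
) -> PosteriorChoice:
    """Scenario posterior = scenario composition of the n_closest rows."""
    if n_closest > table.n_rows:
        raise ValueError("n_closest exceeds table size")
    sel, _ = _closest(table, observed, n_closest, standardize)
    scen = table.data["scenario"].to_numpy()[sel]
    probs, cis = {}, {}
    for s in (1, 2):
        k = int((scen == s).sum())
        probs[s] = k / n_closest
        cis[s] = _wilson(k, n_closest)
    return PosteriorChoice(probs, cis, "direct", n_closest)


def logistic_posterior(
    table: ReferenceTable,
    observed,
    n_closest: int = 10_000,
    n_bootstrap: int = 100,
    rng: np.random.Generator | None = None,
    standardize: str = "mad",
) -> PosteriorChoice:
    """Weighted logistic regression of scenario on statistic differences.

    Rows are the ``n_closest`` by MAD-standardized distance; predictors are
    the standardized differences (observed - simulated); weights are
    Epanechnikov in distance, ``w = 1 - (d/d_max)^2``; the posterior
    probability is the fitted probability at zero difference.  The 95% CI is a
    bootstrap over the selected rows.
    """
    from sklearn.linear_model import LogisticRegression

    if n_closest > table.n_rows:
        raise ValueError("n_closest exceeds table size")
    observed = np.asarray(observed, float)
    sel, d = _closest(table, observed, n_closest, standardize)
    scen = table.data["scenario"].to_numpy()[sel]
    present = np.unique(scen)
    if len(present) < 2:
        warnings.warn("one scenario absent among selected rows: degenerate fit")
        probs = {s: 1.0 if s in present else 0.0 for s in (1, 2)}
        return PosteriorChoice(probs, {s: (p, p) for s, p in probs.items()}, "logistic", n_closest)

    scale = table.mads.to_numpy() if standardize == "mad" else table.stat_matrix().std(axis=0, ddof=1)
    X = (observed[None, :] - table.stat_matrix()[sel]) / scale[None, :]
    dmax = d[sel].max()
    w = 1.0 - (d[sel] / dmax) ** 2 if dmax > 0 else np.ones(len(sel))
    w = np.maximum(w, 1e-8)

    def fit_p2(Xf, yf, wf) -> float:
        model = LogisticRegression(penalty=None, max_iter=2000, tol=1e-8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xf, yf, sample_weight=wf)
        p = model.predict_proba(np.zeros((1, Xf.shape[1])))[0]
        return float(p[list(model.classes_).index(2)])

    p2 = fit_p2(X, scen, w)
    if n_bootstrap > 0:
        rng = rng or np.random.default_rng(0)
        boot = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, len(sel), len(sel))
            if len(np.unique(scen[idx])) < 2:
                boot.append(1.0 if scen[idx][0] == 2 else 0.0)
                continue
            boot.append(fit_p2(X[idx], scen[idx], w[idx]))
        lo2, hi2 = np.quantile(boot, [0.025, 0.975])
    else:
        lo2 = hi2 = p2
    probs = {1: 1.0 - p2, 2: p2}
    cis = {1: (1.0 - hi2, 1.0 - lo2), 2: (lo2, hi2)}
    return PosteriorChoice(probs, cis, "logistic", n_closest)


@dataclass
class ConfusionReport:
    table: pd.DataFrame  # rows per (true scenario); columns type1, type2, n_pods
    approach: str


def confusion_errors(
    table: ReferenceTable,
    priors: PriorSpec,
    config: SampleConfig,
    n_pods: int = 1000,
    approach: str = "direct",
    rng: np.random.Generator | None = None,
    n_closest: int | None = None,
    progress: bool = False,
) -> ConfusionReport:
    """Type I / type II error rates from pseudo-observed datasets.

    For each scenario ``s``, ``n_pods // 2`` pods are simulated under fresh
    prior draws.  Type I error of ``s`` is the fraction of its own pods where
    ``s`` does not have the strictly highest posterior probability (argmax
    ties count as errors — conservative).  Type II error of ``s`` is the
    fraction of the other scenario's pods where ``s`` is the strict argmax.
    """
    if n_pods < 50:
        raise ValueError("n_pods must be >= 50")
    rng = rng or np.random.default_rng(0)
    if n_closest is None:
        n_closest = 500 if approach == "direct" else min(10_000, table.n_rows)
    half = n_pods // 2
    best: dict[int, list[int | None]] = {1: [], 2: []}
    for s in (1, 2):
        for i in range(half):
            params = draw_parameters(priors, s, rng)
            derived, hom = simulate_genotype_counts(params, config, rng)
            obs = stats_from_counts(derived, hom, config)
            if approach == "direct":
                choice = direct_posterior(table, obs, n_closest=n_closest)
            else:
                choice = logistic_posterior(table, obs, n_closest=n_closest, n_bootstrap=0)
            best[s].append(choice.best())
            if progress and (i + 1) % 50 == 0:
                print(f"pods under scenario {s}: {i + 1}/{half}", flush=True)
    rows = {}
    for s in (1, 2):
        other = 2 if s == 1 else 1
        type1 = np.mean([b != s for b in best[s]])
        type2 = np.mean([b == s for b in best[other]])
        rows[s] = {"type1": float(type1), "type2": float(type2), "n_pods": half}
    return ConfusionReport(pd.DataFrame(rows).T, approach)


_QUANTS = (0.025, 0.05, 0.25, 0.5, 0.75, 0.95, 0.975)


def _weighted_quantile(x, w, qs):
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.cumsum(w)
    cw = (cw - 0.5 * w) / w.sum()
    return np.interp(qs, cw, x)


@dataclass
class ParameterPosterior:
    table: pd.DataFrame          # per parameter: mean, median, mode, q025..q975, width95
    samples: pd.DataFrame        # adjusted weighted sample per parameter
    weights: np.ndarray
    scenario: int


def estimate_parameters(
    table: ReferenceTable,
    observed,
    scenario: int,
    fraction: float = 0.01,
    standardize: str = "mad",
) -> ParameterPosterior:
    """Posterior from the closest fraction of the scenario's rows.

    Local-linear regression adjustment: each parameter is logit-transformed to
    its prior range, regressed on the standardized statistic differences with
    Epanechnikov weights, residual-adjusted to zero difference, and
    back-transformed.  Mode from a weighted Gaussian KDE (Silverman
    bandwidth).
    """
    sub_idx = np.where(table.data["scenario"].to_numpy() == scenario)[0]
    if len(sub_idx) < 100:
        raise ValueError("need >= 100 rows of the chosen scenario")
    observed = np.asarray(observed, float)
    # zero-spread statistics carry no information: excluded from distance and design
    sims_all = table.stat_matrix()
    scale_all = (
        table.mads.to_numpy() if standardize == "mad" else sims_all.std(axis=0, ddof=1)
    )
    usable = scale_all > 0
    if not usable.any():
        raise ValueError("every statistic has zero spread in the reference table")
    z_all = (sims_all[:, usable] - observed[None, usable]) / scale_all[None, usable]
    d_all = np.sqrt((z_all**2).sum(axis=1))
    d = d_all[sub_idx]
    n_keep = max(2, int(np.ceil(fraction * len(sub_idx))))
    order = np.argsort(d, kind="stable")[:n_keep]
    sel = sub_idx[order]
    dsel = d_all[sel]
    dmax = dsel.max()
    w = 1.0 - (dsel / dmax) ** 2 if dmax > 0 else np.ones(len(sel))
    w = np.maximum(w, 1e-8)

    X = (observed[None, usable] - sims_all[np.ix_(sel, np.where(usable)[0])]) / scale_all[None, usable]
    keep_cols = X.std(axis=0) > 0  # zero-variance predictors among the selected rows
    X = X[:, keep_cols]

    names = SCENARIO_PARAMS[scenario]
    eps = 1e-9
    sqw = np.sqrt(w)
    design = np.column_stack([np.ones(len(sel)), X])
    rows = {}
    samples = {}
    for name in names:
        lo, hi = table.priors.bounds[name]
        x = table.data[name].to_numpy()[sel]
        u = np.clip((x - lo) / (hi - lo), eps, 1 - eps)
        z = np.log(u / (1 - u))
        adjusted = z
        if X.shape[1] > 0:
            try:
                beta, *_ = np.linalg.lstsq(design * sqw[:, None], z * sqw, rcond=None)
                if np.all(np.isfinite(beta)):
                    adjusted = z - X @ beta[1:]
                else:
                    warnings.warn(f"singular regression for {name}: rejection posterior used")
            except np.linalg.LinAlgError:
                warnings.warn(f"singular regression for {name}: rejection posterior used")
        back = lo + (hi - lo) / (1.0 + np.exp(-adjusted))
        qs = _weighted_quantile(back, w, _QUANTS)
        mode = _weighted_mode(back, w)
        rows[name] = {
            "mean": float(np.average(back, weights=w)),
            "median": float(qs[3]),
            "mode": mode,
            "q025": float(qs[0]),
            "q050": float(qs[1]),
            "q250": float(qs[2]),
            "q750": float(qs[4]),
            "q950": float(qs[5]),
            "q975": float(qs[6]),
            "width95": float(qs[6] - qs[0]),
        }
        samples[name] = back
    post = pd.DataFrame(rows).T[
        ["mean", "median", "mode", "q025", "q050", "q250", "q750", "q950", "q975", "width95"]
    ]
    return ParameterPosterior(post, pd.DataFrame(samples), w, scenario)


def _weighted_mode(x: np.ndarray, w: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return float(x[0])
    try:
        kde = sps.gaussian_kde(x, bw_method="silverman", weights=w)
    except np.linalg.LinAlgError:
        return float(np.average(x, weights=w))
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def validate_estimation(
    table: ReferenceTable,
    priors: PriorSpec,
    config: SampleConfig,
    scenario: int,
    n_pods: int = 1000,
    rng: np.random.Generator | None = None,
    fraction: float = 0.01,
    progress: bool = False,
) -> pd.DataFrame:
    """Bias/precision of the ABC estimator against a prior-only baseline.

    For each pod with known parameters: relative bias of the posterior mean,
    relative RMSE, and 95%-interval coverage; the same quantities for the
    estimator that ignores the data (prior mean and prior 95% interval).
    """
    rng = rng or np.random.default_rng(0)
    names = SCENARIO_PARAMS[scenario]
    prior_rows = table.data[table.data["scenario"] == scenario]
    prior_mean = {n: float(prior_rows[n].mean()) for n in names}
    prior_iv = {n: np.quantile(prior_rows[n], [0.025, 0.975]) for n in names}
    rel_err = {n: [] for n in names}
    cover = {n: [] for n in names}
    prior_rel = {n: [] for n in names}
    prior_cover = {n: [] for n in names}
    for i in range(n_pods):
        params = draw_parameters(priors, scenario, rng)
        derived, hom = simulate_genotype_counts(params, config, rng)
        obs = stats_from_counts(derived, hom, config)
        post = estimate_parameters(table, obs, scenario, fraction=fraction)
        for n in names:
            truth = getattr(params, n)
            est = post.table.loc[n, "mean"]
            rel_err[n].append((est - truth) / truth)
            cover[n].append(post.table.loc[n, "q025"] <= truth <= post.table.loc[n, "q975"])
            prior_rel[n].append((prior_mean[n] - truth) / truth)
            prior_cover[n].append(prior_iv[n][0] <= truth <= prior_iv[n][1])
        if progress and (i + 1) % 50 == 0:
            print(f"validation pods: {i + 1}/{n_pods}", flush=True)
    out = {}
    for n in names:
        e = np.array(rel_err[n])
        pe = np.array(prior_rel[n])
        out[n] = {
            "rel_bias": float(e.mean()),
            "rel_rmse": float(np.sqrt((e**2).mean())),
            "coverage95": float(np.mean(cover[n])),
            "prior_rel_bias": float(pe.mean()),
            "prior_rel_rmse": float(np.sqrt((pe**2).mean())),
            "prior_coverage95": float(np.mean(prior_cover[n])),
        }
    return pd.DataFrame(out).T


def model_check(
    table: ReferenceTable,
    observed,
    posterior: ParameterPosterior | None = None,
    n_pp: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Prior (and optional posterior) predictive checks of the observed data.

    (a) PCA of standardized table statistics with the observed vector
    projected, summarized by a Mahalanobis depth percentile (fraction of
    simulated rows at least as central as the observed); (b) per-statistic
    tail probabilities (fraction of simulations <= observed), flagged when
    outside (0.025, 0.975); (c) with a posterior sample, the same using
    ``n_pp`` datasets re-simulated from posterior parameter draws.
    """
    from sklearn.decomposition import PCA

    observed = np.asarray(observed, float)

    def _check(stat_mat: np.ndarray) -> dict:
        mu = stat_mat.mean(axis=0)
        sd = stat_mat.std(axis=0, ddof=1)
        sd[sd <= 0] = 1.0
        zs = (stat_mat - mu) / sd
        zo = (observed - mu) / sd
        pca = PCA(n_components=min(5, zs.shape[1]))
        scores = pca.fit_transform(zs)
        obs_score = pca.transform(zo[None, :])[0]
        cov = np.cov(scores, rowvar=False)
        cov += 1e-12 * np.eye(cov.shape[0])
        icov = np.linalg.inv(cov)
        centre = scores.mean(axis=0)
        d2 = np.einsum("ij,jk,ik->i", scores - centre, icov, scores - centre)
        d2_obs = float((obs_score - centre) @ icov @ (obs_score - centre))
        depth = float(np.mean(d2 >= d2_obs))  # 1 = perfectly central, 0 = outside cloud
        tails = (stat_mat <= observed[None, :]).mean(axis=0)
        flags = {
            STAT_NAMES[i]: float(tails[i])
            for i in range(len(STAT_NAMES))
            if tails[i] < 0.025 or tails[i] > 0.975
        }
        return {
            "depth_percentile": depth,
            "tail_probabilities": dict(zip(STAT_NAMES, tails.tolist())),
            "flagged_stats": flags,
            "pca_scores": scores,
            "observed_score": obs_score,
        }

    report = {"prior": _check(table.stat_matrix())}
    if posterior is not None:
        rng = rng or np.random.default_rng(0)
        names = list(posterior.samples.columns)
        w = posterior.weights / posterior.weights.sum()
        draws = rng.choice(len(posterior.samples), size=n_pp, p=w)
        stat_rows = []
        for idx in draws:
            vals = {n: float(posterior.samples.iloc[idx][n]) for n in names}
            full = {n: vals.get(n, float(table.priors.bounds[n][0])) for n in ALL_PARAM_NAMES}
            # unused parameters of the scenario stay at neutral mid-prior values
            for n in ALL_PARAM_NAMES:
                if n not in vals:
                    lo, hi = table.priors.bounds[n]
                    full[n] = 0.5 * (lo + hi)
            params = DemographicParameters(scenario=posterior.scenario, **full)
            if not params.validate():
                continue
            derived, hom = simulate_genotype_counts(params, table.config, rng)
            stat_rows.append(stats_from_counts(derived, hom, table.config))
        if len(stat_rows) >= 20:
            report["posterior"] = _check(np.array(stat_rows))
        else:
            report["posterior"] = None
            warnings.warn("too few valid posterior draws for a posterior check")
    return report
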