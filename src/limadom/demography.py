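"""Demographic scenarios of Lima bean domestication and their priors.

Two competing scenarios are modelled (one generation = 1 year):

* **Scenario 1 — two independent domestications.**  Domesticated MI (MID)
  splits from wild MI (MIW) at ``t2`` with a founding bottleneck of size
  ``N2b`` lasting ``db1`` generations; domesticated MII (MIID) splits from
  wild MII (MIIW) at ``t1`` with a bottleneck ``N3b`` for ``db2`` generations.
  MIW and MIIW share a common ancestor at ``t3``.

* **Scenario 2 — single domestication plus admixture.**  MID originates from
  MIW as above; MIID is an admixed population formed at ``t1`` with a
  proportion ``ra`` of its ancestry from MID and ``1 - ra`` from MIIW.

All times are in generations before present, sizes are diploid effective
sizes.  Looking backward in time a domesticated population keeps its modern
size until ``t - db``, shrinks to its bottleneck size on ``[t - db, t)``, and
merges into its source at ``t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

# population indices used throughout the simulator
POP_MIW, POP_MID, POP_MIIW, POP_MIID = 0, 1, 2, 3
POP_NAMES = ("MIW", "MID", "MIIW", "MIID")

# event kinds for the piecewise-constant event table
EV_RESIZE, EV_MERGE, EV_ADMIX = 0, 1, 2


@dataclass(frozen=True)
class DemographicParameters:
    """One draw of the demographic parameters under a scenario."""

    N1: float   # wild MI
    N2: float   # domesticated MI (modern)
    N3: float   # domesticated MII (modern)
    N4: float   # wild MII
    N2b: float  # MI bottleneck size
    N3b: float  # MII bottleneck size (scenario 1 only)
    t1: float   # MII domestication / admixture time
    t2: float   # MI domestication time
    t3: float   # wild MI-MII divergence
    db1: float  # MI bottleneck duration
    db2: float  # MII bottleneck duration (scenario 1 only)
    ra: float   # admixture proportion of MIID ancestry from MID (scenario 2)
    scenario: int

    def validate(self) -> bool:
        p = self
        if p.scenario not in (1, 2):
            return False
        if min(p.N1, p.N2, p.N3, p.N4, p.N2b, p.N3b) < 10:
            return False
        if not (p.t3 > p.t1 and p.t3 > p.t2):
            return False
        if not p.t2 > p.db1:
            return False
        if p.scenario == 1 and not p.t1 > p.db2:
            return False
        if p.scenario == 2 and not (p.t2 > p.t1 and 0.0 <= p.ra <= 1.0):
            return False
        return True

    def as_dict(self) -> dict:
        return asdict(self)


#: free parameters per scenario (order used in reference tables / posteriors)
SCENARIO_PARAMS = {
    1: ("N1", "N2", "N3", "N4", "N2b", "N3b", "t1", "t2", "t3", "db1", "db2"),
    2: ("N1", "N2", "N3", "N4", "N2b", "t1", "t2", "t3", "db1", "ra"),
}


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors on every demographic parameter."""

    bounds: dict = field(
        default_factory=lambda: {
            "N1": (10.0, 2_000_000.0),
            "N2": (10.0, 2_000_000.0),
            "N3": (10.0, 2_000_000.0),
            "N4": (10.0, 2_000_000.0),
            "N2b": (10.0, 5_000.0),
            "N3b": (10.0, 5_000.0),
            "t1": (2_000.0, 10_000.0),
            "t2": (2_000.0, 10_000.0),
            "t3": (300_000.0, 1_000_000.0),
            "db1": (1_000.0, 3_000.0),
            "db2": (1_000.0, 3_000.0),
            "ra": (0.001, 0.999),
        }
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"degenerate prior for {name}: ({lo}, {hi})")


@dataclass(frozen=True)
class SampleConfig:
    """Diploid sample sizes per population and locus count for simulation."""

    n_MIW: int = 30
    n_MID: int = 30
    n_MIIW: int = 30
    n_MIID: int = 17
    n_loci: int = 2527
    maf_min: float = 0.05
    autogamous: bool = False

    def __post_init__(self) -> None:
        if min(self.n_MIW, self.n_MID, self.n_MIIW, self.n_MIID) < 1:
            raise ValueError("sample counts must be >= 1")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")

    @property
    def diploid_counts(self) -> np.ndarray:
        return np.array([self.n_MIW, self.n_MID, self.n_MIIW, self.n_MIID], dtype=np.int64)

    def gene_counts(self) -> np.ndarray:
        """Genes sampled per population: 2 per diploid, or 1 under autogamy."""
        mult = 1 if self.autogamous else 2
        return mult * self.diploid_counts


def draw_parameters(
    prior: PriorSpec, scenario: int, rng: np.random.Generator, max_rejections: int = 1_000_000
) -> DemographicParameters:
    """Rejection-sample one parameter draw satisfying the scenario conditions.

    Returns a valid :class:`DemographicParameters`; the number of rejected
    draws is recorded on the returned object's ``n_rejections`` attribute
    (via object.__setattr__, the dataclass being frozen).
    """
    names = list(prior.bounds)
    lows = np.array([prior.bounds[n][0] for n in names])
    highs = np.array([prior.bounds[n][1] for n in names])
    for attempt in range(max_rejections + 1):
        vals = dict(zip(names, rng.uniform(lows, highs)))
        params = DemographicParameters(scenario=scenario, **vals)
        if params.validate():
            object.__setattr__(params, "n_rejections", attempt)
            return params
    raise RuntimeError(f"degenerate prior: >{max_rejections} rejections")


def build_event_table(params: DemographicParameters):
    """Compile a parameter draw into sorted (time, kind, args) event arrays.

    Returns ``(sizes0, times, kinds, ev_a, ev_b, ev_c, ev_par)`` where
    ``sizes0`` are the present-day diploid sizes per population index and
    events are sorted by time (stable on construction order for equal times:
    at ``t3`` the wild merge precedes the ancestral resize).  For an ADMIX
    event a lineage of population ``a`` moves to ``b`` with probability
    ``par`` and to ``c`` otherwise.

    The ancestral population after ``t3`` takes size ``N4`` (wild MII being
    the larger, more diverse pool); this is a modelling choice, configurable
    upstream via the parameter draw itself.
    """
    p = params
    sizes0 = np.array([p.N1, p.N2, p.N4, p.N3], dtype=np.float64)
    events: list[tuple[float, int, int, int, int, float]] = []
    # MI domestication bottleneck + merge (both scenarios)
    events.append((p.t2 - p.db1, EV_RESIZE, POP_MID, -1, -1, p.N2b))
    events.append((p.t2, EV_MERGE, POP_MID, POP_MIW, -1, 0.0))
    if p.scenario == 1:
        events.append((p.t1 - p.db2, EV_RESIZE, POP_MIID, -1, -1, p.N3b))
        events.append((p.t1, EV_MERGE, POP_MIID, POP_MIIW, -1, 0.0))
    else:
        # admixture: each MIID lineage joins MID with probability ra, else MIIW
        events.append((p.t1, EV_ADMIX, POP_MIID, POP_MID, POP_MIIW, p.ra))
    events.append((p.t3, EV_MERGE, POP_MIIW, POP_MIW, -1, 0.0))
    events.append((p.t3, EV_RESIZE, POP_MIW, -1, -1, p.N4))
    events.sort(key=lambda e: e[0])
    times = np.array([e[0] for e in events], dtype=np.float64)
    kinds = np.array([e[1] for e in events], dtype=np.int64)
    ev_a = np.array([e[2] for e in events], dtype=np.int64)
    ev_b = np.array([e[3] for e in events], dtype=np.int64)
    ev_c = np.array([e[4] for e in events], dtype=np.int64)
    ev_par = np.array([e[5] for e in events], dtype=np.float64)
    return sizes0, times, kinds, ev_a, ev_b, ev_c, ev_par
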