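"""Semi-deterministic serial-passage simulator (pure exponential growth).

The wild type grows deterministically (``N_t = N0 * exp(r00 * t)``) and is
reset to ``N0`` at every bottleneck; mutant lineages are stochastic.  This is
the classic Luria--Delbrueck setting: founding events of a mutant genotype
form an inhomogeneous Poisson process with intensity ``mu * parent_size(t)``,
and each founded lineage runs a linear birth-death process.

Direct individual-based simulation is impossible at the population sizes of
interest (up to ``n**alpha`` with ``n`` as large as 1e12), so the engine is
hybrid:

* lineages below the cutoff ``hybrid_cutoff`` are stochastic; their
  birth-death dynamics over a time step are sampled from the exact
  linear-birth-death transition law (binomial number of surviving founder
  lines, geometric family sizes), not by event-by-event simulation;
* a lineage reaching the cutoff is moved to a deterministic mass that grows
  exponentially; its fate is already decided at that size;
* founding events are sampled individually while their expected number per
  step is below ``founder_cap`` (the early, jackpot-prone founders), and
  aggregated into the deterministic mass afterwards (the many late founders,
  whose total concentrates around its expectation);
* at the bottleneck, stochastic lineages are thinned binomially with
  retention ``D_n``; a deterministic mass whose diluted value falls below
  ``10 * hybrid_cutoff`` is resampled by binomial thinning so that borderline
  survival remains stochastic.

Mutation toward the double mutant is emitted from both stochastic lineages
(per-lineage Poisson on the integrated size) and deterministic masses, with
the parental background recorded (``from10`` / ``from01``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    BirthDeathRates,
    DemographyParams,
    FitnessLandscape,
    ParameterError,
    rates_from_net,
)
from .theory import LABELS, PathConfiguration

__all__ = [
    "DEFAULT_HYBRID_CUTOFF",
    "DEFAULT_ESTABLISH_THRESHOLD",
    "DEFAULT_FOUNDER_CAP",
    "Lineage",
    "GenotypePool",
    "PopulationState",
    "CycleRecord",
    "sample_founding_events",
    "evolve_lineage",
    "apply_bottleneck",
    "run_cycles",
    "classify_observed",
]

#: Lineages at or above this size are treated deterministically.
DEFAULT_HYBRID_CUTOFF = 1.0e4
#: A genotype counts as established once its end-of-cycle total reaches this
#: absolute size: the scale at which a supercritical lineage has escaped
#: drift extinction (see docs/methods.md).
DEFAULT_ESTABLISH_THRESHOLD = 20.0
#: Expected founding events per step above which founders are aggregated
#: deterministically instead of being sampled one by one.
DEFAULT_FOUNDER_CAP = 64.0
#: Default target for per-step wild-type growth, ``r00 * dt``.
DEFAULT_MAX_STEP_GROWTH = 0.35

#: Pool keys tracked by the engine (double mutants split by origin).
POOL_KEYS: tuple[str, ...] = ("10", "01", "11_from10", "11_from01")


@dataclass
class Lineage:
    """One mutant clone: genotype (with origin for ``11``), founding time, size."""

    genotype: str
    origin: str | None
    founded_cycle: int
    founded_time: float
    size: float

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ParameterError("lineage size must be non-negative")


@dataclass
class GenotypePool:
    """All lineages of one genotype/origin: stochastic sizes plus a bulk mass."""

    sizes: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    det_mass: float = 0.0
    foundings: float = 0.0  # founding events this cycle (expected value once aggregated)
    ever_founded: bool = False

    @property
    def total(self) -> float:
        return float(self.sizes.sum()) + self.det_mass


@dataclass
class PopulationState:
    cycle: int
    time_in_cycle: float
    wt_size: float
    n0: float
    pools: dict[str, GenotypePool]


@dataclass
class CycleRecord:
    """Per-cycle bookkeeping of founding, establishment and bottleneck survival."""

    cycle: int
    duration: float
    wt_end: float
    foundings: dict[str, float]
    end_size: dict[str, float]
    established: dict[str, bool]
    post_size: dict[str, float]
    survived: dict[str, bool]


# ---------------------------------------------------------------------------
# elementary stochastic kernels


def _bd_params(b: float, d: float, t: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Extinction probability ``a`` and geometric parameter ``c`` of a linear
    birth-death process started from one individual, after time ``t``.

    ``P(Z_t = 0) = a`` and, conditional on survival, ``Z_t`` is geometric on
    {1, 2, ...} with success probability ``1 - c``.
    """
    t = np.asarray(t, dtype=float)
    if b == d:
        x = b * t
        a = x / (1.0 + x)
        return a, a
    w = np.exp((b - d) * t)
    denom = b * w - d
    a = d * (w - 1.0) / denom
    c = b * (w - 1.0) / denom
    return a, c


def _bd_evolve_sizes(
    sizes: np.ndarray, b: float, d: float, t: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact birth-death transition for an array of lineage sizes over time ``t``."""
    if sizes.size == 0 or t <= 0:
        return sizes
    a, c = _bd_params(b, d, t)
    a, c = float(a), float(c)
    if d == 0.0:
        return sizes + rng.negative_binomial(sizes, max(1.0 - c, 1e-300))
    surv = rng.binomial(sizes, 1.0 - a)
    out = np.zeros_like(sizes)
    pos = surv > 0
    if np.any(pos):
        out[pos] = surv[pos] + rng.negative_binomial(surv[pos], max(1.0 - c, 1e-300))
    return out


def _bd_evolve_singletons(
    t: np.ndarray, b: float, d: float, rng: np.random.Generator
) -> np.ndarray:
    """Sizes reached by independent single founders after (heterogeneous) times."""
    if t.size == 0:
        return np.zeros(0, dtype=np.int64)
    a, c = _bd_params(b, d, t)
    alive = rng.random(t.size) >= a
    out = np.zeros(t.size, dtype=np.int64)
    if np.any(alive):
        out[alive] = rng.geometric(np.maximum(1.0 - c[alive], 1e-300))
    return out


def sample_founding_events(
    parent_size_trajectory,
    mutation_rate: float,
    cycle_duration: float,
    rng: np.random.Generator,
    grid_points: int = 512,
) -> np.ndarray:
    """Founding times of an inhomogeneous Poisson process ``mu * parent(t)``.

    ``parent_size_trajectory`` is either a pair ``(size0, growth_rate)``
    describing exponential growth (sampled exactly by the time-transform
    method) or an arbitrary callable ``t -> size`` (sampled by thinning under
    a piecewise-constant majorant built on a grid).
    """
    if mutation_rate < 0:
        raise ParameterError("mutation rate must be non-negative")
    if mutation_rate == 0 or cycle_duration <= 0:
        return np.zeros(0)
    if callable(parent_size_trajectory):
        edges = np.linspace(0.0, cycle_duration, grid_points + 1)
        vals = np.array([parent_size_trajectory(t) for t in edges])
        seg_max = 1.0001 * np.maximum(vals[:-1], vals[1:])
        times: list[float] = []
        for lo, hi, m in zip(edges[:-1], edges[1:], seg_max):
            lam = mutation_rate * m * (hi - lo)
            k = rng.poisson(lam)
            if k:
                cand = rng.uniform(lo, hi, k)
                keep = rng.random(k) * m <= np.array([parent_size_trajectory(t) for t in cand])
                times.extend(cand[keep])
        return np.sort(np.array(times))
    size0, rate = parent_size_trajectory
    if rate == 0.0:
        lam = mutation_rate * size0 * cycle_duration
        return np.sort(rng.uniform(0.0, cycle_duration, rng.poisson(lam)))
    total = mutation_rate * size0 * (math.exp(rate * cycle_duration) - 1.0) / rate
    k = rng.poisson(total)
    u = rng.random(k)
    times = np.log1p(u * math.expm1(rate * cycle_duration)) / rate
    return np.sort(times)


def evolve_lineage(
    lineage: Lineage,
    rates: BirthDeathRates,
    duration: float,
    rng: np.random.Generator,
    mutation_rate_out: float = 0.0,
    hybrid_cutoff: float = DEFAULT_HYBRID_CUTOFF,
    max_step_growth: float = DEFAULT_MAX_STEP_GROWTH,
) -> tuple[Lineage, np.ndarray]:
    """Evolve one lineage for ``duration``, returning it plus emitted mutation times.

    Stochastic (exact birth-death transitions on sub-steps) below the hybrid
    cutoff, deterministic exponential growth above it; mutation events toward
    the double mutant are emitted at per-capita rate ``mutation_rate_out``
    from the integrated lineage size.
    """
    if duration < 0:
        raise ParameterError("duration must be non-negative")
    g = lineage.genotype
    b, d = rates.birth[g], rates.death[g]
    r = b - d
    if lineage.size == 0 or duration == 0:
        return lineage, np.zeros(0)
    steps = max(1, math.ceil(b * duration / max_step_growth))
    dt = duration / steps
    size = lineage.size
    t = 0.0
    emitted: list[float] = []
    for _ in range(steps):
        if size >= hybrid_cutoff:
            new = size * math.exp(r * dt)
            integral = size * (math.exp(r * dt) - 1.0) / r if r != 0 else size * dt
        else:
            new = float(_bd_evolve_sizes(np.array([int(size)], dtype=np.int64), b, d, dt, rng)[0])
            integral = 0.5 * (size + new) * dt
        k = rng.poisson(mutation_rate_out * integral)
        if k:
            emitted.extend(t + rng.uniform(0.0, dt, k))
        size = new
        t += dt
        if size == 0:
            break
    lineage.size = size
    return lineage, np.sort(np.array(emitted))


# ---------------------------------------------------------------------------
# whole-population engine


def _exp_integral(mass0: float, r_parent: float, r_child: float, dt: float) -> float:
    """``int_0^dt mass0 * exp(r_parent s) * exp(r_child (dt - s)) ds``."""
    if abs(r_parent - r_child) < 1e-12:
        return mass0 * dt * math.exp(r_parent * dt)
    return (
        mass0
        * (math.exp(r_parent * dt) - math.exp(r_child * dt))
        / (r_parent - r_child)
    )


def _wt_founding_step(
    pool: GenotypePool,
    mu: float,
    n0: float,
    r00: float,
    t1: float,
    dt: float,
    b: float,
    d: float,
    r_child: float,
    founder_cap: float,
    rng: np.random.Generator,
) -> None:
    """Founding events from the deterministic wild type during one step."""
    w1 = math.exp(r00 * t1)
    lam = mu * n0 * w1 * math.expm1(r00 * dt) / r00
    if lam <= founder_cap:
        k = rng.poisson(lam)
        pool.foundings += k
        if k:
            pool.ever_founded = True
            u = rng.random(k)
            offsets = np.log1p(u * math.expm1(r00 * dt)) / r00
            sizes = _bd_evolve_singletons(dt - offsets, b, d, rng)
            sizes = sizes[sizes > 0]
            if sizes.size:
                pool.sizes = np.concatenate([pool.sizes, sizes])
    else:
        pool.foundings += lam
        pool.ever_founded = True
        # expected end-of-step descendant mass of this step's founders
        pool.det_mass += mu * n0 * w1 * _exp_integral(1.0, r00, r_child, dt)


def _emission_step(
    parent: GenotypePool,
    child: GenotypePool,
    mu_out: float,
    b_p: float,
    d_p: float,
    b_c: float,
    d_c: float,
    dt: float,
    founder_cap: float,
    rng: np.random.Generator,
) -> None:
    """Evolve a parent pool over one step and emit double-mutant founders."""
    r_p, r_c = b_p - d_p, b_c - d_c
    old = parent.sizes
    if old.size:
        new = _bd_evolve_sizes(old, b_p, d_p, dt, rng)
        if mu_out > 0:
            integrals = 0.5 * (old + new) * dt
            k = int(rng.poisson(mu_out * integrals).sum())
            if k:
                child.foundings += k
                child.ever_founded = True
                sizes = _bd_evolve_singletons(rng.uniform(0.0, dt, k), b_c, d_c, rng)
                sizes = sizes[sizes > 0]
                if sizes.size:
                    child.sizes = np.concatenate([child.sizes, sizes])
        parent.sizes = new[new > 0]
    if parent.det_mass > 0:
        if mu_out > 0:
            mean = (
                mu_out * parent.det_mass * (math.expm1(r_p * dt)) / r_p
                if r_p != 0
                else mu_out * parent.det_mass * dt
            )
            if mean <= founder_cap:
                k = rng.poisson(mean)
                if k:
                    child.foundings += k
                    child.ever_founded = True
                    sizes = _bd_evolve_singletons(rng.uniform(0.0, dt, k), b_c, d_c, rng)
                    sizes = sizes[sizes > 0]
                    if sizes.size:
                        child.sizes = np.concatenate([child.sizes, sizes])
            else:
                child.foundings += mean
                child.ever_founded = True
                child.det_mass += mu_out * _exp_integral(parent.det_mass, r_p, r_c, dt)
        parent.det_mass *= math.exp(r_p * dt)


#: Deterministic masses are capped here: far beyond any establishment or
#: survival threshold, and safely inside float64 across repeated growth.
_DET_CAP = 1e250


def _promote(pool: GenotypePool, cutoff: float) -> None:
    if pool.sizes.size:
        big = pool.sizes >= cutoff
        if np.any(big):
            pool.det_mass += float(pool.sizes[big].sum())
            pool.sizes = pool.sizes[~big]
    if pool.det_mass > _DET_CAP:
        pool.det_mass = _DET_CAP


def _thin_mass(mass: float, dilution: float, rng: np.random.Generator) -> int:
    """Binomial thinning of a deterministic mass (Poisson limit for huge masses)."""
    if mass > 4e18:  # beyond exact int64 binomial; Poisson limit is exact here
        return int(min(rng.poisson(mass * dilution), mass))
    return int(rng.binomial(int(round(mass)), dilution))


def apply_bottleneck(
    state: PopulationState,
    dilution: float,
    rng: np.random.Generator,
    hybrid_cutoff: float = DEFAULT_HYBRID_CUTOFF,
) -> PopulationState:
    """Dilute every lineage by ``dilution`` and reset the wild type to ``N0``.

    Stochastic lineages are thinned binomially; a deterministic mass is scaled
    (with Poisson resampling when the result drops below ``10 * cutoff`` so
    that borderline bottleneck survival stays stochastic).
    """
    if not 0 < dilution <= 1:
        raise ParameterError(f"dilution must be in (0, 1] (got {dilution})")
    for pool in state.pools.values():
        if pool.sizes.size:
            thinned = rng.binomial(pool.sizes, dilution)
            pool.sizes = thinned[thinned > 0]
        if pool.det_mass > 0:
            if pool.det_mass * dilution < 10.0 * hybrid_cutoff:
                k = _thin_mass(pool.det_mass, dilution, rng)
                pool.det_mass = 0.0
                if k:
                    pool.sizes = np.concatenate(
                        [pool.sizes, np.array([k], dtype=np.int64)]
                    )
            else:
                pool.det_mass *= dilution
    state.wt_size = state.n0
    state.time_in_cycle = 0.0
    return state


def _fresh_pools() -> dict[str, GenotypePool]:
    return {k: GenotypePool() for k in POOL_KEYS}


def run_cycles(
    params: DemographyParams,
    landscape: FitnessLandscape,
    rates: BirthDeathRates | None = None,
    n_cycles: int = 7,
    rng: np.random.Generator | int | None = None,
    hybrid_cutoff: float = DEFAULT_HYBRID_CUTOFF,
    establish_threshold: float = DEFAULT_ESTABLISH_THRESHOLD,
    establish_fraction: float = 0.0,
    founder_cap: float = DEFAULT_FOUNDER_CAP,
    max_step_growth: float = DEFAULT_MAX_STEP_GROWTH,
    mu_high: float | None = None,
    mu_low: float | None = None,
) -> tuple[list[CycleRecord], PopulationState]:
    """Simulate ``n_cycles`` growth/bottleneck cycles of one protocol.

    ``rates`` defaults to a pure-birth decomposition (death rate 0) of the
    landscape.  A genotype is *established* in a cycle when its end-of-cycle
    total reaches ``max(establish_threshold, establish_fraction * wt_end)``,
    and *survives* a bottleneck when it was established and its
    post-bottleneck total is positive.  ``mu_high``/``mu_low`` override the
    mutation rates implied by ``params`` (for mutation-free controls).
    """
    if n_cycles < 1:
        raise ParameterError("n_cycles must be >= 1")
    if rates is None:
        rates = rates_from_net(landscape, 0.0)
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    mu_high = params.mu_high if mu_high is None else mu_high
    mu_low = params.mu_low if mu_low is None else mu_low
    if mu_high < 0 or mu_low < 0:
        raise ParameterError("mutation rates must be non-negative")

    t_n = params.t_n(landscape.r00)
    n0 = params.N0
    d_n = params.D_n
    r00 = landscape.r00
    steps = max(8, math.ceil(r00 * t_n / max_step_growth))
    dt = t_n / steps

    state = PopulationState(cycle=1, time_in_cycle=0.0, wt_size=n0, n0=n0, pools=_fresh_pools())
    records: list[CycleRecord] = []

    child_rates = {k: (rates.birth[k[:2]], rates.death[k[:2]]) for k in POOL_KEYS}
    emissions = (
        ("10", "11_from10", mu_low),
        ("01", "11_from01", mu_high),
    )

    for cycle in range(1, n_cycles + 1):
        pools = state.pools
        for p in pools.values():
            p.foundings = 0.0
        for i in range(steps):
            t1 = i * dt
            # existing double-mutant lineages grow first (new founders arrive
            # later in the step already evolved to its end)
            for key in ("11_from10", "11_from01"):
                pool = pools[key]
                b, d = child_rates[key]
                if pool.sizes.size:
                    new = _bd_evolve_sizes(pool.sizes, b, d, dt, rng)
                    pool.sizes = new[new > 0]
                if pool.det_mass > 0:
                    pool.det_mass *= math.exp((b - d) * dt)
            for parent_key, child_key, mu_out in emissions:
                b_p, d_p = child_rates[parent_key]
                b_c, d_c = child_rates[child_key]
                _emission_step(
                    pools[parent_key], pools[child_key], mu_out, b_p, d_p, b_c, d_c,
                    dt, founder_cap, rng,
                )
            for child_key, mu in (("10", mu_high), ("01", mu_low)):
                b_c, d_c = child_rates[child_key]
                _wt_founding_step(
                    pools[child_key], mu, n0, r00, t1, dt, b_c, d_c, b_c - d_c,
                    founder_cap, rng,
                )
            for pool in pools.values():
                _promote(pool, hybrid_cutoff)

        wt_end = n0 * math.exp(r00 * t_n)
        state.wt_size = wt_end
        state.time_in_cycle = t_n
        threshold = max(establish_threshold, establish_fraction * wt_end)

        end = {k: pools[k].total for k in POOL_KEYS}
        end["11"] = end["11_from10"] + end["11_from01"]
        foundings = {k: pools[k].foundings for k in POOL_KEYS}
        foundings["11"] = foundings["11_from10"] + foundings["11_from01"]
        established = {k: end[k] >= threshold for k in end}

        apply_bottleneck(state, d_n, rng, hybrid_cutoff)
        post = {k: pools[k].total for k in POOL_KEYS}
        post["11"] = post["11_from10"] + post["11_from01"]
        survived = {k: established[k] and post[k] > 0 for k in post}

        records.append(
            CycleRecord(
                cycle=cycle,
                duration=t_n,
                wt_end=wt_end,
                foundings=foundings,
                end_size=end,
                established=established,
                post_size=post,
                survived=survived,
            )
        )
        state.cycle = cycle + 1

    return records, state


def classify_observed(records: list[CycleRecord]) -> PathConfiguration:
    """Map a simulated run onto the nearest canonical path configuration.

    Transitions carry a founding event whose target genotype established in
    some cycle; a genotype *survives* when it passed at least one bottleneck
    and is non-extinct after the final one.  Runs without any established
    mutant get the label ``"none"``; patterns outside the six canonical
    configurations (expected near phase boundaries) get ``"unclassified"``.
    """
    if not records:
        raise ParameterError("classify_observed requires at least one cycle record")

    def est(key: str) -> bool:
        return any(r.established[key] for r in records)

    def surv(key: str) -> bool:
        # survives = reached the establishment threshold, passed at least one
        # bottleneck, and is non-extinct at the end of the run
        return (
            est(key)
            and any(r.survived[key] for r in records)
            and records[-1].post_size[key] > 0
        )

    est10, est01, est11 = est("10"), est("01"), est("11")
    surv10, surv01, surv11 = surv("10"), surv("01"), surv("11")
    founded_from10 = any(r.foundings["11_from10"] > 0 for r in records)
    founded_from01 = any(r.foundings["11_from01"] > 0 for r in records)
    via10 = est11 and est10 and founded_from10
    via01 = est11 and est01 and founded_from01

    transitions = set()
    if est10:
        transitions.add(("00", "10"))
    if est01:
        transitions.add(("00", "01"))
    if via10:
        transitions.add(("10", "11"))
    if via01:
        transitions.add(("01", "11"))

    def status_of(established: bool, survives: bool) -> str:
        if not established:
            return "absent"
        return "survives" if survives else "establishes_each_cycle"

    status = {
        "10": status_of(est10, surv10),
        "01": status_of(est01, surv01),
        "11": status_of(est11, surv11),
    }

    # a parent displaced *after* feeding the double mutant (end state of a
    # completed adaptive sweep, or clonal interference) still defines the route
    def passed_bottleneck(key: str) -> bool:
        return est(key) and any(r.survived[key] for r in records)

    flags: list[str] = []
    if not (est10 or est01 or est11):
        label = "none"
    elif est11 and not (via10 or via01):
        label = "unclassified"
        flags.append("double_mutant_without_established_parent")
    elif surv10 and surv01:
        label = "all_survive"
    elif surv10:
        label = "10survives_01establishes" if est01 else "10survives_11from10"
    elif surv01:
        label = "01survives_11from01" if est10 else "unclassified"
    elif surv11:
        # neither parent is alive at the end: color by the realized routes
        route10 = via10 and passed_bottleneck("10")
        route01 = via01 and passed_bottleneck("01")
        flags.append("double_mutant_survives_without_surviving_parent")
        if route10 and route01:
            label = "all_survive"
        elif route01:
            label = "01survives_11from01"
        elif route10:
            label = "10survives_01establishes" if est01 else "10survives_11from10"
        else:
            label = "unclassified"
    elif est10:
        label = "10and01_no_survival" if est01 else "only10"
    else:
        label = "unclassified"

    assert label in LABELS + ("none", "unclassified")
    return PathConfiguration(
        transitions=frozenset(transitions), status=status, label=label, flags=tuple(flags)
    )
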