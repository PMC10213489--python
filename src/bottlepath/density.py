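"""Density-dependent serial-passage simulator.

Relaxes the unlimited-growth assumption: intrinsic division and death rates
of every genotype are multiplied by ``max(0, 1 - Ntot/K)``, where ``Ntot`` is
the current total population size and ``K`` the carrying capacity of that
genotype's class — ``K_wt = n**alpha`` for the wild type and
``K_mut = n**alpha * (1 + s)`` for all mutants, whose small advantage in
exploiting the medium lets them keep growing after the wild type saturates.

The growth phase ends when the *total* population reaches a fraction ``p`` of
the wild-type capacity, upon which every genotype is diluted by the constant
factor ``D = N0 / (p * K_wt)``.  While the wild type dominates the culture
this is exactly a bottleneck returning it to ``N0``; once a mutant has taken
over (the clonal-interference regime) the protocol stays well defined and the
outcompeted genotypes are washed out by the repeated dilutions.

Mutation supply is tied to replication: founding fluxes carry the parent's
division-rate factor, so mutants stop arising when their parent's divisions
stop.  The hybrid stochastic/deterministic machinery is shared with
:mod:`bottlepath.simulate`; density factors are frozen within each (adaptive)
time step, with steps chosen so the factors move by at most a few percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    DemographyParams,
    FitnessLandscape,
    ParameterError,
    rates_from_net,
)
from .simulate import (
    DEFAULT_ESTABLISH_THRESHOLD,
    DEFAULT_FOUNDER_CAP,
    DEFAULT_HYBRID_CUTOFF,
    DEFAULT_MAX_STEP_GROWTH,
    POOL_KEYS,
    CycleRecord,
    GenotypePool,
    PopulationState,
    _bd_evolve_singletons,
    _bd_evolve_sizes,
    _exp_integral,
    _fresh_pools,
    _promote,
    _thin_mass,
)

__all__ = [
    "DensityParams",
    "DilutionTriggerError",
    "density_factor",
    "run_density_cycles",
]


class DilutionTriggerError(RuntimeError):
    """The dilution trigger was not reached within the time guard."""


@dataclass(frozen=True)
class DensityParams:
    """Carrying capacities and dilution-trigger parameters.

    ``s`` is the mutants' capacity advantage (``K_mut = K_wt * (1 + s)``),
    ``p`` the fraction of the wild-type capacity at which the culture is
    diluted, ``death_rate`` the intrinsic per-capita death rate shared by all
    genotypes.  ``double_mutant_capacity`` selects which capacity class the
    double mutant belongs to (``"mut"`` by default, ``"wt"`` otherwise).
    """

    s: float = 0.1
    p: float = 0.5
    death_rate: float = 0.1
    double_mutant_capacity: str = "mut"

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ParameterError(f"capacity advantage must satisfy s >= 0 (got {self.s})")
        if not 0 < self.p <= 1:
            raise ParameterError(f"trigger fraction must satisfy 0 < p <= 1 (got {self.p})")
        if self.death_rate < 0:
            raise ParameterError(f"death rate must be non-negative (got {self.death_rate})")
        if self.double_mutant_capacity not in ("mut", "wt"):
            raise ParameterError("double_mutant_capacity must be 'mut' or 'wt'")

    def k_wt(self, params: DemographyParams) -> float:
        return params.Nfin

    def k_mut(self, params: DemographyParams) -> float:
        return params.Nfin * (1.0 + self.s)


def density_factor(total_size: float, capacity: float) -> float:
    """Logistic modulation ``max(0, 1 - Ntot/K)`` of division and death rates."""
    if capacity <= 0:
        raise ParameterError(f"carrying capacity must be positive (got {capacity})")
    return max(0.0, 1.0 - total_size / capacity)


def run_density_cycles(
    params: DemographyParams,
    landscape: FitnessLandscape,
    density: DensityParams,
    n_cycles: int = 7,
    rng: np.random.Generator | int | None = None,
    hybrid_cutoff: float = DEFAULT_HYBRID_CUTOFF,
    establish_threshold: float = DEFAULT_ESTABLISH_THRESHOLD,
    establish_fraction: float = 0.0,
    founder_cap: float = DEFAULT_FOUNDER_CAP,
    max_step_growth: float = DEFAULT_MAX_STEP_GROWTH,
    max_factor_change: float = 0.02,
    time_guard_factor: float = 50.0,
    mu_high: float | None = None,
    mu_low: float | None = None,
) -> tuple[list[CycleRecord], PopulationState]:
    """Simulate serial passages with density-modulated rates.

    The cycle duration is emergent (time for the total population to reach
    ``p * K_wt``); a cycle exceeding ``time_guard_factor`` times the
    density-free duration raises :class:`DilutionTriggerError`.
    ``mu_high``/``mu_low`` override the rates implied by ``params``.
    """
    if n_cycles < 1:
        raise ParameterError("n_cycles must be >= 1")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    mu_high = params.mu_high if mu_high is None else mu_high
    mu_low = params.mu_low if mu_low is None else mu_low
    if mu_high < 0 or mu_low < 0:
        raise ParameterError("mutation rates must be non-negative")

    rates = rates_from_net(landscape, density.death_rate)
    n0 = params.N0
    r00 = landscape.r00
    k_wt = density.k_wt(params)
    k_mut = density.k_mut(params)
    capacity = {
        "10": k_mut,
        "01": k_mut,
        "11_from10": k_mut if density.double_mutant_capacity == "mut" else k_wt,
        "11_from01": k_mut if density.double_mutant_capacity == "mut" else k_wt,
    }
    target = density.p * k_wt
    if n0 >= target:
        raise ParameterError("initial size already exceeds the dilution trigger")
    dilution = n0 / target
    t_free = params.t_n(r00)
    guard = time_guard_factor * t_free
    dt0 = max_step_growth / r00

    state = PopulationState(cycle=1, time_in_cycle=0.0, wt_size=n0, n0=n0, pools=_fresh_pools())
    records: list[CycleRecord] = []

    child_rates = {k: (rates.birth[k[:2]], rates.death[k[:2]]) for k in POOL_KEYS}
    emissions = (
        ("10", "11_from10", mu_low),
        ("01", "11_from01", mu_high),
    )

    for cycle in range(1, n_cycles + 1):
        pools = state.pools
        for p_ in pools.values():
            p_.foundings = 0.0
        t = 0.0
        wt = state.wt_size
        while True:
            totals = {k: pools[k].total for k in POOL_KEYS}
            ntot = wt + sum(totals.values())
            if ntot >= target:
                break
            if t > guard:
                raise DilutionTriggerError(
                    f"total population did not reach p*K_wt within {guard:.3g} time units "
                    f"(cycle {cycle}); check p, s and the capacity parameters"
                )
            f_wt = density_factor(ntot, k_wt)
            f = {k: density_factor(ntot, capacity[k]) for k in POOL_KEYS}

            # adaptive step: cap the per-step change of the density factors
            growth_speed = r00 * f_wt * wt + sum(
                (child_rates[k][0] - child_rates[k][1]) * f[k] * totals[k] for k in POOL_KEYS
            )
            dt = dt0
            if growth_speed > 0:
                dt = min(dt, max_factor_change * k_wt / growth_speed)
                # do not wildly overshoot the trigger
                dt = min(dt, max(1.05 * (target - ntot) / growth_speed, 1e-3 * dt0))

            # double mutants first, then emission from single mutants, then
            # founding from the wild type (order as in the exponential engine)
            for key in ("11_from10", "11_from01"):
                pool = pools[key]
                b, d = child_rates[key]
                bf, df = b * f[key], d * f[key]
                if pool.sizes.size:
                    new = _bd_evolve_sizes(pool.sizes, bf, df, dt, rng)
                    pool.sizes = new[new > 0]
                if pool.det_mass > 0:
                    pool.det_mass *= math.exp((bf - df) * dt)
            for parent_key, child_key, mu_out in emissions:
                parent, child = pools[parent_key], pools[child_key]
                b_p, d_p = child_rates[parent_key]
                b_c, d_c = child_rates[child_key]
                fp, fc = f[parent_key], f[child_key]
                bpf, dpf = b_p * fp, d_p * fp
                bcf, dcf = b_c * fc, d_c * fc
                r_pf, r_cf = bpf - dpf, bcf - dcf
                mu_eff = mu_out * fp  # mutation happens at division
                old = parent.sizes
                if old.size:
                    new = _bd_evolve_sizes(old, bpf, dpf, dt, rng)
                    if mu_eff > 0:
                        k = int(rng.poisson(mu_eff * 0.5 * (old + new) * dt).sum())
                        if k:
                            child.foundings += k
                            child.ever_founded = True
                            sizes = _bd_evolve_singletons(rng.uniform(0.0, dt, k), bcf, dcf, rng)
                            sizes = sizes[sizes > 0]
                            if sizes.size:
                                child.sizes = np.concatenate([child.sizes, sizes])
                    parent.sizes = new[new > 0]
                if parent.det_mass > 0:
                    if mu_eff > 0:
                        mean = (
                            mu_eff * parent.det_mass * math.expm1(r_pf * dt) / r_pf
                            if r_pf != 0
                            else mu_eff * parent.det_mass * dt
                        )
                        if mean <= founder_cap:
                            k = rng.poisson(mean)
                            if k:
                                child.foundings += k
                                child.ever_founded = True
                                sizes = _bd_evolve_singletons(
                                    rng.uniform(0.0, dt, k), bcf, dcf, rng
                                )
                                sizes = sizes[sizes > 0]
                                if sizes.size:
                                    child.sizes = np.concatenate([child.sizes, sizes])
                        else:
                            child.foundings += mean
                            child.ever_founded = True
                            child.det_mass += mu_out * fp * _exp_integral(
                                parent.det_mass, r_pf, r_cf, dt
                            )
                    parent.det_mass *= math.exp(r_pf * dt)
            r_wt = r00 * f_wt
            for child_key, mu in (("10", mu_high), ("01", mu_low)):
                pool = pools[child_key]
                b_c, d_c = child_rates[child_key]
                fc = f[child_key]
                bcf, dcf = b_c * fc, d_c * fc
                mu_eff = mu * f_wt
                if mu_eff > 0 and wt > 0:
                    lam = (
                        mu_eff * wt * math.expm1(r_wt * dt) / r_wt
                        if r_wt != 0
                        else mu_eff * wt * dt
                    )
                    if lam <= founder_cap:
                        k = rng.poisson(lam)
                        pool.foundings += k
                        if k:
                            pool.ever_founded = True
                            if r_wt != 0:
                                u = rng.random(k)
                                offsets = np.log1p(u * math.expm1(r_wt * dt)) / r_wt
                            else:
                                offsets = rng.uniform(0.0, dt, k)
                            sizes = _bd_evolve_singletons(dt - offsets, bcf, dcf, rng)
                            sizes = sizes[sizes > 0]
                            if sizes.size:
                                pool.sizes = np.concatenate([pool.sizes, sizes])
                    else:
                        pool.foundings += lam
                        pool.ever_founded = True
                        pool.det_mass += mu_eff * _exp_integral(wt, r_wt, bcf - dcf, dt)
            wt *= math.exp(r_wt * dt)
            for pool in pools.values():
                _promote(pool, hybrid_cutoff)
            t += dt

        state.wt_size = wt
        state.time_in_cycle = t
        threshold = max(establish_threshold, establish_fraction * wt)

        end = {k: pools[k].total for k in POOL_KEYS}
        end["11"] = end["11_from10"] + end["11_from01"]
        foundings = {k: pools[k].foundings for k in POOL_KEYS}
        foundings["11"] = foundings["11_from10"] + foundings["11_from01"]
        established = {k: end[k] >= threshold for k in end}

        # constant-severity dilution; the wild type returns to N0 exactly as
        # long as it dominates the culture at the trigger
        for pool in pools.values():
            if pool.sizes.size:
                thinned = rng.binomial(pool.sizes, dilution)
                pool.sizes = thinned[thinned > 0]
            if pool.det_mass > 0:
                if pool.det_mass * dilution < 10.0 * hybrid_cutoff:
                    kk = _thin_mass(pool.det_mass, dilution, rng)
                    pool.det_mass = 0.0
                    if kk:
                        pool.sizes = np.concatenate([pool.sizes, np.array([kk], dtype=np.int64)])
                else:
                    pool.det_mass *= dilution
        wt_end = state.wt_size
        state.wt_size = wt_end * dilution
        state.time_in_cycle = 0.0

        post = {k: pools[k].total for k in POOL_KEYS}
        post["11"] = post["11_from10"] + post["11_from01"]
        survived = {k: established[k] and post[k] > 0 for k in post}

        records.append(
            CycleRecord(
                cycle=cycle,
                duration=t,
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
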