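"""Finite-``n`` numerical mutant-flux oracle.

Independent check of the analytic thresholds: instead of exponent algebra it
integrates, on a fine time grid, the deterministic *typical* mutant dynamics
of one protocol at a finite value of ``n``:

* the wild type is ``N_t = n**beta * exp(r00 * t)`` within each cycle;
* the expected founding flux of genotype ``g'`` from parent ``g`` is
  ``mu_{g->g'} * (size of g at time t)``;
* a genotype *establishes* during cycle ``k`` when its founding flux
  integrated over that cycle first reaches 1 (one expected founder) — before
  that moment its size is held at zero, which discards the rare jackpot
  founders that dominate the mean but not the typical trajectory;
* an established population *survives* the bottleneck when its end-of-cycle
  size times ``D_n`` is at least 1, in which case the thinned remainder is
  carried into the next cycle.

Threshold exponents are then located by bisection on ``alpha``: the value at
which the oracle's verdict flips converges to the analytic line as ``n``
grows (with a drift of order ``1/ln n`` from the neglected subpolynomial
factors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import DemographyParams, FitnessLandscape

__all__ = ["OracleResult", "run_flux_oracle", "flip_alpha", "oracle_k11"]

_SIZE_CAP = 1e250  # keeps multi-cycle exponent growth inside float64


@dataclass(frozen=True)
class OracleResult:
    """Typical-dynamics verdicts of one finite-``n`` protocol."""

    established_cycle: dict[str, float]  # first establishment cycle per genotype/route
    survives: dict[str, bool]  # 10 / 01 survive some bottleneck
    k11: float
    route: str | None


def _grow_with_source(z0: float, flux: np.ndarray, t: np.ndarray, r: float) -> np.ndarray:
    """Solve ``dZ/dt = r Z + flux(t)`` with ``Z(0) = z0`` on the grid ``t``.

    Stepwise exact integration (exponential propagator, trapezoidal source)
    so that no intermediate factor ``exp(r * t)`` is formed on its own.
    """
    z = np.empty_like(t)
    z[0] = z0
    dt = np.diff(t)
    growth = np.exp(r * dt)
    zi = z0
    for i in range(len(dt)):
        zi = zi * growth[i] + 0.5 * dt[i] * (flux[i] * growth[i] + flux[i + 1])
        if zi > _SIZE_CAP:
            zi = _SIZE_CAP
        z[i + 1] = zi
    return z


def _gated_flux(flux: np.ndarray, t: np.ndarray, carried: float) -> tuple[np.ndarray, bool]:
    """Zero the flux before its within-cycle integral reaches one founder.

    A population carried over from the previous cycle is already established,
    so its source is active from the start of the cycle.
    """
    cum = np.concatenate(([0.0], np.cumsum(0.5 * np.diff(t) * (flux[:-1] + flux[1:]))))
    if carried > 0:
        return flux, True
    idx = np.searchsorted(cum, 1.0)
    if idx >= len(t):
        return np.zeros_like(flux), False
    gated = flux.copy()
    gated[:idx] = 0.0
    return gated, True


def run_flux_oracle(
    beta: float,
    alpha: float,
    landscape: FitnessLandscape,
    delta: float,
    n: float,
    n_cycles: int = 12,
    points_per_cycle: int = 2000,
) -> OracleResult:
    """Integrate the typical mutant-flux cascade over ``n_cycles`` cycles."""
    dem = DemographyParams(n=n, beta=beta, alpha=alpha, delta=delta)
    t_n = dem.t_n(landscape.r00)
    if landscape.r01 * t_n > 690:
        raise OverflowError(
            "cycle too long for direct-size integration; reduce n or alpha - beta"
        )
    t = np.linspace(0.0, t_n, points_per_cycle + 1)
    wt = dem.N0 * np.exp(landscape.r00 * t)

    est: dict[str, float] = {g: math.inf for g in ("10", "01", "from10", "from01")}
    surv = {"10": False, "01": False}
    carried = {"10": 0.0, "01": 0.0}

    for cycle in range(1, n_cycles + 1):
        sizes: dict[str, np.ndarray] = {}
        for g, mu, r in (
            ("10", dem.mu_high, landscape.r10),
            ("01", dem.mu_low, landscape.r01),
        ):
            flux = mu * wt
            gated, active = _gated_flux(flux, t, carried[g])
            if active:
                sizes[g] = _grow_with_source(carried[g], gated, t, r)
                est[g] = min(est[g], cycle)
            else:
                sizes[g] = np.zeros_like(t)
        # Double-mutant routes: only the integrated founding flux matters here.
        for route, parent, mu_out in (
            ("from10", "10", dem.mu_low),
            ("from01", "01", dem.mu_high),
        ):
            flux11 = mu_out * sizes[parent]
            total = np.trapezoid(flux11, t)
            if total >= 1.0:
                est[route] = min(est[route], cycle)
        for g in ("10", "01"):
            end = float(sizes[g][-1])
            post = end * dem.D_n
            if post >= 1.0:
                surv[g] = True
                carried[g] = min(post, _SIZE_CAP)
            else:
                carried[g] = 0.0
        if est["from10"] < math.inf and est["from01"] < math.inf:
            break

    k11 = min(est["from10"], est["from01"])
    if math.isinf(k11):
        route = None
    elif est["from10"] == est["from01"]:
        route = "either"
    else:
        route = "from10" if est["from10"] < est["from01"] else "from01"
    return OracleResult(
        established_cycle={"10": est["10"], "01": est["01"], "from10": est["from10"], "from01": est["from01"]},
        survives=surv,
        k11=k11,
        route=route,
    )


def oracle_k11(
    beta: float,
    alpha: float,
    landscape: FitnessLandscape,
    delta: float,
    n: float,
    n_cycles: int = 12,
    points_per_cycle: int = 2000,
) -> float:
    """First cycle at which the oracle sees double mutants establish."""
    return run_flux_oracle(beta, alpha, landscape, delta, n, n_cycles, points_per_cycle).k11


def flip_alpha(
    predicate,
    lo: float,
    hi: float,
    tol: float = 5e-4,
) -> float:
    """Locate by bisection the ``alpha`` at which ``predicate`` turns true.

    ``predicate`` must be monotone in ``alpha`` (false below the flip, true
    above); ``predicate(hi)`` must hold and ``predicate(lo)`` must not.
    """
    if predicate(lo):
        raise ValueError(f"predicate already true at the lower bracket alpha={lo}")
    if not predicate(hi):
        raise ValueError(f"predicate still false at the upper bracket alpha={hi}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if predicate(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def first_cycle_flip(
    route: str,
    landscape: FitnessLandscape,
    delta: float,
    n: float,
    beta: float = 0.5,
    lo: float | None = None,
    hi: float | None = None,
    tol: float = 5e-4,
    points_per_cycle: int = 4000,
) -> float:
    """Oracle flip point of first-cycle double-mutant establishment.

    ``route`` is ``"from01"`` (analytic limit: line (4)) or ``"from10"``
    (line (5)).  Both analytic lines are independent of ``beta``.
    """
    if route not in ("from10", "from01"):
        raise ValueError(f"unknown route {route!r}")
    lo = (delta if route == "from01" else 1.0) + 0.02 if lo is None else lo
    hi = 3.5 if hi is None else hi

    def pred(alpha: float) -> bool:
        res = run_flux_oracle(
            beta, alpha, landscape, delta, n, n_cycles=1, points_per_cycle=points_per_cycle
        )
        return res.established_cycle[route] == 1

    return flip_alpha(pred, lo, hi, tol)


def k11_flip(
    k: int,
    beta: float,
    landscape: FitnessLandscape,
    delta: float,
    n: float,
    lo: float,
    hi: float,
    tol: float = 5e-4,
    points_per_cycle: int = 2000,
) -> float:
    """Oracle flip point of ``k11 <= k`` as ``alpha`` increases at fixed ``beta``."""

    def pred(alpha: float) -> bool:
        return oracle_k11(beta, alpha, landscape, delta, n, n_cycles=max(k + 2, 8),
                          points_per_cycle=points_per_cycle) <= k

    return flip_alpha(pred, lo, hi, tol)


def analytic_k11_flip(
    k: int,
    beta: float,
    landscape: FitnessLandscape,
    delta: float,
    lo: float,
    hi: float,
    tol: float = 1e-9,
) -> float:
    """Analytic flip point of ``k11 <= k``, from the exponent recursion."""
    from .theory import predict_establishment_cycle

    def pred(alpha: float) -> bool:
        return predict_establishment_cycle(beta, alpha, landscape, delta, max_cycles=None).k11 <= k

    return flip_alpha(pred, lo, hi, tol)
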