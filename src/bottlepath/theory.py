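"""Analytic phase diagram of evolutionary paths under periodic bottlenecks.

In the limit of large ``n`` (large populations, small mutation rates), whether
a mutant subpopulation *establishes* (is present in non-negligible quantity at
the end of a growth phase) and *survives* (passes through the bottleneck, and
then every subsequent one) is decided by inequalities between the demographic
exponents ``(beta, alpha)`` and threshold lines in that plane:

* line (1): ``alpha = (r10 - beta*r00) / (r10 - r00)`` — above it the weakly
  beneficial ``10`` population survives every bottleneck (its end-of-cycle
  size ``~ n**((alpha-1)*r10/r00)`` beats the dilution ``n**(alpha-beta)``);
* line (2): ``alpha = delta`` — above it the strongly beneficial ``01``
  establishes during the first cycle, below it it essentially never arises;
* line (3): ``alpha = (delta*r01 - beta*r00) / (r01 - r00)`` — above it ``01``
  survives the bottlenecks;
* line (4): ``alpha = delta + r00/r01`` — above it double mutants establish
  during the first cycle out of the ``01`` background (the end-of-cycle ``01``
  exponent ``(alpha-delta)*r01/r00`` reaches 1, the inverse high rate);
* line (5): ``alpha = 1 + delta*r00/r10`` — above it double mutants establish
  during the first cycle out of the ``10`` background (the ``10`` exponent
  ``(alpha-1)*r10/r00`` reaches ``delta``).

Lines (1) and (3) partition the admissible domain ``0 < beta < 1 < alpha``
into four corners (Southwest: no mutant survives; Southeast: adaptation via
``10``; Northwest: via ``01``; Northeast: via both), refined by lines (2), (4)
and (5) into six canonical path configurations.  Points exactly on a line are
assigned to the region above it.

Lines (4), (5) and the multi-cycle establishment recursion are validated
against an independent finite-``n`` numerical oracle in
:mod:`bottlepath.oracle`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

from .core import FitnessLandscape, ParameterError

__all__ = [
    "LABELS",
    "STATUS_VALUES",
    "PathConfiguration",
    "EstablishmentForecast",
    "OptimalBeta",
    "line1_alpha",
    "line2_alpha",
    "line3_alpha",
    "line4_alpha",
    "line5_alpha",
    "corner",
    "classify",
    "single_mutant_end_exponent",
    "predict_establishment_cycle",
    "optimal_beta",
    "recommended_dilution",
]

#: Canonical path-configuration labels (phase-diagram colors in parentheses):
#: only10 (purple), 10and01_no_survival (green), 10survives_11from10 (blue),
#: 10survives_01establishes (yellow), 01survives_11from01 (orange),
#: all_survive (red).
LABELS: tuple[str, ...] = (
    "only10",
    "10and01_no_survival",
    "10survives_11from10",
    "10survives_01establishes",
    "01survives_11from01",
    "all_survive",
)

STATUS_VALUES = ("absent", "establishes_each_cycle", "survives")

_EPS = 1e-12


@dataclass(frozen=True)
class PathConfiguration:
    """Realized transitions and per-genotype establish/survive status.

    ``transitions`` is the subset of the mutational network that carries at
    least one establishing lineage; ``status`` maps each mutant genotype to
    ``absent``, ``establishes_each_cycle`` (arises every cycle but is lost at
    each bottleneck) or ``survives``.
    """

    transitions: frozenset[tuple[str, str]]
    status: dict[str, str]
    label: str
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            # observed runs may fall outside the six canonical configurations
            # ("none" before any establishment, "unclassified" near boundaries)
            return
        if ("00", "10") not in self.transitions:
            raise ParameterError("every path configuration includes the 00->10 transition")
        if ("10", "11") in self.transitions and self.status.get("10") == "absent":
            raise ParameterError("10->11 requires genotype 10 to be present")
        if ("01", "11") in self.transitions and self.status.get("01") == "absent":
            raise ParameterError("01->11 requires genotype 01 to be present")
        if self.status.get("11", "absent") != "absent" and not (
            ("10", "11") in self.transitions or ("01", "11") in self.transitions
        ):
            raise ParameterError("genotype 11 requires at least one incoming transition")


@dataclass(frozen=True)
class EstablishmentForecast:
    """Predicted cycle of double-mutant establishment and its route."""

    config: PathConfiguration
    k11: float  # positive integer, or math.inf
    route: str | None  # "from10", "from01", "either", or None when k11 is inf


class OptimalBeta(NamedTuple):
    beta: float
    clipped: bool


def line1_alpha(beta: float, landscape: FitnessLandscape) -> float:
    """Survival threshold of the ``10`` mutant: ``(r10 - beta*r00)/(r10 - r00)``."""
    if landscape.r10 <= landscape.r00:
        raise ParameterError("line (1) requires r10 > r00")
    if not 0 < beta < 1:
        raise ParameterError(f"line (1) is defined for 0 < beta < 1 (got beta={beta})")
    return (landscape.r10 - beta * landscape.r00) / (landscape.r10 - landscape.r00)


def line2_alpha(delta: float) -> float:
    """Establishment threshold of the ``01`` mutant: ``alpha = delta``."""
    if not delta > 1:
        raise ParameterError(f"line (2) requires delta > 1 (got delta={delta})")
    return delta


def line3_alpha(beta: float, landscape: FitnessLandscape, delta: float) -> float:
    """Survival threshold of the ``01`` mutant: ``(delta*r01 - beta*r00)/(r01 - r00)``."""
    if landscape.r01 <= landscape.r00:
        raise ParameterError("line (3) requires r01 > r00")
    if not 0 < beta < 1:
        raise ParameterError(f"line (3) is defined for 0 < beta < 1 (got beta={beta})")
    if not delta > 1:
        raise ParameterError(f"line (3) requires delta > 1 (got delta={delta})")
    return (delta * landscape.r01 - beta * landscape.r00) / (landscape.r01 - landscape.r00)


def line4_alpha(landscape: FitnessLandscape, delta: float) -> float:
    """First-cycle double-mutant establishment out of ``01``: ``delta + r00/r01``.

    The ``01`` population, established once the wild type reaches ``n**delta``,
    ends the first cycle at exponent ``(alpha - delta)*r01/r00``; double
    mutants (rate ``mu_high = 1/n``) establish as soon as that exponent
    reaches 1.  Independent of ``beta``.
    """
    if not delta > 1:
        raise ParameterError(f"line (4) requires delta > 1 (got delta={delta})")
    return delta + landscape.r00 / landscape.r01


def line5_alpha(landscape: FitnessLandscape, delta: float) -> float:
    """First-cycle double-mutant establishment out of ``10``: ``1 + delta*r00/r10``.

    The ``10`` population ends the first cycle at exponent
    ``(alpha - 1)*r10/r00``; double mutants (rate ``mu_low = n**-delta``)
    establish as soon as that exponent reaches ``delta``.  Independent of
    ``beta``.
    """
    if not delta > 1:
        raise ParameterError(f"line (5) requires delta > 1 (got delta={delta})")
    return 1.0 + delta * landscape.r00 / landscape.r10


def _check_point(beta: float, alpha: float) -> None:
    if not 0 < beta < 1:
        raise ParameterError(f"admissible domain requires 0 < beta < 1 (got beta={beta})")
    if not alpha > 1:
        raise ParameterError(f"admissible domain requires alpha > 1 (got alpha={alpha})")


def corner(beta: float, alpha: float, landscape: FitnessLandscape, delta: float) -> str:
    """Corner zone (``SW``/``SE``/``NW``/``NE``) cut out by lines (1) and (3)."""
    _check_point(beta, alpha)
    surv10 = alpha >= line1_alpha(beta, landscape) - _EPS
    surv01 = alpha >= line3_alpha(beta, landscape, delta) - _EPS
    return {(False, False): "SW", (True, False): "SE", (False, True): "NW", (True, True): "NE"}[
        (surv10, surv01)
    ]


def single_mutant_end_exponent(
    genotype: str,
    k: int,
    beta: float,
    alpha: float,
    landscape: FitnessLandscape,
    delta: float,
) -> float:
    """End-of-cycle-``k`` size exponent (base ``n``) of a surviving single mutant.

    A surviving mutant population multiplies by ``exp(r_g * t_n) * D_n`` per
    cycle, i.e. gains ``(alpha - beta)*(r_g - r00)/r00`` in exponent, on top of
    its first-cycle exponent (``(alpha-1)*r10/r00`` for ``10``,
    ``(alpha-delta)*r01/r00`` for ``01``).  Valid under unchecked exponential
    growth only.
    """
    if k < 1:
        raise ParameterError(f"cycle index must be >= 1 (got {k})")
    r00 = landscape.r00
    if genotype == "10":
        first = (alpha - 1.0) * landscape.r10 / r00
        gain = (alpha - beta) * (landscape.r10 - r00) / r00
    elif genotype == "01":
        first = (alpha - delta) * landscape.r01 / r00
        gain = (alpha - beta) * (landscape.r01 - r00) / r00
    else:
        raise ParameterError(f"end exponent defined for single mutants only (got {genotype!r})")
    return first + (k - 1) * gain


def classify(
    beta: float, alpha: float, landscape: FitnessLandscape, delta: float
) -> PathConfiguration:
    """Predicted path configuration at ``(beta, alpha)`` in the large-``n`` limit.

    Deterministic mapping: ``10`` always establishes and survives iff
    ``alpha >= line1``; ``01`` is absent below ``alpha = delta``, survives
    above line (3); the double-mutant status follows from which parental
    routes are recurrent (surviving parent) or first-cycle (above line (4) or
    (5)).  The label encodes the survival pattern of the single mutants; the
    rare case of a double mutant surviving although neither parent does is
    reported through ``flags``, not as a seventh label.
    """
    _check_point(beta, alpha)
    r00 = landscape.r00

    surv10 = alpha >= line1_alpha(beta, landscape) - _EPS
    present01 = alpha >= line2_alpha(delta) - _EPS
    surv01 = present01 and alpha >= line3_alpha(beta, landscape, delta) - _EPS
    first_cycle_via01 = present01 and alpha >= line4_alpha(landscape, delta) - _EPS
    first_cycle_via10 = alpha >= line5_alpha(landscape, delta) - _EPS

    status = {
        "10": "survives" if surv10 else "establishes_each_cycle",
        "01": ("survives" if surv01 else "establishes_each_cycle") if present01 else "absent",
    }

    # Routes toward the double mutant: a surviving parent keeps growing across
    # cycles and eventually feeds an establishing-and-surviving 11 population;
    # a non-surviving parent can only seed 11 afresh each cycle, which requires
    # being above the corresponding first-cycle line.
    recurrent = surv10 or surv01
    via10 = surv10 or first_cycle_via10
    via01 = surv01 or first_cycle_via01

    transitions = {("00", "10")}
    if present01:
        transitions.add(("00", "01"))
    if via10:
        transitions.add(("10", "11"))
    if via01:
        transitions.add(("01", "11"))

    flags: list[str] = []
    if via10 or via01:
        if recurrent:
            status["11"] = "survives"
        else:
            status["11"] = "establishes_each_cycle"
            # Establishing-only 11 survives the bottleneck anyway when its
            # end-of-cycle exponent beats the dilution exponent (high r11).
            e11 = -math.inf
            if first_cycle_via01:
                z01 = (alpha - delta) * landscape.r01 / r00
                e11 = max(e11, (z01 - 1.0) * landscape.r11 / landscape.r01)
            if first_cycle_via10:
                z10 = (alpha - 1.0) * landscape.r10 / r00
                e11 = max(e11, (z10 - delta) * landscape.r11 / landscape.r10)
            if e11 > alpha - beta:
                flags.append("double_mutant_survives_without_surviving_parent")
    else:
        status["11"] = "absent"

    if surv10 and surv01:
        label = "all_survive"
    elif surv10:
        label = "10survives_01establishes" if present01 else "10survives_11from10"
    elif surv01:
        label = "01survives_11from01"
    else:
        label = "10and01_no_survival" if present01 else "only10"

    return PathConfiguration(
        transitions=frozenset(transitions), status=status, label=label, flags=tuple(flags)
    )


def predict_establishment_cycle(
    beta: float,
    alpha: float,
    landscape: FitnessLandscape,
    delta: float,
    max_cycles: int | None = 7,
) -> EstablishmentForecast:
    """Predicted cycle at which double mutants first establish.

    ``k11 = 1`` exactly when ``alpha`` is on or above line (4) or line (5).
    Otherwise the first cycle ``k`` at which a *surviving* parent's
    end-of-cycle exponent reaches the inverse mutation-rate exponent
    (``delta`` for the ``10`` route, ``1`` for the ``01`` route) is returned,
    minimized over the available routes; ``inf`` when no route exists (the
    Southwest corner) or when ``k`` exceeds ``max_cycles`` (pass ``None`` for
    an unbounded horizon).
    """
    config = classify(beta, alpha, landscape, delta)
    present01 = config.status["01"] != "absent"

    first_via01 = present01 and alpha >= line4_alpha(landscape, delta) - _EPS
    first_via10 = alpha >= line5_alpha(landscape, delta) - _EPS
    if first_via01 or first_via10:
        if first_via01 and first_via10:
            route = "either"
        else:
            route = "from01" if first_via01 else "from10"
        return EstablishmentForecast(config=config, k11=1, route=route)

    def cycles_needed(genotype: str, target: float) -> float:
        e1 = single_mutant_end_exponent(genotype, 1, beta, alpha, landscape, delta)
        if e1 >= target - _EPS:
            return 1.0
        r_g = landscape.r10 if genotype == "10" else landscape.r01
        gain = (alpha - beta) * (r_g - landscape.r00) / landscape.r00
        return 1.0 + math.ceil((target - e1) / gain - _EPS)

    k10 = cycles_needed("10", delta) if config.status["10"] == "survives" else math.inf
    k01 = cycles_needed("01", 1.0) if config.status["01"] == "survives" else math.inf

    k11 = min(k10, k01)
    if math.isinf(k11):
        route = None
    elif k10 == k01:
        route = "either"
    else:
        route = "from10" if k10 < k01 else "from01"
    if max_cycles is not None and k11 > max_cycles:
        k11, route = math.inf, None
    return EstablishmentForecast(config=config, k11=k11, route=route)


def optimal_beta(alpha: float, landscape: FitnessLandscape) -> OptimalBeta:
    """Initial-size exponent minimizing the double-mutant establishment cycle.

    ``beta* = alpha - (alpha - 1) * r10 / r00`` places the protocol exactly on
    line (1): the mildest bottleneck under which the ``10`` population still
    survives, hence the fastest per-cycle exponent gain.  The value is clipped
    to (0, 1); ``clipped`` reports whether the unconstrained optimum fell
    outside the admissible range.
    """
    if not alpha > 1:
        raise ParameterError(f"optimal beta requires alpha > 1 (got alpha={alpha})")
    beta = alpha - (alpha - 1.0) * landscape.r10 / landscape.r00
    lo, hi = 1e-9, 1.0 - 1e-9
    if beta < lo:
        return OptimalBeta(lo, True)
    if beta > hi:
        return OptimalBeta(hi, True)
    return OptimalBeta(beta, False)


def recommended_dilution(alpha: float, landscape: FitnessLandscape, n: float) -> float:
    """Dilution factor ``n**(-(alpha-1)*r10/r00)`` at the optimal ``beta``.

    This is the dilution ``D_n = n**(beta - alpha)`` evaluated at
    ``beta = optimal_beta(alpha)``: the design that yields double mutants as
    fast as possible for a given final population size ``n**alpha``.
    """
    if not alpha > 1:
        raise ParameterError(f"recommended dilution requires alpha > 1 (got alpha={alpha})")
    if not n > 1:
        raise ParameterError(f"recommended dilution requires n > 1 (got n={n})")
    return n ** (-(alpha - 1.0) * landscape.r10 / landscape.r00)
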