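"""Parameters and derived demographic quantities.

The model describes an asexual population on a minimal four-genotype fitness
landscape (wild type ``00``, single mutants ``10`` and ``01``, double mutant
``11``) growing exponentially between periodic bottlenecks of fixed relative
severity.  All demographic quantities are expressed in exponents of a single
scaling parameter ``n`` (of the order of the inverse of the high mutation
rate): the wild type grows from ``N0 = n**beta`` to ``Nfin = n**alpha`` during
each cycle and is then diluted by ``D_n = n**(beta - alpha)``.

Mutation rates follow the empirically supported rate/benefit trade-off: the
weakly beneficial mutation (``00 -> 10`` and ``01 -> 11``) has the high rate
``mu_high = 1/n`` while the strongly beneficial one (``00 -> 01`` and
``10 -> 11``) has the low rate ``mu_low = 1/n**delta`` with ``delta > 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GENOTYPES",
    "MUTANT_GENOTYPES",
    "TRANSITIONS",
    "ORIGINS",
    "ParameterError",
    "FitnessLandscape",
    "DemographyParams",
    "Genotype",
    "BirthDeathRates",
    "DerivedDemography",
    "derive_demography",
    "rates_from_net",
]

#: Genotype labels, ordered by number of mutations.
GENOTYPES: tuple[str, ...] = ("00", "10", "01", "11")
MUTANT_GENOTYPES: tuple[str, ...] = ("10", "01", "11")

#: Allowed mutational transitions (no recombination, no back mutation).
TRANSITIONS: tuple[tuple[str, str], ...] = (
    ("00", "10"),
    ("00", "01"),
    ("10", "11"),
    ("01", "11"),
)

#: Parental backgrounds a double-mutant lineage can descend from.
ORIGINS: tuple[str, ...] = ("from10", "from01")


class ParameterError(ValueError):
    """A model parameter violates one of the stated inequalities."""


@dataclass(frozen=True)
class FitnessLandscape:
    """Net per-capita growth rates (1/time) of the four genotypes.

    Magnitude epistasis is allowed but sign epistasis is not, so the rates
    must satisfy the strict ordering ``r11 > r01 > r10 > r00 > 0``.
    """

    r00: float
    r10: float
    r01: float
    r11: float

    def __post_init__(self) -> None:
        if not self.r00 > 0:
            raise ParameterError(f"growth rates must be positive: r00={self.r00}")
        if not (self.r11 > self.r01 > self.r10 > self.r00):
            raise ParameterError(
                "growth rates must satisfy r11 > r01 > r10 > r00 "
                f"(got r11={self.r11}, r01={self.r01}, r10={self.r10}, r00={self.r00})"
            )

    def rate(self, genotype: str) -> float:
        """Net growth rate of ``genotype`` (one of ``'00'``..``'11'``)."""
        try:
            return {"00": self.r00, "10": self.r10, "01": self.r01, "11": self.r11}[genotype]
        except KeyError:
            raise ParameterError(f"unknown genotype label {genotype!r}") from None


@dataclass(frozen=True)
class DemographyParams:
    """Scaling parameter and demographic exponents.

    Parameters
    ----------
    n
        Dimensionless scaling parameter, of the order of the inverse of the
        high mutation rate; must exceed 1.
    beta
        Initial-size exponent: the cycle starts with ``N0 = n**beta`` wild-type
        individuals.  Constrained to ``0 < beta < 1`` so that no mutant is
        present at the start of the experiment.
    alpha
        Final-size exponent: growth stops at ``Nfin = n**alpha``; ``alpha > 1``
        guarantees the weakly beneficial mutation appears during every cycle.
    delta
        Rarity exponent of the strongly beneficial mutation
        (``mu_low = n**-delta``), with ``delta > 1``.
    """

    n: float
    beta: float
    alpha: float
    delta: float

    def __post_init__(self) -> None:
        if not self.n > 1:
            raise ParameterError(f"scaling parameter must satisfy n > 1 (got n={self.n})")
        if not 0 < self.beta < 1:
            raise ParameterError(f"initial-size exponent must satisfy 0 < beta < 1 (got beta={self.beta})")
        if not self.alpha > 1:
            raise ParameterError(f"final-size exponent must satisfy alpha > 1 (got alpha={self.alpha})")
        if not self.delta > 1:
            raise ParameterError(f"rarity exponent must satisfy delta > 1 (got delta={self.delta})")

    @property
    def mu_high(self) -> float:
        """Weakly beneficial mutation rate ``1/n``."""
        return 1.0 / self.n

    @property
    def mu_low(self) -> float:
        """Strongly beneficial mutation rate ``1/n**delta``."""
        return self.n ** (-self.delta)

    @property
    def mu(self) -> float:
        """Total beneficial mutation rate ``mu_high + mu_low``."""
        return self.mu_high + self.mu_low

    @property
    def N0(self) -> float:
        return self.n**self.beta

    @property
    def Nfin(self) -> float:
        return self.n**self.alpha

    @property
    def D_n(self) -> float:
        """Dilution factor ``n**(beta - alpha)``, in (0, 1)."""
        return self.n ** (self.beta - self.alpha)

    def t_n(self, r00: float) -> float:
        """Cycle duration ``(alpha - beta) * ln(n) / r00``."""
        if not r00 > 0:
            raise ParameterError(f"wild-type growth rate must be positive (got r00={r00})")
        return (self.alpha - self.beta) * math.log(self.n) / r00


@dataclass(frozen=True)
class Genotype:
    """A genotype label, with the parental background for double mutants."""

    label: str
    origin: str | None = None

    def __post_init__(self) -> None:
        if self.label not in GENOTYPES:
            raise ParameterError(f"unknown genotype label {self.label!r}")
        if self.label == "11":
            if self.origin not in ORIGINS:
                raise ParameterError(
                    f"double mutants must carry an origin in {ORIGINS} (got {self.origin!r})"
                )
        elif self.origin is not None:
            raise ParameterError(f"origin is only meaningful for genotype '11' (got {self.label!r})")


@dataclass(frozen=True)
class DerivedDemography:
    """Derived quantities of one serial-passage protocol."""

    N0: float
    Nfin: float
    t_n: float
    D_n: float
    mu_high: float
    mu_low: float


def derive_demography(params: DemographyParams, landscape: FitnessLandscape) -> DerivedDemography:
    """Derive initial/final sizes, cycle duration, dilution and mutation rates.

    The returned quantities satisfy ``N0 * exp(r00 * t_n) == Nfin`` and
    ``Nfin * D_n == N0`` (the bottleneck exactly undoes the wild-type growth).
    """
    return DerivedDemography(
        N0=params.N0,
        Nfin=params.Nfin,
        t_n=params.t_n(landscape.r00),
        D_n=params.D_n,
        mu_high=params.mu_high,
        mu_low=params.mu_low,
    )


@dataclass(frozen=True)
class BirthDeathRates:
    """Per-genotype intrinsic birth and death rates.

    The net rate ``birth[g] - death[g]`` equals the landscape growth rate of
    genotype ``g``; the intrinsic death rate is shared by all genotypes.
    """

    birth: dict[str, float]
    death: dict[str, float]

    def __post_init__(self) -> None:
        for g in GENOTYPES:
            if g not in self.birth or g not in self.death:
                raise ParameterError(f"rates missing for genotype {g!r}")
            if self.death[g] < 0:
                raise ParameterError(f"death rate must be non-negative (genotype {g!r})")


def rates_from_net(landscape: FitnessLandscape, death_rate: float = 0.0) -> BirthDeathRates:
    """Decompose net growth rates into birth/death with a common death rate."""
    if death_rate < 0:
        raise ParameterError(f"death rate must be non-negative (got {death_rate})")
    birth = {g: landscape.rate(g) + death_rate for g in GENOTYPES}
    death = {g: death_rate for g in GENOTYPES}
    return BirthDeathRates(birth=birth, death=death)
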