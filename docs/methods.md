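# Methods

## Model and assumptions

`bottlepath` studies an asexual population on a four-genotype landscape
(`00`, `10`, `01`, `11`) under serial passaging with bottlenecks of fixed
relative severity. The analytic layer works entirely in exponents of the
scaling parameter `n`: the wild type grows deterministically from `n^β` to
`n^α` per cycle and mutant subpopulations are supercritical birth–death
processes seeded by inhomogeneous Poisson founding with per-capita rates
`μ_high = 1/n` (weak benefit) and `μ_low = n^−δ` (strong benefit). The
central asymptotic statements — which genotypes establish each cycle, which
survive the bottlenecks, and at which cycle the double mutant establishes —
hold with probability tending to 1 as `n → ∞`. Key structural assumptions:
no sign epistasis (`r11 > r01 > r10 > r00 > 0`), no recombination, no
back-mutation, unlimited exponential growth between dilutions (relaxed only
in the density-dependent simulator), and a wild type large enough to be
deterministic while never being depleted by mutation outflow (the standard
Luria–Delbrück approximation; the relative error is O(μ)).

## Threshold lines and their validation

Lines (1)–(3) are closed-form consequences of comparing a mutant's
end-of-cycle exponent with the dilution exponent `α − β` (survival) or the
final wild-type exponent with the inverse mutation-rate exponent
(establishment). The first-cycle double-mutant lines are derived here from
the same exponent book-keeping: the `01` population ends cycle 1 at exponent
`(α−δ)·r01/r00`, so double mutants (rate `1/n`) appear once that reaches 1,
giving line (4) `α = δ + r00/r01`; symmetrically line (5)
`α = 1 + δ·r00/r10`. For later cycles a surviving parent gains
`(α−β)(r_parent − r00)/r00` exponents per cycle (its growth factor times the
dilution), which yields the establishment-cycle recursion and, by
optimizing the per-cycle gain subject to survival, the optimal initial-size
exponent `β* = α − (α−1)·r10/r00` on line (1).

Because these expressions involve more than a direct transcription of the
survival argument, the package carries an independent numerical oracle
(`bottlepath.oracle`): a deterministic integration of the *typical* mutant
flux cascade at finite `n`, in which a genotype's size is held at zero until
its integrated founding flux within a cycle reaches one founder (discarding
the rare jackpot founders that dominate the mean but not the typical
trajectory), grows as `dZ/dt = rZ + flux` afterwards, and survives a
bottleneck when `Z·D_n ≥ 1`. Bisection on α locates where the oracle's
verdict flips; the flip points converge to the analytic lines as `n` grows
through 10^6–10^10 with a gap shrinking like `1/ln n`, which is exactly the
size of the subpolynomial factors the exponent-level theory ignores. The
same machinery validates the establishment-cycle recursion in the pure
`10`-route zone (α < δ at high β).

Boundary tie-break: points exactly on a line are classified as lying above
it. The boundaries have measure zero and the asymptotic theory is silent
there; a fixed convention keeps classification deterministic.

## Exponential-growth simulator

Individual-based simulation is impossible at `n^α` individuals, so the
engine is hybrid, built from exact components wherever a closed form exists:

* **Founding.** Within each time step, founding events from the wild type
  are sampled exactly (Poisson count with the closed-form integrated
  intensity; times by inversion) while their expected number per step is
  below `founder_cap` (64). These early founders carry the Luria–Delbrück
  jackpot statistics. Later founders are aggregated into a deterministic
  mass equal to their expected descendant contribution; with ≥ 64 founders
  per step the relative fluctuation of that cohort is a few percent.
* **Lineage dynamics.** Stochastic lineages evolve by the exact linear
  birth–death transition law over each step (binomial number of surviving
  founder lines, geometric family sizes) rather than event-by-event
  simulation, making the cost independent of lineage size. A lineage
  reaching the hybrid cutoff (10^4 individuals) becomes deterministic; its
  survival is no longer in doubt at that size.
* **Mutation output.** Double-mutant founders are emitted as Poisson counts
  on the trapezoid-integrated parent size per step (per-step growth ≤ e^0.35,
  keeping the quadrature bias at the percent level), tagged by parental
  origin.
* **Bottleneck.** Stochastic lineages are thinned binomially with retention
  `D_n`; deterministic masses are rescaled, and re-enter the stochastic pool
  by binomial resampling when the diluted value falls below 10× the cutoff,
  so borderline bottleneck survival — the central stochastic effect —
  is never truncated.

Default birth/death split is pure birth (death 0) for the exponential model;
any common death rate can be supplied, and the reference parameter set uses
0.1.

**Establishment threshold.** The asymptotic notion "present in
non-negligible quantity" needs a finite-`n` surrogate. The default declares
a genotype established when its end-of-cycle total reaches 20 individuals:
the scale at which a supercritical lineage has escaped drift extinction
(P(extinction) ≈ (d/b)^20 is negligible for the reference rates), while
remaining far below any population scale that depends on `n`. Thresholds
tied to `n` (for example a fixed fraction of the final wild-type size)
misbehave across the range of `n` used here: they can exceed the typical
established-mutant size `n^((α−1)r10/r00)` for small α and thus contradict
the asymptotic statements they are meant to approximate. The threshold is a
parameter (`establish_threshold`, plus an optional wild-type fraction);
doubling or halving it moves the observed establishment boundaries by
`± log_n(2)/slope ≈ 0.02–0.05` in α at `n = 10^6` and has no effect on the
analytic layer. Survival of a bottleneck additionally requires having been
established in that cycle, so sub-threshold stragglers do not count.

## Density-dependent simulator

Division and death rates are both multiplied by `max(0, 1 − Ntot/K)` where
`Ntot` is the total population and `K` the genotype's capacity class
(`K_wt = n^α`; mutants share `K_mut = n^α(1+s)`, the double mutant's class
is configurable and defaults to the mutant class). Clamping at zero means
saturated populations are static within a cycle and decline only through
dilutions. Two protocol choices were genuinely open:

* **Dilution trigger.** Triggering on the *wild type* reaching `p·K_wt`
  deadlocks whenever a mutant saturates the medium first (the wild type's
  modulation factor turns negative-to-clamped and it can never reach the
  trigger) — and mutant takeover is precisely the clonal-interference regime
  this simulator exists to produce. The protocol therefore dilutes when the
  *total* population reaches `p·K_wt`, with the constant factor
  `D = N0/(p·K_wt)`. While the wild type dominates, this is identical to
  resetting it to `N0`; afterwards it remains a well-defined constant-
  severity serial-transfer protocol and outcompeted genotypes wash out. A
  max-time guard converts genuinely unreachable triggers (for example `p = 1`
  with a mutation-free culture) into a documented error.
* **Mutation supply.** Founding fluxes are scaled by the parent's division
  factor: mutations arise at replication, so a saturated (non-dividing)
  parent stops producing mutants. The alternative (per-capita rates
  independent of division) would create mutants in a static culture.

Integration freezes the modulation factors over adaptive steps chosen so
that the total population moves by at most 2% of `K_wt` per step (and at
most `e^0.35` in relative growth), then reuses the exact frozen-rate
birth–death transitions. Cycle durations are emergent and recorded.

## Observed-scenario classification

A simulated run is mapped to the canonical configurations by its aggregated
establishment/survival flags: a transition is realized when it carried a
founding event and the target genotype established; a genotype survives when
it established, passed at least one bottleneck and is non-extinct at the end
of the run. Two escape hatches keep the mapping honest: runs with no
established mutant are labelled `none`, and patterns outside the six
canonical configurations are `unclassified` with explanatory flags. One
deliberate refinement: when the double mutant survives but no parent is
alive at the end — the end state of a completed sweep, where the double
mutant displaces its own parent under density dependence — the run is
labelled by its realized route (which parent established, fed the double
mutant and passed a bottleneck before being displaced), since that is the
scenario the run actually followed.

## Synthetic study conditions and what the tests show

There is no external data; the generators *are* the study system. The
reference parameter set (δ = 1.3, r00 = 0.2, r10 = 0.35, r01 = 0.9,
r11 = 1, death 0.1, p = 0.5, s = 0.1, seven cycles) is the one for which the
six-configuration diagram exists. Sweeps run at `n = 10^6` on a 20×20 grid
with five replicates per cell and a boundary margin of 0.05 in α — sizes
chosen so a full comparison completes in minutes on one CPU; the reference
setting (`n = 10^12`, thousands of grid points) runs unchanged, only slower,
because engine cost scales with `ln n`, not `n`. Two caveats on
interpretation: at `n = 10^6` the `O(1/ln n)` drift of the effective
boundaries is substantial (the observed survival lines sit 0.2–0.3 α-units
below the asymptotic ones, and rare strong mutants establish below
`α = δ`), so theory/simulation agreement is evaluated away from boundaries
and is expected near, not at, 100%; and the generators emulate an idealized
protocol — perfectly timed dilutions, exact parameter control, exactly two
mutation classes — so passing tests validate the mathematics and the
engines, not the fit of the minimal landscape to any particular organism.

## Numerical choices and limitations

Sizes are raw float64 with deterministic masses capped at 10^250 (far beyond
any threshold that matters; prevents overflow across repeated growth);
the oracle integrates stepwise so no intermediate `e^{rt}` factor is formed
alone, and refuses protocols with `r01·t_n > 690`. Extinct lineages are
pruned; empty pools short-circuit. All randomness flows from one seeded
generator per run; sweeps derive independent per-cell/replicate streams from
`SeedSequence(seed, spawn_key=(cell, rep))`, so tables are bit-reproducible.
Known limitations: no more than two mutation classes or four genotypes, no
recombination, no spatial or within-host structure, no chemostat-style
resource dynamics, no inference from experimental data, and establishment
probabilities are handled at exponent level (no `1 − d/b` corrections in the
analytic layer).
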