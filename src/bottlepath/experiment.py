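"""Theory-versus-simulation comparisons over grids of demographic exponents.

Builds the predicted phase diagram (path-configuration label and double-mutant
establishment cycle for every ``(beta, alpha)`` cell), runs either simulator
over the same grid with replicated, reproducibly seeded runs, and summarizes
how often the observed scenario matches the prediction away from the phase
boundaries, where finite-``n`` stochasticity blurs the asymptotic lines.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pandas as pd

from .core import DemographyParams, FitnessLandscape, ParameterError
from .density import DensityParams, run_density_cycles
from .simulate import classify_observed, run_cycles
from .theory import (
    classify,
    corner,
    line1_alpha,
    line2_alpha,
    line3_alpha,
    line4_alpha,
    line5_alpha,
    predict_establishment_cycle,
)

__all__ = [
    "boundary_distance",
    "build_theory_diagram",
    "run_sweep",
    "agreement_summary",
    "plot_phase_diagram",
]


def boundary_distance(
    beta: float, alpha: float, landscape: FitnessLandscape, delta: float
) -> float:
    """Distance (in ``alpha`` units) from the nearest threshold line (1)-(5)."""
    lines = (
        line1_alpha(beta, landscape),
        line2_alpha(delta),
        line3_alpha(beta, landscape, delta),
        line4_alpha(landscape, delta),
        line5_alpha(landscape, delta),
    )
    return min(abs(alpha - line) for line in lines)


def build_theory_diagram(
    beta_grid,
    alpha_grid,
    landscape: FitnessLandscape,
    delta: float,
    max_cycles: int | None = None,
) -> pd.DataFrame:
    """Predicted configuration for every cell of a ``(beta, alpha)`` grid.

    Pure function of its inputs: rebuilding the table is bit-identical.
    """
    rows = []
    for beta in np.asarray(beta_grid, dtype=float):
        for alpha in np.asarray(alpha_grid, dtype=float):
            forecast = predict_establishment_cycle(beta, alpha, landscape, delta, max_cycles)
            rows.append(
                {
                    "beta": beta,
                    "alpha": alpha,
                    "corner": corner(beta, alpha, landscape, delta),
                    "label": forecast.config.label,
                    "k11": forecast.k11,
                    "route": forecast.route if forecast.route is not None else "",
                    "boundary_distance": boundary_distance(beta, alpha, landscape, delta),
                    "log_n_dilution": beta - alpha,
                }
            )
    return pd.DataFrame(rows)


def _observed_k11(records) -> float:
    for rec in records:
        if rec.established["11"]:
            return float(rec.cycle)
    return math.inf


def run_sweep(
    beta_grid,
    alpha_grid,
    landscape: FitnessLandscape,
    delta: float,
    n: float,
    simulator: str = "exponential",
    reps: int = 5,
    n_cycles: int = 7,
    seed: int = 0,
    death_rate: float = 0.0,
    density: DensityParams | None = None,
    establish_threshold: float | None = None,
    rates=None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run one simulator over a grid and tag every replicate with its labels.

    Per-replicate randomness comes from ``SeedSequence(seed, spawn_key=(cell,
    rep))``: reruns with the same seed are identical and cells are mutually
    independent.  ``simulator`` is ``"exponential"`` (pure exponential growth;
    ``death_rate`` selects the birth/death split) or ``"density"`` (requires
    ``density`` parameters, which carry their own death rate).
    """
    from .core import rates_from_net

    if simulator not in ("exponential", "density"):
        raise ParameterError(f"unknown simulator {simulator!r}")
    if simulator == "density" and density is None:
        density = DensityParams()
    betas = np.asarray(beta_grid, dtype=float)
    alphas = np.asarray(alpha_grid, dtype=float)
    kwargs = {}
    if establish_threshold is not None:
        kwargs["establish_threshold"] = establish_threshold
    if rates is None and simulator == "exponential":
        rates = rates_from_net(landscape, death_rate)

    rows = []
    cells = [(b, a) for b in betas for a in alphas]
    iterator = enumerate(cells)
    if progress:
        from tqdm import tqdm

        iterator = enumerate(tqdm(cells, desc=f"{simulator} sweep"))
    for idx, (beta, alpha) in iterator:
        params = DemographyParams(n=n, beta=beta, alpha=alpha, delta=delta)
        forecast = predict_establishment_cycle(beta, alpha, landscape, delta, max_cycles=n_cycles)
        predicted = forecast.config.label
        dist = boundary_distance(beta, alpha, landscape, delta)
        for rep in range(reps):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(idx, rep))
            )
            if simulator == "exponential":
                records, _ = run_cycles(
                    params, landscape, rates=rates, n_cycles=n_cycles, rng=rng, **kwargs
                )
            else:
                records, _ = run_density_cycles(
                    params, landscape, density, n_cycles=n_cycles, rng=rng, **kwargs
                )
            observed = classify_observed(records)
            rows.append(
                {
                    "beta": beta,
                    "alpha": alpha,
                    "rep": rep,
                    "observed_label": observed.label,
                    "predicted_label": predicted,
                    "k11_observed": _observed_k11(records),
                    "k11_predicted": forecast.k11,
                    "agree": observed.label == predicted,
                    "boundary_distance": dist,
                }
            )
    return pd.DataFrame(rows)


def agreement_summary(cells: pd.DataFrame, margin: float = 0.05) -> dict:
    """Prediction/observation agreement away from the threshold lines.

    Restricted to cells with ``boundary_distance >= margin``; a cell agrees
    when the *modal* observed label across its replicates equals the
    prediction.  Returns the overall agreement, per-predicted-label
    agreement, and the most common systematic disagreements.
    """
    if margin < 0:
        raise ParameterError(f"margin must be non-negative (got {margin})")
    interior = cells[cells["boundary_distance"] >= margin]
    if interior.empty:
        raise ParameterError(
            f"no cells left at margin {margin}; largest boundary distance is "
            f"{cells['boundary_distance'].max():.3g}"
        )

    modal_rows = []
    for (beta, alpha), group in interior.groupby(["beta", "alpha"], sort=True):
        modal = Counter(group["observed_label"]).most_common(1)[0][0]
        predicted = group["predicted_label"].iloc[0]
        modal_rows.append(
            {"beta": beta, "alpha": alpha, "predicted": predicted, "modal_observed": modal}
        )
    modal_df = pd.DataFrame(modal_rows)
    modal_df["agree"] = modal_df["predicted"] == modal_df["modal_observed"]

    per_label = {}
    for label, group in modal_df.groupby("predicted"):
        per_label[label] = {
            "n_cells": int(len(group)),
            "agreement": float(group["agree"].mean()),
        }
    mismatches = modal_df[~modal_df["agree"]]
    confusion = Counter(zip(mismatches["predicted"], mismatches["modal_observed"]))
    systematic = [
        {"predicted": pred, "observed": obs, "n_cells": count}
        for (pred, obs), count in confusion.most_common()
    ]
    return {
        "margin": margin,
        "n_cells": int(len(modal_df)),
        "overall_agreement": float(modal_df["agree"].mean()),
        "per_label": per_label,
        "systematic_disagreements": systematic,
    }


def plot_phase_diagram(
    theory_cells: pd.DataFrame,
    path,
    observed_cells: pd.DataFrame | None = None,
) -> None:
    """Render the predicted regions (background) and observed labels (points)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    palette = {
        "only10": "#9467bd",
        "10and01_no_survival": "#2ca02c",
        "10survives_11from10": "#1f77b4",
        "10survives_01establishes": "#ffdd44",
        "01survives_11from01": "#ff7f0e",
        "all_survive": "#d62728",
        "none": "#bbbbbb",
        "unclassified": "#444444",
    }
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(
        theory_cells["beta"],
        theory_cells["alpha"],
        c=[palette.get(l, "#444444") for l in theory_cells["label"]],
        marker="s",
        s=36,
        alpha=0.45,
        linewidths=0,
    )
    if observed_cells is not None:
        modal = (
            observed_cells.groupby(["beta", "alpha"])["observed_label"]
            .agg(lambda s: Counter(s).most_common(1)[0][0])
            .reset_index()
        )
        ax.scatter(
            modal["beta"],
            modal["alpha"],
            c=[palette.get(l, "#444444") for l in modal["observed_label"]],
            marker="o",
            s=12,
            edgecolors="black",
            linewidths=0.3,
        )
    ax.set_xlabel(r"initial-size exponent $\beta$")
    ax.set_ylabel(r"final-size exponent $\alpha$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
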