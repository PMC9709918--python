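"""Boltzmann weighting of conformer ensembles and statistical-relevance summaries.

A conformer's equilibrium population at temperature T is
``w_i = exp(-dE_i / RT) / sum_j exp(-dE_j / RT)`` with relative energies in
kcal/mol and R = 1.987204e-3 kcal/(mol K). The summaries answer the practical
question "how many of the generated conformers actually matter": the fraction
of conformers needed to cover 99% of the population, the cumulative population
curve, and the population mass per 5%-of-conformers interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAS_CONSTANT_KCAL",
    "ThermoParams",
    "BoltzmannSummary",
    "boltzmann_weights",
    "coverage_fraction",
    "population_bins",
    "summarize_population",
]

#: Molar gas constant in kcal/(mol K).
GAS_CONSTANT_KCAL = 1.987204e-3


@dataclass
class ThermoParams:
    """Temperature (K) and gas constant (kcal/(mol K)) for Boltzmann weighting."""

    temperature: float = 298.0
    gas_constant: float = GAS_CONSTANT_KCAL

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature


@dataclass
class BoltzmannSummary:
    """Population summary of one ensemble.

    ``weights`` are in the input (conformer) order; ``cumulative`` are the
    partial sums of the weights sorted descending; ``coverage_fraction_99`` is
    the fraction of conformers needed to reach 99% cumulative population;
    ``bins_5pct`` is the population mass per 5% conformer-rank interval.
    """

    weights: np.ndarray
    cumulative: np.ndarray
    coverage_fraction_99: float
    bins_5pct: np.ndarray = field(default_factory=lambda: np.array([]))


def boltzmann_weights(rel_e: np.ndarray, thermo: ThermoParams | None = None) -> np.ndarray:
    """Boltzmann weights of relative energies (kcal/mol, minimum 0).

    Energies are shifted by their minimum before exponentiation, so the result
    is invariant under any additive shift of the absolute scale and stable for
    large energy spreads.
    """
    thermo = thermo or ThermoParams()
    rel_e = np.asarray(rel_e, dtype=float)
    if rel_e.size == 0:
        raise ValueError("empty energy vector")
    if not np.all(np.isfinite(rel_e)):
        raise ValueError("non-finite energies")
    x = -(rel_e - rel_e.min()) / thermo.rt
    w = np.exp(x)
    return w / w.sum()


def _descending_order(weights: np.ndarray) -> np.ndarray:
    # stable sort on -w: ties broken by the lower conformer index
    return np.argsort(-weights, kind="stable")


def coverage_fraction(weights: np.ndarray, q: float = 0.99) -> float:
    """Fraction of conformers (sorted by population) needed to cover quantile ``q``.

    Returns m/n where m is the smallest count whose cumulative population is
    >= q. A small value means a few conformers carry essentially the whole
    equilibrium population.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    w = np.asarray(weights, dtype=float)
    cum = np.cumsum(w[_descending_order(w)])
    m = int(np.searchsorted(cum, q - 1e-12) + 1)
    m = min(m, w.size)
    return m / w.size


def population_bins(weights: np.ndarray, bin_width: float = 0.05) -> np.ndarray:
    """Population mass per conformer-rank percentile interval.

    Conformers are ranked descending by weight; bin k collects the weight of
    conformers whose rank percentile falls in ``((k-1)*bin_width, k*bin_width]``.
    Bins sum to 1. With the default width there are 20 bins.
    """
    w = np.asarray(weights, dtype=float)
    n = w.size
    n_bins = int(np.ceil(1.0 / bin_width - 1e-9))
    out = np.zeros(n_bins)
    sorted_w = w[_descending_order(w)]
    for rank, wi in enumerate(sorted_w, start=1):
        pct = rank / n
        k = int(np.ceil(pct / bin_width - 1e-9)) - 1
        out[min(k, n_bins - 1)] += wi
    return out


def summarize_population(
    rel_e: np.ndarray, thermo: ThermoParams | None = None, q: float = 0.99
) -> BoltzmannSummary:
    """Weights, cumulative curve, 99%-coverage fraction, and 5% bins in one call."""
    w = boltzmann_weights(rel_e, thermo)
    cum = np.cumsum(w[_descending_order(w)])
    return BoltzmannSummary(
        weights=w,
        cumulative=cum,
        coverage_fraction_99=coverage_fraction(w, q),
        bins_5pct=population_bins(w),
    )
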