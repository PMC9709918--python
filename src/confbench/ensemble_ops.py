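"""Ensemble filtration: energy windows, RMSD deduplication, diversity picking.

These mirror the post-search filters conformational-search programs apply
before any comparison: an energy window about the global minimum, greedy
RMSD-based duplicate removal (optionally gated by a pair-energy threshold, the
convention metadynamics-based searchers use), and maximally diverse subset
selection for expensive follow-up calculations. All thresholds are inclusive.
"""

from __future__ import annotations

import numpy as np

from .io_conformers import Ensemble, RepresentativeSelection
from .geometry import subset_rmsd

__all__ = [
    "relative_energies",
    "energy_window_filter",
    "rmsd_dedupe",
    "diversity_subset",
    "suggested_conformer_count",
]


def relative_energies(ensemble: Ensemble) -> np.ndarray:
    """Energies shifted so the global minimum is exactly 0 (kcal/mol)."""
    e = ensemble.energies
    return e - e.min()


def energy_window_filter(ensemble: Ensemble, cutoff: float) -> Ensemble:
    """Keep conformers with relative energy <= ``cutoff`` kcal/mol (inclusive).

    Order is preserved and the global minimum always survives. Typical cutoffs
    are 10 kcal/mol for unconstrained and 20 kcal/mol for constrained searches.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rel = relative_energies(ensemble)
    keep = [i for i in range(len(ensemble)) if rel[i] <= cutoff]
    return ensemble.subset(keep)


def rmsd_dedupe(
    ensemble: Ensemble,
    rmsd_threshold: float,
    sel: RepresentativeSelection,
    energy_threshold: float | None = None,
) -> Ensemble:
    """Greedy duplicate removal in ascending energy order.

    Conformers are visited from lowest to highest energy; one is dropped when
    it lies within ``rmsd_threshold`` (subset RMSD, inclusive) of an
    already-kept conformer — and, when ``energy_threshold`` is given, only if
    it is also within that energy of the same kept conformer (both gates must
    fire, mirroring pair-threshold merging). The lowest-energy conformer is
    always kept, and with no energy gate every dropped conformer is within
    ``rmsd_threshold`` of some kept one.
    """
    if rmsd_threshold <= 0:
        raise ValueError("rmsd_threshold must be positive")
    if energy_threshold is not None and energy_threshold <= 0:
        raise ValueError("energy_threshold must be positive")
    energies = ensemble.energies
    order = sorted(range(len(ensemble)), key=lambda i: (energies[i], i))
    kept: list[int] = []
    for i in order:
        duplicate = False
        for j in kept:
            if subset_rmsd(ensemble[i], ensemble[j], sel) <= rmsd_threshold:
                if energy_threshold is None or abs(energies[i] - energies[j]) <= energy_threshold:
                    duplicate = True
                    break
        if not duplicate:
            kept.append(i)
    return ensemble.subset(kept)


def diversity_subset(ensemble: Ensemble, k: int, sel: RepresentativeSelection) -> Ensemble:
    """Max-min greedy selection of ``k`` mutually diverse conformers.

    Seeds with the lowest-energy conformer, then repeatedly adds the conformer
    whose minimum subset-RMSD distance to the current selection is largest
    (ties broken by the lower index). Deterministic; used to pick the handful
    of structures worth re-optimizing at a higher level of theory.
    """
    n = len(ensemble)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    energies = ensemble.energies
    seed = min(range(n), key=lambda i: (energies[i], i))
    chosen = [seed]
    if k > 1:
        min_dist = np.array(
            [subset_rmsd(ensemble[i], ensemble[seed], sel) for i in range(n)]
        )
        min_dist[seed] = -np.inf
        while len(chosen) < k:
            nxt = int(np.argmax(min_dist))  # argmax takes the first (lowest index) tie
            chosen.append(nxt)
            dists = np.array(
                [subset_rmsd(ensemble[i], ensemble[nxt], sel) for i in range(n)]
            )
            min_dist = np.minimum(min_dist, dists)
            min_dist[nxt] = -np.inf
    return ensemble.subset(chosen)


def suggested_conformer_count(n_rotatable: int) -> int:
    """Requested conformer count as the cube of the rotatable-bond count."""
    if n_rotatable < 1:
        raise ValueError("need at least one rotatable bond")
    return int(n_rotatable) ** 3
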