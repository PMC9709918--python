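"""The five 0-10 benchmark criteria and the per-method grade report.

A conformational-search method is graded on five axes:

* **prediction capacity** — on how many catalysts its most stable conformer
  coincides (within an RMSD threshold on representative atoms) with the
  reference method's most stable conformer: ``10 * n_correct / N``.
* **tunability** — how many of the seven benchmark features (conformer
  optimization method, conformer generation method, cutoff modifications,
  molecule charge, molecular constraints, solvent selection, temperature
  selection) the program lets the user modify: ``10 * n_features / 7``.
* **space exploration** — the mean over catalysts of the method's cluster
  participation fraction, times 10.
* **structural accuracy** — a linear map of the RMSD to the reference-optimized
  structure: 10 at RMSD 0, 0 at the calibration maximum 4.70 Å, clipped below.
* **energy accuracy** — the same linear map on the RMSD between relative-energy
  vectors, calibrated to 17.31 kcal/mol.

The two calibration maxima are the largest values observed across the original
benchmark's structure (12063 comparisons) and energy (120 comparisons)
calculations; grades for larger errors clip at 0. Energies are compared as
RELATIVE energies (each ensemble shifted to its own minimum) because force
field, semiempirical and DFT absolute scales are incommensurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_conformers import Ensemble, RepresentativeSelection, StudyRegistry
from .geometry import subset_rmsd

__all__ = [
    "GradingConstants",
    "AccuracyResult",
    "GradeReport",
    "grade_prediction_capacity",
    "grade_tunability",
    "grade_exploration",
    "structure_rmsd_grade",
    "energy_rmsd",
    "energy_rmsd_grade",
    "most_stable_agrees",
    "compile_report",
]

#: The seven tunable features evaluated by the tunability criterion.
FEATURE_LIST = (
    "conformer optimization method",
    "conformer generation method",
    "cutoff modifications",
    "molecule charge",
    "molecular constraints",
    "solvent selection",
    "temperature selection",
)


@dataclass
class GradingConstants:
    """Calibration anchors of the linear grade maps."""

    grade_scale: float = 10.0
    rmsd_max: float = 4.70  # Å; worst observed structural RMSD
    energy_rmsd_max: float = 17.31  # kcal/mol; worst observed energy RMSD
    n_feature_total: int = 7
    feature_list: tuple[str, ...] = FEATURE_LIST

    def __post_init__(self) -> None:
        if min(self.grade_scale, self.rmsd_max, self.energy_rmsd_max) <= 0:
            raise ValueError("calibration constants must be positive")
        if len(self.feature_list) != self.n_feature_total:
            raise ValueError("feature_list length must equal n_feature_total")


@dataclass
class AccuracyResult:
    """Accuracy measurements for one (method, catalyst) pair.

    ``structure_rmsds`` holds one subset RMSD per compared conformer (method
    geometry vs its reference-optimized counterpart); the two energy vectors
    are paired by conformer identity and each relative to its own minimum.
    """

    method_label: str
    catalyst_id: str
    structure_rmsds: np.ndarray
    rel_energies_method: np.ndarray
    rel_energies_ref: np.ndarray


@dataclass
class GradeReport:
    """Per-method grades plus the inputs they were computed from."""

    table: pd.DataFrame  # index: method; columns: the five grades + provenance
    constants: GradingConstants = field(default_factory=GradingConstants)

    GRADE_COLUMNS = ("prediction", "tunability", "exploration", "structure", "energy")

    def __post_init__(self) -> None:
        g = self.table[list(self.GRADE_COLUMNS)].to_numpy(dtype=float)
        if np.any(g < -1e-9) or np.any(g > self.constants.grade_scale + 1e-9):
            raise ValueError("grades out of [0, grade_scale]")


def _clip_grade(x: float, scale: float) -> float:
    return float(min(max(x, 0.0), scale))


def grade_prediction_capacity(
    n_correct: int, n_catalysts: int, constants: GradingConstants | None = None
) -> float:
    """``grade_scale * n_correct / N`` — most-stable-conformer agreement rate."""
    constants = constants or GradingConstants()
    if n_catalysts < 1:
        raise ValueError("need at least one catalyst")
    if not 0 <= n_correct <= n_catalysts:
        raise ValueError(f"n_correct={n_correct} out of [0, {n_catalysts}]")
    return constants.grade_scale * n_correct / n_catalysts


def grade_tunability(n_features: int, constants: GradingConstants | None = None) -> float:
    """``grade_scale * n_features / n_feature_total`` (integer feature counts only)."""
    constants = constants or GradingConstants()
    if not float(n_features).is_integer():
        raise ValueError("n_features must be an integer feature count")
    n_features = int(n_features)
    if not 0 <= n_features <= constants.n_feature_total:
        raise ValueError(
            f"n_features={n_features} out of [0, {constants.n_feature_total}]"
        )
    return constants.grade_scale * n_features / constants.n_feature_total


def grade_exploration(
    participation: Sequence[float], constants: GradingConstants | None = None
) -> float:
    """``grade_scale * mean(per-catalyst participation fractions)``."""
    constants = constants or GradingConstants()
    p = np.asarray(list(participation), dtype=float)
    if p.size == 0:
        raise ValueError("no participation fractions given")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("participation fractions must lie in [0, 1]")
    return constants.grade_scale * float(p.mean())


def structure_rmsd_grade(rmsd: float, constants: GradingConstants | None = None) -> float:
    """Linear structural grade: 10 at RMSD 0, 0 at ``rmsd_max``, clipped below."""
    constants = constants or GradingConstants()
    if rmsd < 0:
        raise ValueError("rmsd must be non-negative")
    return _clip_grade(
        constants.grade_scale * (1.0 - rmsd / constants.rmsd_max), constants.grade_scale
    )


def energy_rmsd(rel_method: np.ndarray, rel_ref: np.ndarray) -> float:
    """RMS deviation between two relative-energy vectors paired by conformer.

    Both vectors must already be relative to their own minimum; the pairing is
    by conformer identity (position), not by energy rank.
    """
    a = np.asarray(rel_method, dtype=float)
    b = np.asarray(rel_ref, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"energy vectors differ in length: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty energy vectors")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def energy_rmsd_grade(e: float, constants: GradingConstants | None = None) -> float:
    """Linear energy grade: 10 at 0, 0 at ``energy_rmsd_max``, clipped below."""
    constants = constants or GradingConstants()
    if e < 0:
        raise ValueError("energy RMSD must be non-negative")
    return _clip_grade(
        constants.grade_scale * (1.0 - e / constants.energy_rmsd_max),
        constants.grade_scale,
    )


def most_stable_agrees(
    ens: Ensemble,
    ref: Ensemble,
    sel: RepresentativeSelection,
    match_threshold: float = 0.5,
) -> bool:
    """Whether the two ensembles' lowest-energy conformers are the same structure.

    Agreement means subset RMSD (representative atoms) <= ``match_threshold``
    (default 0.5 Å, the usual duplicate-detection cutoff).
    """
    a = ens.lowest_energy_conformer()
    b = ref.lowest_energy_conformer()
    return subset_rmsd(a, b, sel) <= match_threshold


def compile_report(
    registry: StudyRegistry,
    participations: Mapping[str, Mapping[str, float]],
    accuracy: Sequence[AccuracyResult],
    tunability_counts: Mapping[str, int],
    constants: GradingConstants | None = None,
    match_threshold: float = 0.5,
    constrained: bool = False,
) -> GradeReport:
    """Assemble the five grades for every non-reference method.

    Parameters
    ----------
    participations
        ``{method: {catalyst: participation fraction}}`` from the clustering
        stage.
    accuracy
        One :class:`AccuracyResult` per (method, catalyst) accuracy comparison.
        The structural grade of a method is the mean of the per-conformer
        structure grades; the energy grade is the mean over catalysts of the
        grade of each catalyst's energy RMSD.
    tunability_counts
        ``{method: n_features}`` — declared per software, not computed.
    """
    constants = constants or GradingConstants()
    registry.validate()
    methods = [m for m in registry.methods if m != registry.reference_method]
    catalysts = registry.catalysts
    n_cat = len(catalysts)

    acc_by_method: dict[str, list[AccuracyResult]] = {m: [] for m in methods}
    for res in accuracy:
        if res.method_label in acc_by_method:
            acc_by_method[res.method_label].append(res)

    rows = []
    for m in methods:
        if m not in tunability_counts:
            raise ValueError(f"missing tunability count for method {m!r}")
        if m not in participations:
            raise ValueError(f"missing participation fractions for method {m!r}")
        if not acc_by_method[m]:
            raise ValueError(f"missing accuracy results for method {m!r}")

        n_correct = 0
        for cat in catalysts:
            ens = registry.get(cat, m, constrained)
            ref = registry.get(cat, registry.reference_method, constrained)
            if most_stable_agrees(ens, ref, registry.selection_for(cat), match_threshold):
                n_correct += 1

        frac = [participations[m][cat] for cat in catalysts if cat in participations[m]]
        struct_grades = [
            structure_rmsd_grade(r, constants)
            for res in acc_by_method[m]
            for r in np.atleast_1d(res.structure_rmsds)
        ]
        energy_grades = [
            energy_rmsd_grade(
                energy_rmsd(res.rel_energies_method, res.rel_energies_ref), constants
            )
            for res in acc_by_method[m]
        ]
        rows.append(
            {
                "method": m,
                "prediction": grade_prediction_capacity(n_correct, n_cat, constants),
                "tunability": grade_tunability(tunability_counts[m], constants),
                "exploration": grade_exploration(frac, constants),
                "structure": float(np.mean(struct_grades)),
                "energy": float(np.mean(energy_grades)),
                "n_correct": n_correct,
                "n_catalysts": n_cat,
                "n_features": int(tunability_counts[m]),
            }
        )
    table = pd.DataFrame(rows).set_index("method")
    return GradeReport(table=table, constants=constants)
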