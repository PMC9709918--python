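"""Ground-truthed synthetic conformer studies.

A synthetic "catalyst" is a multi-basin torsion landscape over an idealized
atom chain (fixed 1.5 Å bonds, 109.5° angles): each basin is a torsion-vector
center with a well energy. A synthetic "method" is a sampler that covers a
subset of the basins with wrapped-Gaussian torsion jitter, Cartesian noise,
and Gaussian energy error — emulating how real search programs differ in
coverage, geometric precision and energy-model quality. A designated
reference sampler covers the global-minimum basin of every catalyst with zero
energy bias, standing in for the high-level reference calculations.

Energies are declarative labels, not a force field; that is sufficient to
exercise every downstream statistic with a known answer. Because the basin
centers are separated by at least five torsion-jitter standard deviations,
clustering should recover exactly the true basins, participation fractions
should match true coverage, and grades become checkable against construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_conformers import Conformer, Ensemble, RepresentativeSelection, StudyRegistry
from .geometry import circular_difference

__all__ = [
    "Basin",
    "LandscapeSpec",
    "SamplerSpec",
    "StudyTruth",
    "build_chain_geometry",
    "sample_method",
    "make_study",
    "default_landscapes",
    "default_samplers",
    "default_study",
]

_BOND_LENGTH = 1.5  # Å, generic single bond
_BOND_ANGLE = 109.5  # degrees, tetrahedral


@dataclass
class Basin:
    """One torsion-space well: a center vector (degrees) and its energy (kcal/mol)."""

    center: tuple[float, ...]
    energy: float


@dataclass
class LandscapeSpec:
    """A synthetic catalyst: chain size, basins, and the torsion jitter scale.

    ``frozen_dihedral`` (index, angle) emulates a constrained search by pinning
    one torsion to a fixed value in every sampled conformer.
    """

    catalyst_id: str
    n_chain_atoms: int
    basins: tuple[Basin, ...]
    torsion_jitter_sigma: float = 5.0
    seed: int = 0
    frozen_dihedral: tuple[int, float] | None = None

    def __post_init__(self) -> None:
        self.basins = tuple(self.basins)
        if self.n_chain_atoms < 4:
            raise ValueError("chain needs at least 4 atoms")
        if len(self.basins) < 2:
            raise ValueError("a landscape needs at least 2 basins")
        nt = self.n_torsions
        for b in self.basins:
            if len(b.center) != nt:
                raise ValueError(
                    f"basin center length {len(b.center)} != {nt} chain torsions"
                )
        energies = [b.energy for b in self.basins]
        if energies.count(min(energies)) != 1:
            raise ValueError("global-minimum basin energy must be unique")
        # separability: basins must be distinguishable above the jitter
        if self.torsion_jitter_sigma > 0:
            for i in range(len(self.basins)):
                for j in range(i + 1, len(self.basins)):
                    d = float(
                        np.sqrt(
                            np.mean(
                                circular_difference(
                                    self.basins[i].center, self.basins[j].center
                                )
                                ** 2
                            )
                        )
                    )
                    if d < 5.0 * self.torsion_jitter_sigma:
                        raise ValueError(
                            f"basins {i} and {j} are {d:.1f} deg apart, below "
                            f"5 x jitter sigma ({5 * self.torsion_jitter_sigma:.1f})"
                        )

    @property
    def n_torsions(self) -> int:
        return self.n_chain_atoms - 3

    @property
    def dihedral_quads(self) -> tuple[tuple[int, int, int, int], ...]:
        return tuple(
            (i, i + 1, i + 2, i + 3) for i in range(self.n_chain_atoms - 3)
        )

    @property
    def global_min_basin(self) -> int:
        return int(np.argmin([b.energy for b in self.basins]))

    @property
    def selection(self) -> RepresentativeSelection:
        """All chain atoms and all consecutive backbone quads."""
        return RepresentativeSelection(
            atom_indices=tuple(range(self.n_chain_atoms)),
            dihedral_quads=self.dihedral_quads,
        )


@dataclass
class SamplerSpec:
    """A synthetic search method: which basins it finds and how noisily.

    ``energy_bias`` maps basin index -> a systematic per-basin energy offset
    (kcal/mol), emulating a method that mis-ranks particular wells.
    """

    method_label: str
    basin_coverage: tuple[int, ...]
    samples_per_basin: int = 15
    geometric_jitter_sigma: float = 0.02  # Å
    energy_error_sigma: float = 0.0  # kcal/mol
    energy_bias: Mapping[int, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.basin_coverage = tuple(sorted(set(int(i) for i in self.basin_coverage)))
        if not self.basin_coverage:
            raise ValueError("basin coverage must be non-empty")
        if self.samples_per_basin < 1:
            raise ValueError("samples_per_basin must be >= 1")
        if self.geometric_jitter_sigma < 0 or self.energy_error_sigma < 0:
            raise ValueError("jitter sigmas must be non-negative")


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta: float, tau: float) -> np.ndarray:
    """Place atom d with bond |cd| = r, angle bcd = theta, dihedral abcd = tau."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    t, p = np.radians(theta), np.radians(tau)
    d_local = np.array([-r * np.cos(t), r * np.sin(t) * np.cos(p), r * np.sin(t) * np.sin(p)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_chain_geometry(
    torsions: Sequence[float],
    n_chain_atoms: int,
    bond_length: float = _BOND_LENGTH,
    bond_angle: float = _BOND_ANGLE,
) -> np.ndarray:
    """Cartesian coordinates of an idealized chain with the given torsions.

    Internal coordinates (fixed bond length and angle, one torsion per
    consecutive atom quadruple) are converted atom by atom; measuring the
    dihedral on quad i of the result returns ``torsions[i]`` to < 1e-6°.
    """
    torsions = np.asarray(torsions, dtype=float)
    if n_chain_atoms < len(torsions) + 3:
        raise ValueError(
            f"{n_chain_atoms} atoms cannot carry {len(torsions)} torsions "
            f"(need >= {len(torsions) + 3})"
        )
    coords = np.zeros((n_chain_atoms, 3))
    coords[1] = [bond_length, 0.0, 0.0]
    ang = np.radians(180.0 - bond_angle)
    coords[2] = coords[1] + bond_length * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(3, n_chain_atoms):
        tau = torsions[i - 3] if i - 3 < len(torsions) else 180.0
        coords[i] = _place_atom(
            coords[i - 3], coords[i - 2], coords[i - 1], bond_length, bond_angle, tau
        )
    return coords


def _wrap_angles(a: np.ndarray) -> np.ndarray:
    """Wrap degrees to (-180, 180]."""
    out = (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0
    out[out == -180.0] = 180.0
    return out


def sample_method(
    landscape: LandscapeSpec, sampler: SamplerSpec, constrained: bool | None = None
) -> tuple[Ensemble, np.ndarray, np.ndarray]:
    """Sample one method's ensemble from a landscape.

    For each covered basin, ``samples_per_basin`` conformers are drawn:
    torsions are the basin center plus wrapped Gaussian jitter, coordinates
    are the rebuilt chain plus Cartesian noise, and the energy is the well
    energy plus the basin bias plus Gaussian error. Deterministic for fixed
    (landscape.seed, sampler.seed).

    Returns
    -------
    ensemble, basin_labels, true_energies
        The ensemble, the ground-truth basin index of each conformer, and each
        conformer's noise-free energy (well + bias excluded — the bare well
        energy, which is what the reference method would assign).
    """
    if max(sampler.basin_coverage) >= len(landscape.basins):
        raise ValueError(
            f"sampler {sampler.method_label!r} covers basin "
            f"{max(sampler.basin_coverage)} but landscape has {len(landscape.basins)}"
        )
    if constrained is None:
        constrained = landscape.frozen_dihedral is not None
    rng = np.random.default_rng([abs(landscape.seed), abs(sampler.seed)])
    conformers: list[Conformer] = []
    labels: list[int] = []
    true_e: list[float] = []
    symbols = tuple("C" for _ in range(landscape.n_chain_atoms))
    for basin_idx in sampler.basin_coverage:
        basin = landscape.basins[basin_idx]
        for j in range(sampler.samples_per_basin):
            torsions = np.asarray(basin.center, dtype=float)
            if landscape.torsion_jitter_sigma > 0:
                torsions = torsions + rng.normal(
                    0.0, landscape.torsion_jitter_sigma, size=torsions.shape
                )
            torsions = _wrap_angles(torsions)
            if landscape.frozen_dihedral is not None:
                idx, value = landscape.frozen_dihedral
                torsions[idx] = value
            coords = build_chain_geometry(torsions, landscape.n_chain_atoms)
            if sampler.geometric_jitter_sigma > 0:
                coords = coords + rng.normal(
                    0.0, sampler.geometric_jitter_sigma, size=coords.shape
                )
            energy = basin.energy + float(sampler.energy_bias.get(basin_idx, 0.0))
            if sampler.energy_error_sigma > 0:
                energy += rng.normal(0.0, sampler.energy_error_sigma)
            conformers.append(
                Conformer(
                    conformer_id=(
                        f"{landscape.catalyst_id}_{sampler.method_label}_b{basin_idx}_{j}"
                    ),
                    catalyst_id=landscape.catalyst_id,
                    method_label=sampler.method_label,
                    constrained=constrained,
                    atom_symbols=symbols,
                    coords=coords,
                    energy=energy,
                )
            )
            labels.append(basin_idx)
            true_e.append(basin.energy)
    ensemble = Ensemble(
        catalyst_id=landscape.catalyst_id,
        method_label=sampler.method_label,
        conformers=conformers,
        constrained=constrained,
        provenance=f"synthetic:{landscape.catalyst_id}/{sampler.method_label}",
    )
    return ensemble, np.array(labels), np.array(true_e)


@dataclass
class StudyTruth:
    """Ground truth of a synthetic study, for validating pipeline output.

    ``basin_labels`` / ``true_energies`` are keyed by (catalyst, method);
    ``ideal_geometries`` maps (catalyst, basin index) to the noise-free chain
    geometry at the basin center.
    """

    n_basins: dict[str, int]
    global_min_basin: dict[str, int]
    coverage: dict[tuple[str, str], tuple[int, ...]]
    basin_labels: dict[tuple[str, str], np.ndarray]
    true_energies: dict[tuple[str, str], np.ndarray]
    ideal_geometries: dict[tuple[str, int], np.ndarray]


def make_study(
    landscapes: Sequence[LandscapeSpec],
    samplers: Sequence[SamplerSpec],
    reference: SamplerSpec,
) -> tuple[StudyRegistry, StudyTruth]:
    """Assemble a full registry (every sampler × every catalyst) plus ground truth.

    The reference sampler must cover the global-minimum basin of every
    catalyst and carry no energy bias; otherwise the grading criteria would be
    calibrated against a broken reference.
    """
    for land in landscapes:
        if land.global_min_basin not in reference.basin_coverage:
            raise ValueError(
                f"reference sampler misses the global-minimum basin of "
                f"{land.catalyst_id!r}"
            )
    if any(v != 0 for v in reference.energy_bias.values()):
        raise ValueError("reference sampler must have zero energy bias")

    registry = StudyRegistry(reference_method=reference.method_label)
    truth = StudyTruth(
        n_basins={},
        global_min_basin={},
        coverage={},
        basin_labels={},
        true_energies={},
        ideal_geometries={},
    )
    for land in landscapes:
        registry.selections[land.catalyst_id] = land.selection
        truth.n_basins[land.catalyst_id] = len(land.basins)
        truth.global_min_basin[land.catalyst_id] = land.global_min_basin
        for b_idx, basin in enumerate(land.basins):
            center = np.asarray(basin.center, dtype=float)
            if land.frozen_dihedral is not None:
                center = center.copy()
                center[land.frozen_dihedral[0]] = land.frozen_dihedral[1]
            truth.ideal_geometries[(land.catalyst_id, b_idx)] = build_chain_geometry(
                center, land.n_chain_atoms
            )
        for sampler in [*samplers, reference]:
            ens, labels, true_e = sample_method(land, sampler)
            registry.add(ens)
            key = (land.catalyst_id, sampler.method_label)
            truth.coverage[key] = sampler.basin_coverage
            truth.basin_labels[key] = labels
            truth.true_energies[key] = true_e
    registry.validate()
    return registry, truth


def accuracy_from_truth(
    registry: StudyRegistry, truth: StudyTruth, method_label: str
):
    """Accuracy comparisons of one method against the synthetic ground truth.

    For each catalyst, one representative conformer per covered basin is
    compared: its geometry against the noise-free basin-center geometry
    (structure), and its sampled energy against the true well energy (energy),
    both energy vectors relative to their own minimum within the compared set.

    The representative is each basin's first sample — chosen independently of
    the sampled energies, because anchoring on the apparent minimum would
    select the most favorably noised conformer and bias the energy comparison
    (a winner's-curse effect that grows with ensemble size).

    Returns a list of :class:`confbench.grading.AccuracyResult`, one per
    catalyst.
    """
    from .geometry import subset_rmsd
    from .grading import AccuracyResult

    results = []
    for cat in registry.catalysts:
        ens = registry.get(cat, method_label)
        key = (cat, method_label)
        labels = truth.basin_labels[key]
        true_e = truth.true_energies[key]
        sel = registry.selection_for(cat)
        rep_idx = [int(np.where(labels == b)[0][0]) for b in sorted(set(labels.tolist()))]
        rmsds = []
        for i in rep_idx:
            ideal = truth.ideal_geometries[(cat, int(labels[i]))]
            ref_conf = Conformer(
                conformer_id=f"{cat}_ideal_b{labels[i]}",
                catalyst_id=cat,
                method_label=ens.method_label,
                constrained=ens[i].constrained,
                atom_symbols=ens.atom_symbols,
                coords=ideal,
                energy=0.0,
            )
            rmsds.append(subset_rmsd(ens[i], ref_conf, sel))
        em = ens.energies[rep_idx]
        et = true_e[rep_idx]
        results.append(
            AccuracyResult(
                method_label=method_label,
                catalyst_id=cat,
                structure_rmsds=np.array(rmsds),
                rel_energies_method=em - em.min(),
                rel_energies_ref=et - et.min(),
            )
        )
    return results


#: Torsion centers of the six default basins (all chain torsions equal).
_DEFAULT_BASIN_ANGLES = (-150.0, -90.0, -30.0, 30.0, 90.0, 150.0)
#: Well energies of the six default basins, kcal/mol above the global minimum.
_DEFAULT_BASIN_ENERGIES = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5)


def default_landscapes(seed: int = 0, n_catalysts: int = 3, n_chain_atoms: int = 8) -> list[LandscapeSpec]:
    """The default study's catalysts: 6 basins at 60°-spaced torsion values.

    All torsions of a basin share one angle, so adjacent basins are 60° apart
    in circular torsion distance — 12 standard deviations at the default 5°
    jitter, comfortably above the 5-sigma separability floor.
    """
    out = []
    for i in range(n_catalysts):
        nt = n_chain_atoms - 3
        basins = tuple(
            Basin(center=(a,) * nt, energy=e)
            for a, e in zip(_DEFAULT_BASIN_ANGLES, _DEFAULT_BASIN_ENERGIES)
        )
        out.append(
            LandscapeSpec(
                catalyst_id=f"cat_{chr(ord('a') + i)}",
                n_chain_atoms=n_chain_atoms,
                basins=basins,
                torsion_jitter_sigma=5.0,
                seed=seed + i,
            )
        )
    return out


def default_samplers(samples_per_basin: int = 15) -> tuple[list[SamplerSpec], SamplerSpec]:
    """Four graded methods (coverages 6/5/4/3) plus the full-coverage reference.

    Energy-error sigmas (0.3-0.8 kcal/mol) are on the scale of force-field vs
    reference discrepancies; the reference has zero energy error by design.
    """
    methods = [
        SamplerSpec("method_full", tuple(range(6)), samples_per_basin, 0.02, 0.3, seed=11),
        SamplerSpec("method_broad", tuple(range(5)), samples_per_basin, 0.02, 0.5, seed=12),
        SamplerSpec("method_mid", tuple(range(4)), samples_per_basin, 0.02, 0.8, seed=13),
        SamplerSpec("method_narrow", tuple(range(3)), samples_per_basin, 0.02, 0.4, seed=14),
    ]
    reference = SamplerSpec(
        "reference", tuple(range(6)), samples_per_basin, 0.02, 0.0, seed=10
    )
    return methods, reference


def default_study(
    seed: int = 0, n_catalysts: int = 3, samples_per_basin: int = 15
) -> tuple[StudyRegistry, StudyTruth]:
    """The canonical synthetic study: 6 basins, 4 methods + reference."""
    landscapes = default_landscapes(seed=seed, n_catalysts=n_catalysts)
    methods, reference = default_samplers(samples_per_basin=samples_per_basin)
    return make_study(landscapes, methods, reference)
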