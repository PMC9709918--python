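"""Multi-conformer ensemble I/O and the study registry.

An :class:`Ensemble` holds every conformer produced by one conformational-search
method ("method") for one molecule ("catalyst"), with one energy per conformer.
Two on-disk formats are supported: multi-record V2000 SDF (energy stored as a
named SD property) and plain multi-frame XYZ (energy parsed from the comment
line). Energies are kept in kcal/mol throughout; readers accept a unit override
for files written in hartree.

All atom indices exposed by this package are 0-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem

__all__ = [
    "HARTREE_TO_KCAL",
    "Conformer",
    "Ensemble",
    "RepresentativeSelection",
    "StudyRegistry",
    "read_sdf",
    "read_xyz",
    "write_sdf",
    "write_xyz",
]

#: Conversion factor from hartree to kcal/mol.
HARTREE_TO_KCAL = 627.509

_UNIT_FACTORS = {"kcal/mol": 1.0, "hartree": HARTREE_TO_KCAL}


@dataclass
class RepresentativeSelection:
    """Atom subset and dihedral quadruples used for featurization and subset RMSD.

    Parameters
    ----------
    atom_indices
        0-based indices of the representative atoms (scaffold plus substituent
        anchor atoms). Used for every subset-RMSD computation.
    dihedral_quads
        Bonded atom quadruples (0-based) whose signed torsion angles form the
        feature vector of a conformer.
    """

    atom_indices: tuple[int, ...]
    dihedral_quads: tuple[tuple[int, int, int, int], ...] = ()

    def __post_init__(self) -> None:
        self.atom_indices = tuple(int(i) for i in self.atom_indices)
        self.dihedral_quads = tuple(tuple(int(i) for i in q) for q in self.dihedral_quads)
        if not self.atom_indices:
            raise ValueError("atom_indices must be non-empty")
        if any(i < 0 for i in self.atom_indices):
            raise ValueError("atom indices are 0-based and must be non-negative")
        for quad in self.dihedral_quads:
            if len(quad) != 4 or len(set(quad)) != 4:
                raise ValueError(f"dihedral quad {quad!r} must contain 4 distinct atoms")

    def validate_for(self, n_atoms: int) -> None:
        """Raise if any index exceeds the molecule's atom count."""
        top = max(self.atom_indices)
        for quad in self.dihedral_quads:
            top = max(top, *quad)
        if top >= n_atoms:
            raise ValueError(f"selection references atom {top} but molecule has {n_atoms} atoms")


@dataclass
class Conformer:
    """One molecular geometry with its energy and provenance.

    ``coords`` is an (n_atoms, 3) array of Cartesian coordinates in Å;
    ``energy`` is in kcal/mol on the originating method's own scale (only
    relative energies within an ensemble are ever compared).
    """

    conformer_id: str
    catalyst_id: str
    method_label: str
    constrained: bool
    atom_symbols: tuple[str, ...]
    coords: np.ndarray
    energy: float

    def __post_init__(self) -> None:
        self.atom_symbols = tuple(self.atom_symbols)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atom_symbols), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.atom_symbols)} atom symbols"
            )
        if len(self.atom_symbols) < 4:
            raise ValueError("a conformer needs at least 4 atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        self.energy = float(self.energy)
        if not np.isfinite(self.energy):
            raise ValueError("non-finite energy")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_symbols)


@dataclass
class Ensemble:
    """All conformers produced by one method for one catalyst.

    Invariants: non-empty; every member shares the atom count, element
    ordering, and the (catalyst, method, constrained) provenance triple.
    """

    catalyst_id: str
    method_label: str
    conformers: list[Conformer]
    constrained: bool = False
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError("an Ensemble must contain at least one conformer")
        ref = self.conformers[0]
        for i, c in enumerate(self.conformers):
            if c.atom_symbols != ref.atom_symbols:
                raise ValueError(f"conformer {i} has inconsistent atom ordering")
            if (c.catalyst_id, c.method_label, c.constrained) != (
                self.catalyst_id,
                self.method_label,
                self.constrained,
            ):
                raise ValueError(f"conformer {i} provenance disagrees with ensemble")

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    def __getitem__(self, i: int) -> Conformer:
        return self.conformers[i]

    @property
    def atom_symbols(self) -> tuple[str, ...]:
        return self.conformers[0].atom_symbols

    @property
    def energies(self) -> np.ndarray:
        """Energies in file order, kcal/mol."""
        return np.array([c.energy for c in self.conformers])

    def lowest_energy_conformer(self) -> Conformer:
        """Global-minimum conformer; ties broken by the lower index."""
        return self.conformers[int(np.argmin(self.energies))]

    def subset(self, indices: Sequence[int]) -> "Ensemble":
        """New ensemble keeping ``indices`` in their original order."""
        kept = [self.conformers[i] for i in sorted(indices)]
        return Ensemble(
            catalyst_id=self.catalyst_id,
            method_label=self.method_label,
            conformers=kept,
            constrained=self.constrained,
            provenance=self.provenance,
        )


@dataclass
class StudyRegistry:
    """All ensembles of a benchmark study, keyed by (catalyst, method, constrained).

    ``reference_method`` names the method whose ensembles serve as ground truth
    for the accuracy and prediction criteria; ``selections`` maps each catalyst
    to its representative-atom selection.
    """

    ensembles: dict[tuple[str, str, bool], Ensemble] = field(default_factory=dict)
    reference_method: str = "reference"
    selections: dict[str, RepresentativeSelection] = field(default_factory=dict)

    def add(self, ensemble: Ensemble) -> None:
        key = (ensemble.catalyst_id, ensemble.method_label, ensemble.constrained)
        if key in self.ensembles:
            raise ValueError(f"duplicate ensemble {key}")
        self.ensembles[key] = ensemble

    def get(self, catalyst_id: str, method_label: str, constrained: bool = False) -> Ensemble:
        try:
            return self.ensembles[(catalyst_id, method_label, constrained)]
        except KeyError:
            raise KeyError(
                f"no ensemble for catalyst={catalyst_id!r} method={method_label!r} "
                f"constrained={constrained}"
            ) from None

    @property
    def catalysts(self) -> list[str]:
        return sorted({k[0] for k in self.ensembles})

    @property
    def methods(self) -> list[str]:
        return sorted({k[1] for k in self.ensembles})

    def methods_for(self, catalyst_id: str, constrained: bool = False) -> list[str]:
        return sorted(
            {m for (c, m, f) in self.ensembles if c == catalyst_id and f == constrained}
        )

    def selection_for(self, catalyst_id: str) -> RepresentativeSelection:
        try:
            return self.selections[catalyst_id]
        except KeyError:
            raise KeyError(f"no representative selection for catalyst {catalyst_id!r}") from None

    def validate(self) -> None:
        """Check that the reference method is present for every graded catalyst."""
        if not self.ensembles:
            raise ValueError("empty registry")
        for cat in self.catalysts:
            flags = {f for (c, m, f) in self.ensembles if c == cat}
            for flag in flags:
                if (cat, self.reference_method, flag) not in self.ensembles:
                    raise ValueError(
                        f"reference method {self.reference_method!r} missing for "
                        f"catalyst {cat!r} (constrained={flag})"
                    )


def _energy_factor(energy_unit: str) -> float:
    try:
        return _UNIT_FACTORS[energy_unit]
    except KeyError:
        raise ValueError(
            f"unknown energy unit {energy_unit!r}; expected one of {sorted(_UNIT_FACTORS)}"
        ) from None


def read_sdf(
    path: str | Path,
    catalyst_id: str,
    method_label: str,
    energy_property_name: str = "energy",
    constrained: bool = False,
    energy_unit: str = "kcal/mol",
) -> Ensemble:
    """Read a multi-record V2000 SDF file into an :class:`Ensemble`.

    Each record becomes one conformer, in file order. The energy is taken from
    the SD property ``energy_property_name``; a missing or non-numeric property
    is a hard error naming the record index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    factor = _energy_factor(energy_unit)
    try:
        supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    except OSError as exc:
        raise ValueError(f"{path}: no records ({exc})") from None
    conformers: list[Conformer] = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"{path}: record {idx} failed to parse")
        if not mol.HasProp(energy_property_name):
            raise ValueError(
                f"{path}: record {idx} lacks energy property {energy_property_name!r}"
            )
        raw = mol.GetProp(energy_property_name)
        try:
            energy = float(raw) * factor
        except ValueError:
            raise ValueError(
                f"{path}: record {idx} has non-numeric energy {raw!r}"
            ) from None
        symbols = tuple(a.GetSymbol() for a in mol.GetAtoms())
        coords = np.asarray(mol.GetConformer().GetPositions(), dtype=float)
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        conformers.append(
            Conformer(
                conformer_id=name or f"{catalyst_id}_{method_label}_{idx}",
                catalyst_id=catalyst_id,
                method_label=method_label,
                constrained=constrained,
                atom_symbols=symbols,
                coords=coords,
                energy=energy,
            )
        )
    if not conformers:
        raise ValueError(f"{path}: no records")
    return Ensemble(
        catalyst_id=catalyst_id,
        method_label=method_label,
        conformers=conformers,
        constrained=constrained,
        provenance=f"sdf:{path}",
    )


_FLOAT_RE = re.compile(r"[-+]?\d+\.?\d*(?:[eE][-+]?\d+)?")


def _parse_comment_energy(comment: str) -> float:
    """First numeric token in an XYZ comment line, with '=' treated as a separator."""
    for token in comment.replace("=", " ").split():
        try:
            return float(token)
        except ValueError:
            continue
    raise ValueError(f"no numeric energy token in comment line {comment!r}")


def read_xyz(
    path: str | Path,
    catalyst_id: str,
    method_label: str,
    constrained: bool = False,
    energy_unit: str = "kcal/mol",
) -> Ensemble:
    """Read a multi-frame XYZ file; the energy is the first numeric token of each
    frame's comment line (an optional ``Energy=`` key is tolerated)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    factor = _energy_factor(energy_unit)
    conformers: list[Conformer] = []
    pos, frame = 0, 0
    ref_symbols: tuple[str, ...] | None = None
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].strip())
        except ValueError:
            raise ValueError(f"{path}: frame {frame}: bad atom-count line {lines[pos]!r}") from None
        if pos + 2 + n_atoms > len(lines):
            raise ValueError(f"{path}: frame {frame}: truncated (expected {n_atoms} atoms)")
        try:
            energy = _parse_comment_energy(lines[pos + 1]) * factor
        except ValueError as exc:
            raise ValueError(f"{path}: frame {frame}: {exc}") from None
        symbols: list[str] = []
        coords = np.empty((n_atoms, 3))
        for i in range(n_atoms):
            parts = lines[pos + 2 + i].split()
            if len(parts) < 4:
                raise ValueError(f"{path}: frame {frame}: bad atom line {lines[pos + 2 + i]!r}")
            symbols.append(parts[0])
            coords[i] = [float(x) for x in parts[1:4]]
        if ref_symbols is None:
            ref_symbols = tuple(symbols)
        elif tuple(symbols) != ref_symbols:
            raise ValueError(f"{path}: frame {frame}: atom count/order mismatch with frame 0")
        conformers.append(
            Conformer(
                conformer_id=f"{catalyst_id}_{method_label}_{frame}",
                catalyst_id=catalyst_id,
                method_label=method_label,
                constrained=constrained,
                atom_symbols=tuple(symbols),
                coords=coords,
                energy=energy,
            )
        )
        pos += 2 + n_atoms
        frame += 1
    if not conformers:
        raise ValueError(f"{path}: no frames")
    return Ensemble(
        catalyst_id=catalyst_id,
        method_label=method_label,
        conformers=conformers,
        constrained=constrained,
        provenance=f"xyz:{path}",
    )


def _conformer_to_mol(c: Conformer, energy_property_name: str) -> Chem.Mol:
    mol = Chem.RWMol()
    for sym in c.atom_symbols:
        atom = Chem.Atom(sym)
        atom.SetNoImplicit(True)
        mol.AddAtom(atom)
    conf = Chem.Conformer(c.n_atoms)
    for i, (x, y, z) in enumerate(c.coords):
        conf.SetAtomPosition(i, (float(x), float(y), float(z)))
    mol.AddConformer(conf)
    out = mol.GetMol()
    out.SetProp("_Name", c.conformer_id)
    out.SetProp(energy_property_name, repr(c.energy))
    return out


def write_sdf(
    ensemble: Ensemble, path: str | Path, energy_property_name: str = "energy"
) -> None:
    """Write an ensemble as a multi-record V2000 SDF (coordinates keep the
    format's 4-decimal precision). Bond information is not emitted; records are
    coordinate + energy carriers."""
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    try:
        for c in ensemble:
            writer.write(_conformer_to_mol(c, energy_property_name))
    finally:
        writer.close()


def write_xyz(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-frame XYZ file, energy in the comment line."""
    path = Path(path)
    with path.open("w") as fh:
        for c in ensemble:
            fh.write(f"{c.n_atoms}\n")
            fh.write(f"Energy= {c.energy!r} kcal/mol {c.conformer_id}\n")
            for sym, (x, y, z) in zip(c.atom_symbols, c.coords):
                fh.write(f"{sym} {x:.6f} {y:.6f} {z:.6f}\n")
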