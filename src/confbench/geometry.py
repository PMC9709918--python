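"""Superposition RMSD, torsion featurization, and pairwise distance matrices.

Conformers coming from different search programs live in arbitrary coordinate
frames, so every structural comparison first removes translation and finds the
optimal proper rotation (Kabsch superposition); without it an RMSD would
measure frame placement rather than conformation. Torsion features use the
standard IUPAC signed-dihedral convention, wrapped to (-180, 180], and all
torsion distances are circular (359 degrees apart means 1 degree apart).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .io_conformers import Conformer, RepresentativeSelection

__all__ = [
    "DistanceMatrix",
    "kabsch_rmsd",
    "subset_rmsd",
    "dihedral_angle",
    "torsion_features",
    "circular_difference",
    "pairwise_distance_matrix",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over a list of conformers."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite distances")
        if np.any(np.abs(np.diag(self.values)) > 0):
            raise ValueError("diagonal must be exactly zero")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.labels)

    def to_tsv(self, path: str | Path) -> None:
        """Export as TSV with a header row of conformer ids."""
        with Path(path).open("w") as fh:
            fh.write("\t".join(self.labels) + "\n")
            for row in self.values:
                fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")


def kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Minimum RMSD (Å) between two point sets over all proper rigid motions.

    Both sets are centered at their centroids and the optimal proper rotation
    is found in closed form; the result is symmetric in its arguments and
    invariant under any rotation + translation of either input.

    Parameters
    ----------
    P, Q
        (m, 3) coordinate arrays with m >= 3, paired row by row.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("expected (m, 3) arrays with m >= 3")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # closed-form optimal proper rotation via SVD of the covariance matrix
    H = Qc.T @ Pc
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(U @ Vt))
    S[-1] *= sign
    msd = (np.sum(Pc**2) + np.sum(Qc**2) - 2.0 * np.sum(S)) / P.shape[0]
    return float(np.sqrt(max(msd, 0.0)))


def subset_rmsd(a: Conformer, b: Conformer, sel: RepresentativeSelection) -> float:
    """Kabsch RMSD restricted to the representative atoms of ``sel``."""
    if a.atom_symbols != b.atom_symbols:
        raise ValueError("conformers do not share atom ordering")
    sel.validate_for(a.n_atoms)
    idx = list(sel.atom_indices)
    return kabsch_rmsd(a.coords[idx], b.coords[idx])


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion angle (degrees) of four points, IUPAC convention.

    Returned in (-180, 180]. Raises on degenerate geometry (coincident
    consecutive points or collinear triples, where the torsion is undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < 1e-12 or np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("degenerate geometry: dihedral angle undefined")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2 / b2n)
    angle = np.degrees(np.arctan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def torsion_features(c: Conformer, sel: RepresentativeSelection) -> np.ndarray:
    """One signed dihedral per quad of ``sel``, in the selection's order."""
    if not sel.dihedral_quads:
        raise ValueError("selection has no dihedral quads")
    sel.validate_for(c.n_atoms)
    return np.array(
        [dihedral_angle(*(c.coords[i] for i in quad)) for quad in sel.dihedral_quads]
    )


def circular_difference(a, b) -> np.ndarray:
    """Elementwise circular angle difference in degrees, in [0, 180]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)


def _torsion_distance_matrix(features: np.ndarray) -> np.ndarray:
    # RMS of circular differences across dihedrals, fully vectorized
    diff = np.abs(features[:, None, :] - features[None, :, :]) % 360.0
    diff = np.minimum(diff, 360.0 - diff)
    out = np.sqrt(np.mean(diff**2, axis=2))
    np.fill_diagonal(out, 0.0)
    return out


def _rmsd_distance_matrix(conformers: Sequence[Conformer], sel: RepresentativeSelection) -> np.ndarray:
    idx = list(sel.atom_indices)
    coords = [c.coords[idx] for c in conformers]
    n = len(coords)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = kabsch_rmsd(coords[i], coords[j])
    return out


def pairwise_distance_matrix(
    conformers: Sequence[Conformer],
    sel: RepresentativeSelection,
    metric: Literal["subset_rmsd", "torsion", "blended"] = "blended",
    blend_weight: float = 0.5,
) -> DistanceMatrix:
    """Pairwise conformer distances on the representative atoms.

    metric
        ``"subset_rmsd"`` — Kabsch RMSD on the selected atoms (Å);
        ``"torsion"`` — root-mean-square circular difference over the selected
        dihedrals (degrees);
        ``"blended"`` — ``w * torsion / max(torsion) + (1 - w) * rmsd /
        max(rmsd)``, each term normalized by its own matrix maximum so the two
        heterogeneous units contribute on a common [0, 1] scale.
    blend_weight
        The torsion weight ``w`` of the blended metric (default 0.5).
    """
    if len(conformers) < 2:
        raise ValueError("need at least 2 conformers for a distance matrix")
    labels = tuple(c.conformer_id for c in conformers)
    if metric == "subset_rmsd":
        values = _rmsd_distance_matrix(conformers, sel)
    elif metric == "torsion":
        feats = np.stack([torsion_features(c, sel) for c in conformers])
        values = _torsion_distance_matrix(feats)
    elif metric == "blended":
        if not 0.0 <= blend_weight <= 1.0:
            raise ValueError("blend_weight must lie in [0, 1]")
        feats = np.stack([torsion_features(c, sel) for c in conformers])
        tors = _torsion_distance_matrix(feats)
        rmsd = _rmsd_distance_matrix(conformers, sel)
        tmax, rmax = tors.max(), rmsd.max()
        values = blend_weight * (tors / tmax if tmax > 0 else tors) + (
            1.0 - blend_weight
        ) * (rmsd / rmax if rmax > 0 else rmsd)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(labels=labels, values=values)
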