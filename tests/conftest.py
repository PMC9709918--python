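import numpy as np
import pytest

from confbench import (
    Conformer,
    Ensemble,
    RepresentativeSelection,
)
from confbench.synthetic import build_chain_geometry


def chain_conformer(
    torsions,
    energy=0.0,
    conformer_id="c0",
    catalyst_id="cat",
    method_label="m",
    n_atoms=None,
    jitter=None,
    rng=None,
):
    """Conformer on the idealized chain with the given backbone torsions."""
    n_atoms = n_atoms or len(torsions) + 3
    coords = build_chain_geometry(torsions, n_atoms)
    if jitter:
        coords = coords + (rng or np.random.default_rng(0)).normal(0, jitter, coords.shape)
    return Conformer(
        conformer_id=conformer_id,
        catalyst_id=catalyst_id,
        method_label=method_label,
        constrained=False,
        atom_symbols=tuple("C" for _ in range(n_atoms)),
        coords=coords,
        energy=energy,
    )


def chain_ensemble(torsion_rows, energies, **kw):
    """Ensemble of chain conformers, one row of torsions per conformer."""
    confs = [
        chain_conformer(t, energy=e, conformer_id=f"c{i}", **kw)
        for i, (t, e) in enumerate(zip(torsion_rows, energies))
    ]
    return Ensemble(catalyst_id="cat", method_label="m", conformers=confs)


@pytest.fixture
def chain_selection():
    """All atoms + all consecutive quads of a 6-atom chain (3 torsions)."""
    return RepresentativeSelection(
        atom_indices=tuple(range(6)),
        dihedral_quads=((0, 1, 2, 3), (1, 2, 3, 4), (2, 3, 4, 5)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
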