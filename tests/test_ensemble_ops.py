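"""Filtration rules: energy windows, RMSD dedupe, diversity selection."""

import itertools

import numpy as np
import pytest

from confbench import (
    diversity_subset,
    energy_window_filter,
    relative_energies,
    rmsd_dedupe,
    subset_rmsd,
    suggested_conformer_count,
)

from conftest import chain_ensemble


def _torsion_ensemble(angles, energies, **kw):
    return chain_ensemble([[a, a, a] for a in angles], energies, **kw)


class TestRelativeEnergies:
    def test_shifts_to_zero_minimum(self):
        ens = _torsion_ensemble([0, 40, 80], [-5.0, -3.0, -1.0])
        np.testing.assert_allclose(relative_energies(ens), [0.0, 2.0, 4.0])

    def test_idempotent(self):
        ens = _torsion_ensemble([0, 40], [0.0, 1.2])
        np.testing.assert_allclose(relative_energies(ens), [0.0, 1.2])


class TestEnergyWindow:
    def test_inclusive_boundary(self):
        ens = _torsion_ensemble([0, 40, 80, 120], [0.0, 2.9, 6.0, 7.4])
        kept = energy_window_filter(ens, 6.0)
        assert len(kept) == 3
        np.testing.assert_allclose(kept.energies, [0.0, 2.9, 6.0])

    def test_identity_when_all_within(self):
        ens = _torsion_ensemble([0, 40, 80], [0.0, 3.0, 9.0])
        assert len(energy_window_filter(ens, 10.0)) == 3

    def test_monotone_in_cutoff(self):
        ens = _torsion_ensemble([0, 40, 80, 120, 160], [0.0, 5.0, 12.0, 15.0, 25.0])
        ids10 = {c.conformer_id for c in energy_window_filter(ens, 10.0)}
        ids20 = {c.conformer_id for c in energy_window_filter(ens, 20.0)}
        assert ids10 <= ids20

    def test_idempotent(self):
        ens = _torsion_ensemble([0, 40, 80], [0.0, 4.0, 11.0])
        once = energy_window_filter(ens, 6.0)
        twice = energy_window_filter(once, 6.0)
        assert [c.conformer_id for c in once] == [c.conformer_id for c in twice]


class TestRmsdDedupe:
    def test_identical_geometries_collapse_to_lowest(self, chain_selection):
        ens = _torsion_ensemble([60, 60, 60], [1.0, 0.2, 3.0])
        kept = rmsd_dedupe(ens, 0.5, chain_selection)
        assert len(kept) == 1
        assert kept[0].energy == 0.2

    def test_energy_gate_blocks_merge(self, chain_selection):
        """Geometric duplicates survive when their energies differ beyond the gate."""
        ens = chain_ensemble([[60, 60, 60], [61, 60, 60]], [0.0, 0.2])
        d = subset_rmsd(ens[0], ens[1], chain_selection)
        assert d < 0.125  # near-duplicate pair by construction
        kept = rmsd_dedupe(ens, 0.125, chain_selection, energy_threshold=0.05)
        assert len(kept) == 2
        kept_no_gate = rmsd_dedupe(ens, 0.125, chain_selection)
        assert len(kept_no_gate) == 1

    def test_all_distinct_is_identity(self, chain_selection):
        ens = _torsion_ensemble([0, 120, -120], [0.0, 1.0, 2.0])
        assert len(rmsd_dedupe(ens, 0.5, chain_selection)) == 3

    def test_dropped_conformers_covered_by_kept(self, chain_selection, rng):
        """Without an energy gate, every dropped conformer lies within the
        threshold of some kept conformer, and kept ones are pairwise distinct."""
        angles = rng.uniform(-180, 180, size=12)
        ens = _torsion_ensemble(angles, rng.uniform(0, 5, size=12))
        thr = 1.0
        kept = rmsd_dedupe(ens, thr, chain_selection)
        kept_ids = {c.conformer_id for c in kept}
        for c in ens:
            if c.conformer_id not in kept_ids:
                assert min(subset_rmsd(c, k, chain_selection) for k in kept) <= thr
        for a, b in itertools.combinations(kept.conformers, 2):
            assert subset_rmsd(a, b, chain_selection) > thr

    def test_idempotent(self, chain_selection, rng):
        angles = rng.uniform(-180, 180, size=10)
        ens = _torsion_ensemble(angles, rng.uniform(0, 5, size=10))
        once = rmsd_dedupe(ens, 0.8, chain_selection)
        twice = rmsd_dedupe(once, 0.8, chain_selection)
        assert [c.conformer_id for c in once] == [c.conformer_id for c in twice]


class TestDiversitySubset:
    def test_full_k_is_identity(self, chain_selection):
        ens = _torsion_ensemble([0, 90, 180], [0.0, 1.0, 2.0])
        sub = diversity_subset(ens, 3, chain_selection)
        assert [c.conformer_id for c in sub] == [c.conformer_id for c in ens]

    def test_k1_is_lowest_energy(self, chain_selection):
        ens = _torsion_ensemble([0, 90, 180], [2.0, 0.5, 1.0])
        sub = diversity_subset(ens, 1, chain_selection)
        assert sub[0].energy == 0.5

    def test_matches_exhaustive_search(self, chain_selection, rng):
        """Greedy max-min selection achieves the same minimum pairwise distance
        as exhaustive search over all k-subsets containing the energy minimum,
        for small ensembles (greedy max-min is near-optimal; here we check the
        selected set against the brute-force oracle's objective)."""
        for trial in range(5):
            n, k = 8, 4
            angles = rng.uniform(-180, 180, size=n)
            energies = rng.uniform(0, 5, size=n)
            ens = _torsion_ensemble(angles, energies)
            D = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    D[i, j] = D[j, i] = subset_rmsd(ens[i], ens[j], chain_selection)
            seed = int(np.argmin(energies))
            # brute-force: best min-pairwise-distance over subsets containing the seed
            best = max(
                min(D[i, j] for i, j in itertools.combinations((seed, *rest), 2))
                for rest in itertools.combinations(
                    [i for i in range(n) if i != seed], k - 1
                )
            )
            sub = diversity_subset(ens, k, chain_selection)
            idx = [int(c.conformer_id[1:]) for c in sub]
            got = min(D[i, j] for i, j in itertools.combinations(idx, 2))
            # greedy max-min is a 2-approximation of the oracle objective
            assert got >= best / 2 - 1e-9

    def test_min_distance_non_increasing_in_k(self, chain_selection, rng):
        angles = rng.uniform(-180, 180, size=8)
        ens = _torsion_ensemble(angles, rng.uniform(0, 5, size=8))
        prev = np.inf
        for k in range(2, 7):
            sub = diversity_subset(ens, k, chain_selection)
            d = min(
                subset_rmsd(a, b, chain_selection)
                for a, b in itertools.combinations(sub.conformers, 2)
            )
            assert d <= prev + 1e-9
            prev = d

    def test_k_out_of_range(self, chain_selection):
        ens = _torsion_ensemble([0, 90], [0.0, 1.0])
        with pytest.raises(ValueError):
            diversity_subset(ens, 0, chain_selection)
        with pytest.raises(ValueError):
            diversity_subset(ens, 3, chain_selection)


def test_suggested_conformer_count():
    assert suggested_conformer_count(3) == 27
    assert suggested_conformer_count(1) == 1
    assert suggested_conformer_count(5) == 125
    with pytest.raises(ValueError):
        suggested_conformer_count(0)
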