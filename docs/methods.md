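# Methods

## Problem

Conformational-search programs differ in how much of a flexible molecule's
conformational space they find, how accurately they optimize each conformer's
geometry, and how accurately they rank conformers by energy. `confbench`
quantifies those differences for a set of molecules ("catalysts", after the
flexible organocatalysts this kind of benchmark is typically run on), each
searched by several programs ("methods"), with one method designated the
reference (in practice a DFT-level recomputation).

## Featurization and distances

All structural comparisons run on a per-molecule *representative selection*:
a subset of atoms (scaffold plus substituent anchor atoms, chosen to make
conformers distinguishable while avoiding symmetry-equivalent-atom
ambiguities) and a list of bonded atom quadruples whose signed torsions form
the feature vector. Three pairwise metrics are available:

* **subset RMSD** — Kabsch superposition RMSD (Å) on the selected atoms.
  Superposition is applied because ensembles from different programs sit in
  arbitrary coordinate frames; without it the "RMSD" would measure frame
  placement. The closed-form SVD solution is constrained to proper rotations.
* **torsion** — root-mean-square circular difference (degrees) over the
  selected dihedrals; each difference is wrapped to [0°, 180°], so θ and
  θ ± 360° are identical features.
* **blended** (default, weight w = 0.5) — `w·T/max(T) + (1−w)·R/max(R)`,
  each matrix normalized by its own maximum so degrees and Å contribute on a
  common [0, 1] scale. This feeds both kinds of information (torsional and
  Cartesian) into the clustering, and w is exposed in the config for users
  who want one or the other alone.

Dihedrals use the IUPAC sign convention and are reported in (−180°, 180°].
Degenerate quads (coincident or collinear points) raise instead of returning
an arbitrary angle.

## Clustering and participation

Per catalyst, every method's ensemble is pooled and the blended distance
matrix is embedded to 2-D with UMAP (`metric="precomputed"`,
`n_components=2`, `random_state=42`; a fixed seed trades parallelism for
bitwise reproducibility). HDBSCAN then labels clusters, with low-density
points assigned −1 (outliers) rather than forced into a cluster. A method's
*participation* for a catalyst is the fraction of non-outlier clusters that
contain at least one of its conformers; outliers appear in the composition
tables but enter neither numerator nor denominator.

Defaults: `n_neighbors=30`, `min_distance=0.1`, `min_samples=5`,
`min_cluster_size=8`, overridable globally and per catalyst. The
neighborhood size is deliberately on the order of the smallest cluster
occupancy expected in a pooled ensemble (≥ 30 conformers per conformer
family in the default synthetic study): UMAP neighborhoods much smaller than
a cluster's population can tear one continuous family into fragments in the
embedding — we observed exactly that (a ~75-conformer basin splitting 60/15,
with the fragment's input-space distances indistinguishable from the rest of
the basin) at `n_neighbors=15`, and no fragmentation across 12 independent
study instantiations for any value in 25–40.

## Boltzmann populations

Weights are `w_i = exp(−ΔE_i/RT)/Σ_j exp(−ΔE_j/RT)` with R =
1.987204×10⁻³ kcal/(mol·K) and T = 298 K by default; energies are shifted by
their minimum before exponentiation, so weights are invariant under additive
shifts and stable for large spreads. Summaries: the cumulative population of
conformers sorted by descending weight, the fraction of conformers needed to
reach 99 % cumulative population (ties broken by conformer index), and the
population mass per 5 %-of-conformers rank interval. No free-energy
corrections (ZPE, entropy) are applied — weighting is over bare relative
energies.

## Filtration

* `energy_window_filter` keeps conformers with ΔE ≤ cutoff (inclusive);
  typical cutoffs are 10 kcal/mol unconstrained, 20 kcal/mol constrained.
* `rmsd_dedupe` makes a greedy pass in ascending energy order, dropping a
  conformer within the RMSD threshold of an already-kept one; when a pair
  energy threshold is given (e.g. 0.125 Å / 0.05 kcal/mol, the
  metadynamics-searcher convention), BOTH gates must fire. Ascending-energy
  order guarantees the global minimum survives. All boundaries inclusive.
* `diversity_subset` is deterministic greedy max–min selection seeded at the
  lowest-energy conformer (ties to the lower index). Greedy max–min carries
  the standard factor-2 guarantee on the min-pairwise-distance objective; it
  is not exact, which is acceptable for its purpose (picking structures for
  expensive re-optimization) and is what the tests assert.

## Grading

Five criteria, each mapped to [0, 10]:

| criterion | formula | calibration |
|---|---|---|
| prediction capacity | 10·n_correct/N | agreement = subset RMSD of the two lowest-energy conformers ≤ 0.5 Å (configurable) |
| tunability | 10·n_features/7 | 7 features: optimization method, generation method, cutoffs, charge, constraints, solvent, temperature |
| exploration | 10·mean over catalysts of participation | — |
| structure | 10·(1 − RMSD/4.70 Å), clipped at 0 | 4.70 Å = worst observed structural RMSD in the calibration set |
| energy | 10·(1 − RMSD_E/17.31 kcal/mol), clipped at 0 | 17.31 kcal/mol = worst observed energy RMSD |

Linear interpolation between the two published anchors (10 at 0, 0 at the
maximum) is the minimal assumption; values beyond the calibration maximum
clip at 0. Energy vectors are compared as *relative* energies, each shifted
to its own minimum, because force-field, semiempirical and DFT absolute
scales are incommensurable; pairing is by conformer identity, never by rank.
The exploration grade averages per-catalyst participation fractions (rather
than pooling counts), so every catalyst contributes equally regardless of
its cluster count. A method's structure grade is the mean of per-conformer
grades; its energy grade is the mean over catalysts of the per-catalyst
energy-RMSD grade.

## Synthetic studies

A synthetic catalyst is a torsion landscape over an idealized carbon chain
(bonds 1.5 Å, angles 109.5°): each basin is a torsion-vector center with a
well energy. Chain geometries are built from internal coordinates; measured
torsions reproduce the requested ones to < 10⁻⁶°. A synthetic method covers
a subset of basins and draws, per covered basin, conformers with
wrapped-Gaussian torsion jitter, Gaussian Cartesian noise, and Gaussian
energy error plus an optional per-basin systematic bias. Sampling is
deterministic per (landscape seed, sampler seed). A "constrained" landscape
pins one torsion to a fixed value in every conformer, emulating a
constrained search. Landscapes enforce basin separability (pairwise circular
torsion distance ≥ 5× jitter σ) and a unique global minimum.

Default study (the conditions every recovery test runs under): 3 catalysts
× 6 basins at 60°-spaced torsion values with well energies 0–2.5 kcal/mol in
0.5 steps; torsion jitter 5°; four methods with basin coverages 6/5/4/3,
Cartesian noise 0.02 Å and energy errors 0.3/0.5/0.8/0.4 kcal/mol; a
full-coverage reference with zero energy error; 15 samples per basin
(50 for the energy-recovery check, where sampling error matters). These
sizes keep the full pipeline — distance matrices, UMAP, HDBSCAN, grading —
around half a minute on one core.

**Accuracy protocol.** Structural and energy accuracy are measured on one
representative conformer per covered basin, chosen *independently of the
sampled energies* (each basin's first sample). Anchoring instead on the
apparent energy minimum would systematically select the most favorably
noised conformer of the ensemble (a winner's-curse effect whose magnitude
grows with ensemble size, ≈ 2.3σ at 300 draws) and inflate the measured
energy RMSD by that bias once vectors are shifted to their own minima. With
energy-independent representatives the measured energy RMSD recovers the
injected noise σ to within ±50 %. Structure RMSDs compare each
representative against the noise-free basin-center geometry.

**What the generator does not emulate:** real energy errors are correlated
with structure (not i.i.d. Gaussian), basins are neither equally wide nor
isotropic, search programs do not sample basins uniformly, and real
molecules have symmetry-equivalent atoms the representative selection must
dodge. Passing recovery tests therefore demonstrates the *statistics* are
computed correctly under known ground truth, not that any particular real
program would receive these grades.

## Numerical choices

* Kabsch RMSD requires ≥ 3 points; the proper-rotation branch of the SVD
  solution is always taken (no reflections).
* All energy/RMSD thresholds are inclusive; ties in energy ordering and in
  greedy selection break to the lower index; Boltzmann rank ties break to
  the lower conformer index.
* The blended metric's normalization uses the matrix maximum; an all-zero
  component matrix contributes zeros (no 0/0).
* HDBSCAN labels are relabeled to first-appearance order 0..k−1 so output is
  stable; an all-identical point cloud is one cluster by definition; fewer
  points than `min_cluster_size` yields all-outliers with a warning.
* Hartree inputs are converted at 627.509 kcal/mol per hartree.

## Known limitations

* UMAP + HDBSCAN cluster counts are not guaranteed to equal the true basin
  count outside the separability regime the generator enforces; the
  composition tables, not the raw count, are the robust output.
* File-based (non-synthetic) studies compute accuracy only when method and
  reference ensembles are index-paired (the same conformers re-optimized);
  there is no automatic conformer matching.
* Tunability counts are declared study inputs, not measured quantities.
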