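# Methods

## Problem

Rosetta-style packing and design needs, for every residue type, a rotamer
library: the recurring side-chain conformations (chi-angle wells) with
their probabilities and spreads. For the 20 canonical amino acids these
are tabulated from crystal-structure statistics; for noncanonical amino
acids (NCAAs) no such statistics exist. `rotafit` parametrizes an
arbitrary monosubstituted amino-acid side chain by *simulating* the
statistics: it generates a large conformer ensemble of the capped
dipeptide with a cheminformatics conformer generator, then fits a mixture
model to the observed chi-angle distribution and writes the fitted wells
as a backbone-independent rotamer library.

## Pipeline

1. **Residue model.** The input (SDF/MOL/SMILES with N, CA, C annotated or
   auto-detected) is capped into a dipeptide: acetyl on the amine,
   N-methylamide on the acid, i.e. the backbone is extended through a
   peptide bond to an alpha-carbon-like methyl on both sides. Chi angles
   are derived by walking the heavy-atom path N → CA → CB → … along the
   longest heavy-atom chain; ring-interior bonds and bonds whose far side
   carries only hydrogens end the walk, and equally long branches resolve
   to the lowest canonical atom rank. This reproduces the standard chi
   quadruples for the canonical amino acids (and a fifth torsion for
   arginine's guanidinium, which the writer later truncates).

2. **Conformers.** The dipeptide is embedded `n_generate` times with
   RDKit's ETKDG distance-geometry generator (single-threaded, seeded, so
   runs are bit-reproducible). The experimental-torsion knowledge terms
   can be disabled (`use_experimental_torsions=False`) to emulate a purely
   geometric generator. For energy ranking, the caps are deleted, the
   opened valences are hydrogen-completed, and each pose is scored with
   UFF — so the score reflects the side chain's own strain, not cap-cap
   contacts. The best `n_keep` poses (default 100 of 1000-scale runs)
   form the explicit PDB-rotamer ensemble.

3. **Cartesian representation of angles.** Gaussians are a poor model on
   the circle, so nothing is fitted in angle space at the multivariate
   stage. For each chi quadruple (a, b, c, d), atoms a, b, c are
   Kabsch-superposed (proper rotation + translation) onto a canonical
   frame — b at the origin, c on +Z at the b–c bond length, a in the
   x > 0 half of the XZ plane — and the fourth atom's XYZ position is
   recorded. In this frame the dihedral is exactly `atan2(y, x)` with the
   conventional IUPAC sign, which the test suite verifies against the
   textbook four-atom formula to 1e-6 degrees. The shared frame per chi is
   built from the first conformer's internal geometry; other conformers'
   bond-length/angle jitter contributes sub-degree angular noise that the
   mixture fit absorbs.

4. **Mixture fit.** The n × 3N sample matrix (N = chi count) is fitted
   with scikit-learn's Dirichlet-process `BayesianGaussianMixture`
   ("infinite mixture"): 10^N initial components (capped at 1000 and at
   the sample count, which the backend requires), diagonal covariance,
   seeded. Components with weight < 0.005 are discarded and the survivors
   renormalized.

5. **Conversion to dihedral space.** A fitted peak's angular mean is the
   dihedral of its Cartesian mean. Its angular std follows the one-sigma
   ellipse construction: take the XY unit vector orthogonal to the
   origin→mean direction, intersect it with the peak's one-sigma XY
   ellipse (the t > 0 root), and report the circular difference between
   the dihedral at the intersection and the mean dihedral. The Z
   components never enter. For isotropic XY spread s at radius r this
   reduces to arctan(s/r) exactly, which is the closed form the tests
   check to 1e-9 degrees.

6. **Per-chi binning.** Each chi's marginal distribution is fitted
   independently as a one-dimensional mixture over its dihedral angles,
   after recentering the circle at the midpoint of the largest empty gap
   so that no cluster straddles the wrap-around seam (10 initial
   components, same 0.005 threshold). The surviving bin means, sorted
   ascending, define the 1-based rotamer bin indices.

7. **Assignment and merging.** Every surviving 3N-D peak is assigned, chi
   by chi, to the circularly nearest bin mean (ties to the lower index).
   Peaks sharing the full assignment vector are merged by a
   weight-proportional average of their Cartesian means and diagonal
   covariances, then converted to angles. The merged peaks are the final
   wells; their densities sum to 1 by construction.

8. **Output.** Wells are truncated to at most four chi angles (re-merging
   wells that collapse together, as for arginine's fifth torsion) and
   written to the rotlib dialect documented in `rotlib_format.md`, the
   same well set repeated over the whole 37 × 37 phi/psi grid — the
   file-format encoding of backbone independence. The energy-ranked
   ensemble is written as a multi-model PDB. Residues the format cannot
   express — no chi angles, a disubstituted alpha carbon, or a side chain
   conjugated back onto the backbone (proline-like) — fall back to
   PDB-rotamer output only.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `n_generate` | 10 000 | poses | the fitted ensemble; large enough that wells of a few-percent population carry hundreds of samples |
| `n_keep` | 100 | poses | explicit PDB-rotamer ensemble size (top-scoring 10% of a 1000-pose run) |
| `fit_filtered_only` | False | – | see "fit set" below |
| `density_threshold` | 0.005 | probability | minimum surviving peak/bin weight |
| initial components | 10^N (≤ 1000) | – | overcomplete start for the Dirichlet process |
| `std_floor_deg` | 1.0 | degrees | zero-width wells break off-rotamer scoring downstream |
| `seed` | 1 | – | drives embedding and (via a fixed offset) fitting |

Mixture hyperparameters beyond these (weight-concentration prior,
tolerance 1e-3, `reg_covar` 1e-6, 500 iterations for the joint fit / 2000
for the 1-D bin fits, up to 3 re-seeded retries on non-convergence) are
frozen in `FitConfig` for determinism. The 1-D bin fits additionally use
five restarts with `random_from_data` initialization, keeping the best
evidence lower bound: single-initialization EM on an overcomplete mixture
can stall in a local optimum where one angular cluster is covered by two
overlapping components, which would double-count a bin; restart selection
removes this failure mode on ground-truth sweeps while leaving
well-separated multi-bin fits unchanged.

## Design choices that were genuinely open

* **Fit set.** The joint mixture is fitted on the *full* generated
  ensemble, not the energy-filtered subset. UFF ranking of the capless
  dipeptide is aggressive: for leucine it removes the strained
  (−60°, +60°) chi1/chi2 combination from a top-10% cut entirely, so a
  filtered fit can never recover the full nine-well staggered structure.
  The unfiltered 10 000-pose ensemble populates all nine combinations at
  ≥ 7% each. `fit_filtered_only=True` restores the filtered behaviour for
  comparison.
* **Per-chi bins in angle space.** The joint fit must avoid angle space,
  but a one-dimensional marginal can be fitted on angles safely once the
  circle is cut at its largest empty gap. Fitting the marginals in the
  3-D Cartesian representation instead (available as
  `per_chi_cartesian=True`) tends to split each angular cluster into
  co-located components at large n — the clusters are arcs, not
  ellipsoids — which inflates the bin count and fragments wells.
* **Merge formula.** Same-assignment peaks merge by weighted averages of
  means and variances, without the between-means dispersion term a full
  moment match would add; wells merged this way are slightly narrower
  than a moment-matched alternative would be.
* **Frame details.** Only the two alignment constraints (central bond on
  Z, first three atoms in the XZ plane) are forced by the construction;
  pinning b to the origin, a to x > 0, and the frame's internal geometry
  to the first conformer makes outputs bit-reproducible.
* **Tie-breaks.** Branch ties in chi derivation go to the lowest
  canonical atom rank; bin-assignment ties go to the lower bin index;
  energy ties keep generation order. All are arbitrary but deterministic.

## Synthetic fixtures

`rotafit.synthetic` draws ground-truth mixtures: well labels by weight,
per-chi angles from wrapped normals (indistinguishable from von Mises at
the ≤ 30° widths used), lifted onto ideal sp3 geometry (C–C 1.53 Å,
109.47°) in the canonical frame. This emulates exactly what the extraction
stage produces — including nothing else: no energy correlation between
chis, no non-Gaussian well shapes, no bond-geometry jitter, no conformer
generator bias. Passing the recovery tests therefore demonstrates that the
fit-prune-bin-merge machinery inverts its own generative model at realistic
widths and weights; it does not by itself validate the conformer ensemble
as a stand-in for experimental rotamer statistics.

## Problem sizes and numerical notes

The acceptance script runs leucine at the full 10 000-conformer default;
the test suite exercises the same pipeline at 300-2000 conformers, which
already yields the identical nine-well structure, and uses 1000-sample,
10-seed synthetic recoveries. Degenerate inputs are handled explicitly:
collinear frame atoms and on-axis means raise geometry errors; a
zero-width converted std clamps to the 1° floor; an empty post-pruning
peak set raises an "empty library" error suggesting a lower threshold;
mixture non-convergence retries up to three times with derived seeds
before failing.

## Known limitations

* The ensemble is a force-field proxy for crystallographic statistics:
  well *probabilities* inherit UFF's and ETKDG's biases even where well
  *positions* are right.
* Backbone independence is an approximation by construction; phi/psi
  coupling of side-chain preferences is deliberately not modelled.
* Only monosubstituted, non-backbone-conjugated side chains with ≥ 1 chi
  get a rotlib; everything else degrades to explicit PDB rotamers.
* Chi angles beyond the fourth are truncated at output time (format
  limit), discarding e.g. guanidinium torsion statistics.
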