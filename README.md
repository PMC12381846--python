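# rotafit

Rotamer-library parametrization for noncanonical amino acids (NCAAs).

Protein packing and design software scores side-chain conformations
against a rotamer library — the recurring chi-angle wells of a residue,
each with a mean, a standard deviation and a probability. Canonical amino
acids have such libraries tabulated from crystal structures; noncanonical
side chains do not. `rotafit` builds one from chemistry alone: it caps the
residue into a dipeptide, generates a large seeded conformer ensemble
(RDKit ETKDG), and fits the chi-angle distribution with a
Dirichlet-process Gaussian mixture, writing the result as a
Dunbrack-style, backbone-independent rotamer library plus an explicit
multi-model PDB rotamer set.

## The statistical core

Angles live on a circle, so the mixture is never fitted in angle space.
Each chi quadruple (a, b, c, d) is Kabsch-superposed onto a canonical
frame (central b–c bond on the Z axis, atom a in the XZ plane), and the
fourth atom's Cartesian position is the fitted variable — 3N dimensions
for N chi angles. A Bayesian Gaussian mixture with 10^N initial
components and diagonal covariance infers the number of wells through its
Dirichlet-process prior; components with weight < 0.005 are pruned. Peak
means convert back to dihedrals via atan2; peak spreads convert by
intersecting the one-sigma XY ellipse tangentially, which for isotropic
spread s at radius r gives the closed form

    sigma_chi = arctan(s / r).

Each chi is then binned by an independent one-dimensional mixture over
its angles, every 3N-D peak is assigned its nearest bin per chi, and
same-assignment peaks merge by weighted averages into the final wells.

## Worked example

```bash
rotafit run --smiles "NC(CC(C)C)C(=O)O" --name LEU \
    --n-generate 2000 --seed 1 --out out_leu --mode both
```

prints (abridged):

```json
{
  "name": "LEU",
  "n_chi": 2,
  "n_generated": 2000,
  "rotlib_capable": true,
  "n_wells": 9,
  "per_chi_bin_counts": [3, 3],
  "wells": [
    {"bin": [3, 3], "chi_means": [179.95, 179.91], "chi_stds": [2.26, 2.35], "density": 0.182203},
    {"bin": [2, 3], "chi_means": [60.51, 179.88], "chi_stds": [3.92, 2.11], "density": 0.143814},
    {"bin": [3, 1], "chi_means": [179.93, -62.47], "chi_stds": [3.97, 5.94], "density": 0.1178},
    {"bin": [3, 2], "chi_means": [-179.97, 61.87], "chi_stds": [3.81, 5.72], "density": 0.11761},
    ...
  ]
}
```

Leucine's two chi angles each split into the three staggered bins near
−60°, +60° and 180°, and their product gives the nine classic leucine
rotamer wells; `density` is each well's probability in the fitted
ensemble, and `chi_stds` the within-well spread the packer will use for
off-rotamer scoring. `out_leu/LEU.rotlib` holds the same wells repeated
over the 37 × 37 phi/psi grid (the backbone-independent encoding;
dialect spec in `docs/rotlib_format.md`) and `out_leu/LEU_rotamers.pdb`
the energy-ranked explicit rotamers.

The same machinery is importable (see `examples/` for runnable
single-topic scripts):

```python
import rotafit as rf

spec = rf.load_residue("NC(CC(C)C)C(=O)O", "smiles", name="LEU")
dipep = rf.build_dipeptide(spec)
chis = rf.derive_chi_definitions(dipep)          # 2 chi quadruples
ens = rf.generate_conformers(dipep, 2000, seed=1)
samples = rf.extract_chi_samples(ens, chis)       # (2000, 6) matrix
wells, bins = rf.fit_wells(samples, rf.FitConfig(seed=8))
```

Residues the rotlib format cannot express — glycine/alanine-like (no chi
angle), disubstituted alpha carbons, or proline-like backbone-conjugated
rings — automatically fall back to PDB-rotamer output.

## Layout

* `src/rotafit/` — library modules: `residue_model`, `conformers`,
  `dihedral_geometry`, `well_fitting`, `rotlib_io`, `synthetic`,
  `pipeline`, `cli`.
* `docs/methods.md` — model, assumptions, parameter defaults, design
  rationale, limitations.
* `docs/rotlib_format.md` — the pinned output dialect.
* `examples/` — one short narrative script per capability.
* `tests/` — pytest suite (unit, property, and acceptance-level tests).
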