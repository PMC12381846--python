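"""Rotlib serialization, truncation, and PDB rotamer output."""

import io

import numpy as np
import pytest

import rotafit as rf
from rotafit.errors import RotlibFormatError
from rotafit.rotlib_io import PHI_PSI_GRID


def make_library(n_wells=3, n_chi=2, seed=0):
    rng = np.random.default_rng(seed)
    dens = rng.dirichlet(np.ones(n_wells) * 5)
    wells = []
    for i in range(n_wells):
        wells.append(rf.DihedralWell(
            chi_means=tuple(float(x) for x in rng.uniform(-179, 180, n_chi)),
            chi_stds=tuple(float(x) for x in rng.uniform(5, 15, n_chi)),
            density=float(dens[i]),
            bin_assignment=tuple(int(x) for x in (np.arange(n_chi) + 1 + i))))
    return rf.RotamerLibrary(residue_code="TST", wells=wells, n_chi=n_chi,
                             n_samples=1000)


class TestWriteRotlib:
    def test_grid_arithmetic(self):
        lib = make_library(n_wells=4)
        buf = io.StringIO()
        rf.write_rotlib(lib, buf)
        data_lines = [ln for ln in buf.getvalue().splitlines()
                      if ln and not ln.startswith("#")]
        assert len(data_lines) == 37 * 37 * 4
        assert len(PHI_PSI_GRID) == 37
        assert PHI_PSI_GRID[0] == -180 and PHI_PSI_GRID[-1] == 180

    def test_single_well_prints_unit_probability(self):
        lib = rf.RotamerLibrary(
            residue_code="ONE",
            wells=[rf.DihedralWell((60.0,), (9.0,), 1.0, (1,))],
            n_chi=1, n_samples=500)
        buf = io.StringIO()
        rf.write_rotlib(lib, buf)
        for ln in buf.getvalue().splitlines():
            if not ln.startswith("#"):
                assert "1.000000" in ln

    def test_block_probability_sums_within_rounding(self):
        lib = make_library(n_wells=5, seed=3)
        buf = io.StringIO()
        rf.write_rotlib(lib, buf)
        sums = {}
        for ln in buf.getvalue().splitlines():
            if ln.startswith("#"):
                continue
            tok = ln.split()
            sums.setdefault((tok[1], tok[2]), 0.0)
            sums[(tok[1], tok[2])] += float(tok[8])
        assert len(sums) == 37 * 37
        for s in sums.values():
            assert abs(s - 1.0) <= 5e-6 * 5

    def test_five_chi_library_rejected(self):
        with pytest.raises(RotlibFormatError):
            rf.RotamerLibrary(
                residue_code="BAD",
                wells=[rf.DihedralWell((0,) * 5, (9,) * 5, 1.0, (1,) * 5)],
                n_chi=5)


class TestReadRotlib:
    def test_round_trip_at_printed_precision(self):
        lib = make_library(n_wells=4, seed=7)
        buf = io.StringIO()
        rf.write_rotlib(lib, buf)
        back = rf.read_rotlib(buf.getvalue())
        assert back.residue_code == "TST"
        assert back.n_chi == lib.n_chi
        assert len(back.wells) == len(lib.wells)
        for w0, w1 in zip(lib.wells, back.wells):
            assert w1.density == pytest.approx(w0.density, abs=5e-6)
            for a, b in zip(w0.chi_means, w1.chi_means):
                assert abs(a - b) <= 0.05 + 1e-12
            for a, b in zip(w0.chi_stds, w1.chi_stds):
                assert abs(a - b) <= 0.05 + 1e-12
            assert w1.bin_assignment == w0.bin_assignment

    def test_backbone_dependent_file_warns(self, caplog):
        lib = make_library(n_wells=2, seed=1)
        buf = io.StringIO()
        rf.write_rotlib(lib, buf)
        lines = buf.getvalue().splitlines()
        # perturb one block's probabilities: backbone dependence
        for i, ln in enumerate(lines):
            if not ln.startswith("#"):
                tok = ln.split()
                tok[8] = "0.999000" if float(tok[8]) > 0.5 else "0.001000"
                lines[i] = " ".join(tok)
                break
        import logging
        with caplog.at_level(logging.WARNING, logger="rotafit.rotlib_io"):
            rf.read_rotlib("\n".join(lines) + "\n")
        assert any("backbone-dependent" in r.message for r in caplog.records)

    def test_truncated_line_raises_with_line_number(self):
        lib = make_library()
        buf = io.StringIO()
        rf.write_rotlib(lib, buf)
        broken = buf.getvalue()[:200]  # cut mid-line
        with pytest.raises(rf.errors.RotlibParseError):
            rf.read_rotlib(broken)


class TestTruncateToFourChi:
    def _five_chi_wells(self):
        return [
            rf.DihedralWell((60, 180, -60, 60, 180), (8,) * 5, 0.5, (1, 2, 1, 1, 2)),
            rf.DihedralWell((60, 180, -60, 60, -60), (8,) * 5, 0.3, (1, 2, 1, 1, 1)),
            rf.DihedralWell((-60, 60, 180, 180, 60), (8,) * 5, 0.2, (2, 1, 2, 2, 1)),
        ]

    def _five_chi_defs(self):
        return [rf.ChiDefinition((i, i + 1, i + 2, i + 3), i + 1) for i in range(5)]

    def test_arginine_style_truncation(self):
        wells, chi_defs = rf.truncate_to_four_chi(self._five_chi_wells(),
                                                  self._five_chi_defs())
        assert len(chi_defs) == 4
        assert all(w.n_chi == 4 for w in wells)
        assert sum(w.density for w in wells) == pytest.approx(1.0, abs=1e-9)
        # first two wells differed only in chi5: forced merge
        assert len(wells) == 2
        merged = max(wells, key=lambda w: w.density)
        assert merged.density == pytest.approx(0.8)

    def test_four_or_fewer_chi_unchanged(self):
        wells = [rf.DihedralWell((60, 180), (8, 9), 1.0, (1, 1))]
        defs = self._five_chi_defs()[:2]
        out_wells, out_defs = rf.truncate_to_four_chi(wells, defs)
        assert out_wells == wells and out_defs == defs


class TestPdbRotamers:
    def test_model_count_and_atom_order(self, leu_small_ensemble):
        kept = rf.rank_and_filter(leu_small_ensemble, 20)
        buf = io.StringIO()
        rf.write_pdb_rotamers(kept, strip_caps_flag=False, out=buf)
        text = buf.getvalue()
        assert text.count("MODEL") == 20
        assert text.count("ENDMDL") == 20
        models = [blk for blk in text.split("MODEL")[1:]]
        names0 = [ln[12:16] for ln in models[0].splitlines() if ln.startswith("ATOM")]
        assert len(names0) == kept.mol.GetNumAtoms()
        assert len(set(names0)) == len(names0)  # unique names
        for blk in models[1:]:
            names = [ln[12:16] for ln in blk.splitlines() if ln.startswith("ATOM")]
            assert names == names0

    def test_strip_caps_removes_cap_atoms(self, leu_small_ensemble):
        kept = rf.rank_and_filter(leu_small_ensemble, 3)
        full = io.StringIO()
        stripped = io.StringIO()
        rf.write_pdb_rotamers(kept, strip_caps_flag=False, out=full)
        rf.write_pdb_rotamers(kept, strip_caps_flag=True, out=stripped)
        n_full = full.getvalue().count("ATOM")
        n_stripped = stripped.getvalue().count("ATOM")
        # 12 cap atoms removed, 2 hydrogens added back to close valences
        assert n_stripped == n_full - 3 * len(kept.spec.cap_atoms) + 3 * 2

    def test_empty_ensemble_rejected(self, leu_dipeptide):
        from rdkit import Chem
        mol = Chem.Mol(leu_dipeptide.mol)
        mol.RemoveAllConformers()
        empty = rf.ConformerEnsemble(mol=mol, spec=leu_dipeptide, seed=0)
        with pytest.raises(RotlibFormatError):
            rf.write_pdb_rotamers(empty, out=io.StringIO())
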