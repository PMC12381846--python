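"""Rotamer-library ("rotlib") and multi-model PDB rotamer output.

The rotlib dialect is the 2002-style backbone-dependent library layout:
one line per well per (phi, psi) backbone block, with columns

    residue  phi  psi  count  r1 r2 r3 r4  probability  chi1..chi4  sd1..sd4

The backbone grid runs from -180 to +180 inclusive in 10-degree steps
(37 x 37 blocks, both endpoints present) and every block repeats the same
well list, which is what makes the library backbone-independent.  At most
four chi angles fit the format; unused chi columns hold 0.  The exact
column layout is documented byte-for-byte in ``docs/rotlib_format.md``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, TextIO

import numpy as np
from rdkit import Chem

from .conformers import ConformerEnsemble
from .dihedral_geometry import circular_difference, wrap_angle
from .errors import NamingError, RotlibFormatError, RotlibParseError
from .residue_model import ChiDefinition, strip_caps
from .well_fitting import DihedralWell

logger = logging.getLogger(__name__)

PHI_PSI_GRID = tuple(range(-180, 181, 10))  # 37 values, both endpoints

_LINE_FMT = ("{code:>3s} {phi:5.0f} {psi:5.0f} {count:6d}  "
             "{r1:d} {r2:d} {r3:d} {r4:d}  {prob:.6f}"
             "{c1:8.1f}{c2:8.1f}{c3:8.1f}{c4:8.1f}"
             "{s1:8.1f}{s2:8.1f}{s3:8.1f}{s4:8.1f}")


@dataclass
class RotamerLibrary:
    """An ordered, backbone-independent set of rotamer wells.

    ``n_samples`` is the number of conformers the wells were fitted from;
    it only feeds the informational count column of the output file.
    """

    residue_code: str
    wells: list[DihedralWell]
    n_chi: int
    n_samples: int = 0
    seed: int | None = None

    def __post_init__(self):
        if not self.wells:
            raise RotlibFormatError("a rotamer library needs at least one well")
        if self.n_chi > 4:
            raise RotlibFormatError(
                "the rotlib format represents at most four chi angles; "
                "truncate first")
        if any(w.n_chi != self.n_chi for w in self.wells):
            raise RotlibFormatError("well chi count disagrees with library n_chi")
        self.residue_code = self.residue_code.upper()[:3]
        self.wells = sorted(self.wells, key=lambda w: -w.density)
        total = sum(w.density for w in self.wells)
        if abs(total - 1.0) > 1e-9:
            logger.info("renormalizing well densities (sum was %.6f)", total)
            self.wells = [replace(w, density=w.density / total) for w in self.wells]


def _merge_wells_circular(wells: Sequence[DihedralWell]) -> DihedralWell:
    """Weight-proportional merge in dihedral space (circular mean of the
    means, average of the variances)."""
    w = np.array([x.density for x in wells])
    frac = w / w.sum()
    n_chi = wells[0].n_chi
    means, stds = [], []
    for k in range(n_chi):
        ang = np.radians([x.chi_means[k] for x in wells])
        m = math.degrees(math.atan2(np.dot(frac, np.sin(ang)),
                                    np.dot(frac, np.cos(ang))))
        means.append(wrap_angle(m))
        stds.append(float(np.sqrt(np.dot(frac, [x.chi_stds[k] ** 2 for x in wells]))))
    return DihedralWell(chi_means=tuple(means), chi_stds=tuple(stds),
                        density=float(w.sum()),
                        bin_assignment=wells[0].bin_assignment[:n_chi])


def truncate_to_four_chi(wells: Sequence[DihedralWell],
                         chi_defs: Sequence[ChiDefinition]
                         ) -> tuple[list[DihedralWell], list[ChiDefinition]]:
    """Drop chi 5+ from every well (the rotlib format's hard limit) and
    re-merge wells whose surviving assignment vectors coincide."""
    if len(chi_defs) <= 4:
        return list(wells), list(chi_defs)
    logger.info("truncating %d chi angles to 4 for rotlib output", len(chi_defs))
    cut: dict[tuple[int, ...], list[DihedralWell]] = {}
    for well in wells:
        trimmed = DihedralWell(chi_means=well.chi_means[:4],
                               chi_stds=well.chi_stds[:4],
                               density=well.density,
                               bin_assignment=well.bin_assignment[:4])
        cut.setdefault(trimmed.bin_assignment, []).append(trimmed)
    merged = [members[0] if len(members) == 1 else _merge_wells_circular(members)
              for members in cut.values()]
    total = sum(w.density for w in merged)
    merged = [replace(w, density=w.density / total) for w in merged]
    return sorted(merged, key=lambda w: -w.density), list(chi_defs[:4])


def _open_sink(out) -> tuple[TextIO, bool]:
    if isinstance(out, (str, bytes)) or hasattr(out, "__fspath__"):
        return open(out, "w"), True
    return out, False


def write_rotlib(lib: RotamerLibrary, out) -> None:
    """Emit the library in the pinned rotlib dialect (path or stream).

    Lines are grouped by (phi, psi) in row-major grid order; within each
    block wells appear by descending probability.  Probabilities print to
    six decimals and angles to one.
    """
    if lib.n_chi > 4:
        raise RotlibFormatError("libraries with more than four chi angles "
                                "cannot be written; truncate first")
    handle, close = _open_sink(out)
    try:
        handle.write(f"# rotamer library for {lib.residue_code}: "
                     f"{len(lib.wells)} wells, {lib.n_chi} chi, "
                     f"fitted from {lib.n_samples} conformers"
                     + (f", seed {lib.seed}" if lib.seed is not None else "")
                     + "\n")
        for phi in PHI_PSI_GRID:
            for psi in PHI_PSI_GRID:
                for well in lib.wells:
                    c = list(well.chi_means) + [0.0] * (4 - lib.n_chi)
                    s = list(well.chi_stds) + [0.0] * (4 - lib.n_chi)
                    r = list(well.bin_assignment) + [0] * (4 - lib.n_chi)
                    handle.write(_LINE_FMT.format(
                        code=lib.residue_code, phi=phi, psi=psi,
                        count=round(well.density * lib.n_samples),
                        r1=r[0], r2=r[1], r3=r[2], r4=r[3],
                        prob=well.density,
                        c1=c[0], c2=c[1], c3=c[2], c4=c[3],
                        s1=s[0], s2=s[1], s3=s[2], s4=s[3]) + "\n")
    finally:
        if close:
            handle.close()


def read_rotlib(source) -> RotamerLibrary:
    """Parse a rotlib file (path, stream, or text).

    Backbone-independence is validated: blocks whose well lists differ
    from the first block's trigger a warning (native backbone-dependent
    libraries do this legitimately), and the first block defines the
    returned library.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "\n" in source:
        text = source
    else:
        with open(source) as fh:
            text = fh.read()

    blocks: dict[tuple[float, float], list[tuple]] = {}
    code = None
    n_samples = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tok = line.split()
        if len(tok) != 17:
            raise RotlibParseError(f"expected 17 fields, found {len(tok)}", lineno)
        try:
            code = tok[0]
            phi, psi = float(tok[1]), float(tok[2])
            count = int(tok[3])
            bins = tuple(int(x) for x in tok[4:8])
            prob = float(tok[8])
            means = tuple(float(x) for x in tok[9:13])
            stds = tuple(float(x) for x in tok[13:17])
        except ValueError as exc:
            raise RotlibParseError(str(exc), lineno) from exc
        blocks.setdefault((phi, psi), []).append((bins, prob, means, stds, count))

    if not blocks:
        raise RotlibParseError("no data lines found")
    expected = len(PHI_PSI_GRID) ** 2
    if len(blocks) not in (1, expected):
        logger.warning("library has %d backbone blocks (expected %d)",
                       len(blocks), expected)
    first_key = sorted(blocks)[0]
    first = blocks[first_key]
    for key, rows in blocks.items():
        if rows != first:
            logger.warning("backbone block (%.0f, %.0f) differs from (%.0f, %.0f): "
                           "library is backbone-dependent", *key, *first_key)
            break

    n_chi = max((sum(1 for b in bins if b > 0) for bins, *_ in first), default=0)
    wells = []
    for bins, prob, means, stds, count in first:
        n_samples = max(n_samples, round(count / prob) if prob > 0 else 0)
        wells.append(DihedralWell(
            chi_means=means[:n_chi], chi_stds=stds[:n_chi],
            density=prob, bin_assignment=bins[:n_chi]))
    return RotamerLibrary(residue_code=code, wells=wells, n_chi=n_chi,
                          n_samples=n_samples)


# --- PDB rotamer output ----------------------------------------------------

def _assign_atom_names(mol: Chem.Mol, backbone_map: dict[str, int]) -> list[str]:
    """Deterministic, unique <=4-character PDB atom names: backbone atoms
    get their conventional names, everything else element + serial."""
    names = [""] * mol.GetNumAtoms()
    taken = set()
    for role in ("N", "CA", "C"):
        idx = backbone_map.get(role)
        if idx is not None and idx < mol.GetNumAtoms():
            names[idx] = role
            taken.add(role)
    # conventional O: the double-bonded oxygen on the backbone C
    c_idx = backbone_map.get("C")
    if c_idx is not None and c_idx < mol.GetNumAtoms():
        for nb in mol.GetAtomWithIdx(c_idx).GetNeighbors():
            bond = mol.GetBondBetweenAtoms(c_idx, nb.GetIdx())
            if nb.GetAtomicNum() == 8 and bond.GetBondType() == Chem.BondType.DOUBLE \
                    and not names[nb.GetIdx()]:
                names[nb.GetIdx()] = "O"
                taken.add("O")
                break
    counters: dict[str, int] = {}
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        if names[i]:
            continue
        sym = atom.GetSymbol().upper()
        while True:
            counters[sym] = counters.get(sym, 0) + 1
            cand = f"{sym}{counters[sym]}"
            if cand not in taken:
                break
        if len(cand) > 4:
            raise NamingError(f"atom name {cand} exceeds 4 characters")
        names[i] = cand
        taken.add(cand)
    return names


def write_pdb_rotamers(ensemble: ConformerEnsemble,
                       strip_caps_flag: bool = False,
                       out=None) -> None:
    """Write the ensemble as a multi-model PDB (MODEL/ENDMDL per pose).

    Atom names and order are identical across models; with
    ``strip_caps_flag`` the dipeptide caps are removed first (open
    valences hydrogen-completed with ideal coordinates).
    """
    if len(ensemble) == 0:
        raise RotlibFormatError("empty ensemble: nothing to write")
    spec = ensemble.spec
    if strip_caps_flag:
        mol = strip_caps(spec, ensemble.mol)
        from .residue_model import _read_backbone_tags  # index map after stripping
        backbone = _read_backbone_tags(mol)
    else:
        mol = Chem.Mol(ensemble.mol)
        backbone = dict(spec.backbone_map)
    names = _assign_atom_names(mol, backbone)
    resname = (spec.name or "UNK").upper()[:3]
    for atom, name in zip(mol.GetAtoms(), names):
        info = Chem.AtomPDBResidueInfo()
        # PDB alignment: 4-char names start at column 13, shorter at 14
        info.SetName(name if len(name) == 4 else f" {name:<3s}")
        info.SetResidueName(resname)
        info.SetResidueNumber(1)
        info.SetChainId("A")
        info.SetOccupancy(1.0)
        info.SetTempFactor(0.0)
        atom.SetMonomerInfo(info)

    handle, close = _open_sink(out)
    try:
        handle.write(f"REMARK   6 rotamer ensemble for {resname}, "
                     f"seed {ensemble.seed}\n")
        for i in range(mol.GetNumConformers()):
            block = Chem.MolToPDBBlock(mol, confId=i)
            atom_lines = [ln for ln in block.splitlines()
                          if ln.startswith(("ATOM", "HETATM"))]
            handle.write(f"MODEL {i + 1:>8d}\n")
            handle.write("\n".join(atom_lines) + "\n")
            handle.write("ENDMDL\n")
        handle.write("END\n")
    finally:
        if close:
            handle.close()


def match_wells(a: Sequence[DihedralWell], b: Sequence[DihedralWell]
                ) -> list[tuple[int, int, float]]:
    """Greedy circular-distance matching between two well lists.

    Returns (index in a, index in b, summed per-chi circular distance),
    greedily pairing the globally closest wells first.
    """
    pairs = []
    for i, wa in enumerate(a):
        for j, wb in enumerate(b):
            d = sum(circular_difference(x, y)
                    for x, y in zip(wa.chi_means, wb.chi_means))
            pairs.append((d, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    out = []
    for d, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append((i, j, d))
    return out
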