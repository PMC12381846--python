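"""Residue parsing, dipeptide capping, and chi-angle derivation.

A residue arrives as a MOL/SDF block or a SMILES string with its backbone
N, CA, C atoms annotated (explicitly, or auto-detected from the standard
amino-acid substructure).  For rotamer statistics the side chain must feel
a protein-like backbone, so the residue is capped into a dipeptide: an
acetyl group on the amine and an N-methylamide on the carbonyl, i.e. the
backbone is extended through a peptide bond to an alpha-carbon-like methyl
on each side.  The cap atoms are recorded so they can be stripped again
before side-chain energy scoring.

Chi angles are derived by walking the heavy-atom path N -> CA -> CB -> ...
along the longest heavy-atom chain of the side chain.  Rotation about
bonds interior to rings or about terminal bonds bearing only hydrogens
defines no chi; branch ties are broken by lowest canonical atom rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

from rdkit import Chem
from rdkit.Chem import rdmolops

from .errors import AnnotationError, ChemistryError, ConnectivityError, FormatError

logger = logging.getLogger(__name__)

# amine (neutral or protonated, not amide/imine) - CA - carbonyl carbon
_BACKBONE_SMARTS = Chem.MolFromSmarts(
    "[$([NX3;!$(N=*);!$(NC=O)]),$([NX4+])][CX4][CX3]=[OX1]")

#: role property set on backbone atoms; survives RDKit mol copies.
_ROLE_PROP = "rotafit_role"


@dataclass(frozen=True)
class ChiDefinition:
    """One chi angle: four atom indices (a, b, c, d) with the rotatable
    b-c bond as axis, plus the 1-based chi ordinal."""

    quadruple: tuple[int, int, int, int]
    index: int


@dataclass
class SideChainSpec:
    """A residue (or capped dipeptide) as an RDKit molecule with explicit
    hydrogens plus backbone bookkeeping.

    ``backbone_map`` holds the indices of N, CA and C; ``cap_atoms`` is
    empty until :func:`build_dipeptide` records the added cap atoms.
    """

    mol: Chem.Mol
    backbone_map: dict[str, int]
    name: str = "UNK"
    cap_atoms: tuple[int, ...] = ()

    def __post_init__(self):
        n_atoms = self.mol.GetNumAtoms()
        idxs = [self.backbone_map.get(k) for k in ("N", "CA", "C")]
        if any(i is None for i in idxs):
            raise AnnotationError("backbone map must name N, CA and C")
        if len(set(idxs)) != 3 or any(not 0 <= i < n_atoms for i in idxs):
            raise AnnotationError(f"backbone indices {idxs} must be distinct, valid atoms")
        if len(rdmolops.GetMolFrags(self.mol)) != 1:
            raise ConnectivityError("molecular graph is not connected")

    # --- convenience views -------------------------------------------------

    @property
    def atoms(self) -> list[tuple[str, int]]:
        """(element, formal charge) per atom."""
        return [(a.GetSymbol(), a.GetFormalCharge()) for a in self.mol.GetAtoms()]

    @property
    def bonds(self) -> list[tuple[int, int, float]]:
        """(begin, end, bond order) per bond."""
        return [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
                for b in self.mol.GetBonds()]

    @property
    def n_idx(self) -> int:
        return self.backbone_map["N"]

    @property
    def ca_idx(self) -> int:
        return self.backbone_map["CA"]

    @property
    def c_idx(self) -> int:
        return self.backbone_map["C"]

    def sidechain_root(self) -> int | None:
        """Index of CB: the unique non-backbone heavy neighbor of CA, or
        None for glycine-like residues (and for multiply substituted CA,
        where no unique root exists)."""
        roots = self._sidechain_roots()
        return roots[0] if len(roots) == 1 else None

    def _sidechain_roots(self) -> list[int]:
        ca = self.mol.GetAtomWithIdx(self.ca_idx)
        backbone = {self.n_idx, self.c_idx}
        return [nb.GetIdx() for nb in ca.GetNeighbors()
                if nb.GetAtomicNum() > 1 and nb.GetIdx() not in backbone]

    @property
    def is_monosubstituted(self) -> bool:
        """True when CA carries exactly one side-chain heavy atom — the
        precondition for the rotlib output path."""
        return len(self._sidechain_roots()) == 1

    @property
    def is_backbone_conjugated(self) -> bool:
        """True when the side chain bonds back onto the backbone (proline
        and derivatives), i.e. some ring contains both CA and N or C."""
        ri = self.mol.GetRingInfo()
        for ring in ri.AtomRings():
            ring = set(ring)
            if self.ca_idx in ring and (self.n_idx in ring or self.c_idx in ring):
                return True
        return False


def _tag_backbone(mol: Chem.Mol, backbone_map: Mapping[str, int]) -> None:
    for role in ("N", "CA", "C"):
        mol.GetAtomWithIdx(backbone_map[role]).SetProp(_ROLE_PROP, role)


def _read_backbone_tags(mol: Chem.Mol) -> dict[str, int]:
    out: dict[str, int] = {}
    for a in mol.GetAtoms():
        if a.HasProp(_ROLE_PROP):
            out[a.GetProp(_ROLE_PROP)] = a.GetIdx()
    return out


def _auto_backbone(mol: Chem.Mol) -> dict[str, int]:
    matches = mol.GetSubstructMatches(_BACKBONE_SMARTS)
    if not matches:
        raise AnnotationError(
            "no backbone annotation given and the N-CA-C(=O) motif was not found")
    n, ca, c, _o = matches[0]
    if len(matches) > 1:
        logger.warning("multiple backbone motifs matched; using the first (N=%d CA=%d C=%d)",
                       n, ca, c)
    return {"N": n, "CA": ca, "C": c}


def load_residue(structure_text: str,
                 format_tag: str = "sdf",
                 backbone_annotation: Mapping[str, int] | None = None,
                 name: str = "UNK") -> SideChainSpec:
    """Parse a residue from SDF/MOL text or a SMILES string.

    ``backbone_annotation`` maps {"N": i, "CA": j, "C": k} onto atom
    indices of the input (heavy-atom order as written); omit it to
    auto-detect the alpha-amino-acid backbone motif.  Hydrogens are made
    explicit on the returned molecule; formal charges are preserved.
    """
    fmt = format_tag.lower()
    if fmt in ("sdf", "mol"):
        mol = Chem.MolFromMolBlock(structure_text, removeHs=False)
    elif fmt in ("smiles", "line-notation", "smi"):
        mol = Chem.MolFromSmiles(structure_text)
    else:
        raise FormatError(f"unknown format tag {format_tag!r}")
    if mol is None:
        raise FormatError(f"could not parse {fmt} input")
    if len(rdmolops.GetMolFrags(mol)) != 1:
        raise ConnectivityError("input structure has disconnected fragments")

    if backbone_annotation is None:
        bb = _auto_backbone(mol)
    else:
        try:
            bb = {k: int(backbone_annotation[k]) for k in ("N", "CA", "C")}
        except KeyError as exc:
            raise AnnotationError(f"backbone annotation missing key {exc}") from exc
        for role, i in bb.items():
            if not 0 <= i < mol.GetNumAtoms():
                raise AnnotationError(f"backbone atom {role}={i} does not exist")
        if len(set(bb.values())) != 3:
            raise AnnotationError("backbone atoms N, CA, C must be distinct")
    _tag_backbone(mol, bb)
    molh = Chem.AddHs(mol)
    return SideChainSpec(mol=molh, backbone_map=_read_backbone_tags(molh), name=name)


def build_dipeptide(spec: SideChainSpec) -> SideChainSpec:
    """Cap the residue into its dipeptide form.

    The amine nitrogen gains an acetyl group (C(=O)-CH3) and the carbonyl
    carbon an N-methylamide (-NH-CH3); a hydroxyl on the carbonyl carbon
    (free-acid input) is removed first.  Cap atom indices, hydrogens
    included, are recorded on the returned spec.
    """
    mol = Chem.RemoveHs(Chem.Mol(spec.mol))
    bb = _read_backbone_tags(mol)
    if len(bb) != 3:
        raise AnnotationError("spec lost its backbone annotation")
    rw = Chem.RWMol(mol)

    c_idx = bb["C"]
    hydroxyl = None
    for nb in rw.GetAtomWithIdx(c_idx).GetNeighbors():
        bond = rw.GetBondBetweenAtoms(c_idx, nb.GetIdx())
        if nb.GetAtomicNum() == 8 and bond.GetBondType() == Chem.BondType.SINGLE \
                and nb.GetDegree() == 1:
            hydroxyl = nb.GetIdx()
            break
    if hydroxyl is not None:
        rw.RemoveAtom(hydroxyl)
        bb = _read_backbone_tags(rw)

    def new_atom(z: int) -> int:
        idx = rw.AddAtom(Chem.Atom(z))
        rw.GetAtomWithIdx(idx).SetProp("rotafit_cap", "1")
        return idx

    # acetyl on N: N-C(=O)-CH3
    ac_c = new_atom(6)
    ac_o = new_atom(8)
    ac_me = new_atom(6)
    rw.AddBond(ac_c, ac_o, Chem.BondType.DOUBLE)
    rw.AddBond(ac_c, ac_me, Chem.BondType.SINGLE)
    rw.AddBond(ac_c, bb["N"], Chem.BondType.SINGLE)
    # N-methylamide on C: C(=O)-NH-CH3
    am_n = new_atom(7)
    am_me = new_atom(6)
    rw.AddBond(bb["C"], am_n, Chem.BondType.SINGLE)
    rw.AddBond(am_n, am_me, Chem.BondType.SINGLE)

    capped = rw.GetMol()
    try:
        Chem.SanitizeMol(capped)
    except Exception as exc:  # RDKit raises several sanitize exception types
        raise ChemistryError(f"capping produced an invalid molecule: {exc}") from exc
    capped = Chem.AddHs(capped)

    cap_heavy = {a.GetIdx() for a in capped.GetAtoms() if a.HasProp("rotafit_cap")}
    cap_all = set(cap_heavy)
    for i in cap_heavy:
        for nb in capped.GetAtomWithIdx(i).GetNeighbors():
            if nb.GetAtomicNum() == 1:
                cap_all.add(nb.GetIdx())

    return SideChainSpec(mol=capped,
                         backbone_map=_read_backbone_tags(capped),
                         name=spec.name,
                         cap_atoms=tuple(sorted(cap_all)))


def strip_caps(spec: SideChainSpec, mol: Chem.Mol | None = None) -> Chem.Mol:
    """Remove the recorded cap atoms (from ``mol`` or the spec's own
    molecule), hydrogen-completing the valences opened at N and C.

    Conformers on the molecule are preserved; hydrogens added to close
    valences get coordinates from ideal placement when conformers exist.
    """
    if not spec.cap_atoms:
        raise ChemistryError("spec has no recorded cap atoms to strip")
    target = Chem.Mol(mol if mol is not None else spec.mol)
    rw = Chem.RWMol(target)
    for idx in sorted(spec.cap_atoms, reverse=True):
        rw.RemoveAtom(idx)
    stripped = rw.GetMol()
    try:
        Chem.SanitizeMol(stripped)
    except Exception as exc:
        raise ChemistryError(f"cap stripping produced an invalid molecule: {exc}") from exc
    return Chem.AddHs(stripped, addCoords=stripped.GetNumConformers() > 0)


def _longest_chain_from(mol: Chem.Mol, start: int, blocked: frozenset[int]) -> int:
    """Length of the longest simple heavy-atom path starting at ``start``,
    never entering ``blocked``.  Side chains are small; plain DFS is fine."""
    best = 0
    stack = [(start, {start})]
    while stack:
        node, seen = stack.pop()
        best = max(best, len(seen))
        for nb in mol.GetAtomWithIdx(node).GetNeighbors():
            j = nb.GetIdx()
            if nb.GetAtomicNum() > 1 and j not in seen and j not in blocked:
                stack.append((j, seen | {j}))
    return best


def derive_chi_definitions(spec: SideChainSpec) -> list[ChiDefinition]:
    """Walk the side chain from the backbone and emit ordered chi quadruples.

    chi1 is (N, CA, CB, G-atom); each further chi advances one bond along
    the longest heavy-atom chain.  The walk stops at ring-interior bonds
    and at bonds whose far side carries only hydrogens.  Equally long
    branches are resolved toward the lowest canonical atom rank.
    """
    mol = spec.mol
    cb = spec.sidechain_root()
    if cb is None:
        return []
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    path = [spec.n_idx, spec.ca_idx, cb]
    chis: list[ChiDefinition] = []
    while True:
        b, c = path[-2], path[-1]
        bond = mol.GetBondBetweenAtoms(b, c)
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            break
        candidates = [nb.GetIdx() for nb in mol.GetAtomWithIdx(c).GetNeighbors()
                      if nb.GetAtomicNum() > 1 and nb.GetIdx() not in path]
        if not candidates:
            break
        blocked = frozenset(path)
        scored = sorted(
            candidates,
            key=lambda j: (-_longest_chain_from(mol, j, blocked), ranks[j]))
        d = scored[0]
        chis.append(ChiDefinition(quadruple=(path[-3], b, c, d), index=len(chis) + 1))
        path.append(d)
    return chis


def with_name(spec: SideChainSpec, name: str) -> SideChainSpec:
    return replace(spec, name=name)
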