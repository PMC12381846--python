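"""Conformer ensemble generation, side-chain energy scoring, and filtering.

The dipeptide is embedded with RDKit's distance-geometry generator (ETKDG);
the experimental-torsion knowledge terms can be switched off to emulate a
purely geometric generator.  Scoring removes the dipeptide caps first and
hydrogen-completes the open valences, so the UFF energy reflects the side
chain's rotameric strain rather than backbone-backbone contacts.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdDistGeom

from .errors import GenerationError, ScoringError
from .residue_model import SideChainSpec, strip_caps

logger = logging.getLogger(__name__)


@dataclass
class ConformerEnsemble:
    """Energy-rankable 3-D poses of one dipeptide.

    ``mol`` carries one RDKit conformer per pose, all sharing the spec's
    atom ordering.  ``energies`` is parallel to the conformers and stays
    None until :func:`score_sidechain_energy` runs.
    """

    mol: Chem.Mol
    spec: SideChainSpec
    seed: int
    energies: np.ndarray | None = None
    sorted_by_energy: bool = field(default=False)

    def __post_init__(self):
        if self.energies is not None:
            self.energies = np.asarray(self.energies, dtype=float)
            if len(self.energies) != self.mol.GetNumConformers():
                raise ValueError("energies list must parallel the conformers")

    def __len__(self) -> int:
        return self.mol.GetNumConformers()

    @property
    def coordinates(self) -> list[np.ndarray]:
        """Per-conformer (n_atoms, 3) coordinate arrays in Angstrom."""
        return [self.mol.GetConformer(i).GetPositions()
                for i in range(self.mol.GetNumConformers())]

    def to_sdf(self, path_or_stream) -> None:
        """Write the ensemble as a multi-record SDF (one record per pose)."""
        close = False
        if isinstance(path_or_stream, (str, bytes)) or hasattr(path_or_stream, "__fspath__"):
            handle = open(path_or_stream, "w")
            close = True
        else:
            handle = path_or_stream
        try:
            writer = Chem.SDWriter(handle)
            writer.SetKekulize(True)
            for i in range(len(self)):
                if self.energies is not None:
                    self.mol.SetProp("energy", f"{self.energies[i]:.6f}")
                writer.write(self.mol, confId=i)
            writer.close()
        finally:
            if close:
                handle.close()


def ensemble_from_sdf(text_or_path, spec: SideChainSpec, seed: int = 0) -> ConformerEnsemble:
    """Load an externally produced ensemble from multi-record SDF text or a
    path.  Records must share the spec's atom count and order."""
    if hasattr(text_or_path, "__fspath__") or (isinstance(text_or_path, str)
                                               and "\n" not in text_or_path):
        with open(text_or_path) as fh:
            text = fh.read()
    else:
        text = text_or_path
    supplier = Chem.ForwardSDMolSupplier(io.BytesIO(text.encode()), removeHs=False,
                                         sanitize=True)
    base: Chem.Mol | None = None
    energies: list[float] = []
    have_energy = True
    for rec in supplier:
        if rec is None:
            continue
        if base is None:
            base = Chem.Mol(rec)
            base.RemoveAllConformers()
        if rec.GetNumAtoms() != base.GetNumAtoms():
            raise GenerationError("SDF records disagree on atom count")
        conf = Chem.Conformer(rec.GetConformer())
        conf.SetId(base.GetNumConformers())
        base.AddConformer(conf, assignId=False)
        if rec.HasProp("energy"):
            energies.append(float(rec.GetProp("energy")))
        else:
            have_energy = False
    if base is None or base.GetNumConformers() == 0:
        raise GenerationError("no conformers found in SDF input")
    if base.GetNumAtoms() != spec.mol.GetNumAtoms():
        raise GenerationError(
            f"SDF atom count {base.GetNumAtoms()} != spec atom count {spec.mol.GetNumAtoms()}")
    return ConformerEnsemble(mol=base, spec=spec, seed=seed,
                             energies=np.array(energies) if have_energy else None)


def generate_conformers(spec: SideChainSpec,
                        n_generate: int,
                        seed: int,
                        use_experimental_torsions: bool = True) -> ConformerEnsemble:
    """Embed ``n_generate`` 3-D poses of the capped dipeptide.

    ``use_experimental_torsions`` toggles ETKDG's knowledge-based torsion
    preferences; with it off the generator falls back to plain distance
    geometry plus basic chemical knowledge.  Deterministic for a fixed
    seed (embedding runs single-threaded).
    """
    if n_generate < 1:
        raise ValueError("n_generate must be at least 1")
    mol = Chem.Mol(spec.mol)
    params = rdDistGeom.ETKDGv3()
    params.randomSeed = int(seed)
    params.numThreads = 1
    params.useExpTorsionAnglePrefs = bool(use_experimental_torsions)
    cids = rdDistGeom.EmbedMultipleConfs(mol, int(n_generate), params)
    n_ok = len(cids)
    if n_ok == 0:
        raise GenerationError("conformer embedding failed for every pose")
    if n_ok < n_generate:
        logger.warning("embedded %d of %d requested conformers", n_ok, n_generate)
    return ConformerEnsemble(mol=mol, spec=spec, seed=int(seed))


def score_sidechain_energy(ensemble: ConformerEnsemble) -> ConformerEnsemble:
    """UFF-score every conformer after deleting the dipeptide caps.

    Cap removal (with hydrogen completion of the opened valences) makes
    the side chain's own strain dominate the score instead of cap-cap
    backbone contacts.  Coordinates of the ensemble are unchanged; only
    energies are attached.
    """
    spec = ensemble.spec
    if not spec.cap_atoms:
        raise ScoringError("spec records no cap atoms; build the dipeptide first")
    try:
        stripped = strip_caps(spec, ensemble.mol)
    except Exception as exc:
        raise ScoringError(f"cap removal failed: {exc}") from exc
    n = stripped.GetNumConformers()
    energies = np.empty(n)
    for cid in range(n):
        try:
            ff = AllChem.UFFGetMoleculeForceField(stripped, confId=cid)
            if ff is None:
                raise ScoringError(f"UFF setup failed for conformer {cid}")
            energies[cid] = ff.CalcEnergy()
        except ScoringError:
            raise
        except Exception as exc:
            raise ScoringError(f"UFF evaluation failed for conformer {cid}: {exc}") from exc
    return replace(ensemble, energies=energies, sorted_by_energy=False)


def rank_and_filter(ensemble: ConformerEnsemble, n_keep: int) -> ConformerEnsemble:
    """Keep the ``n_keep`` lowest-energy conformers, sorted ascending.

    Ties keep their original conformer order (stable sort).  Asking for
    more conformers than exist keeps everything, with a warning.
    """
    if ensemble.energies is None:
        raise ScoringError("ensemble has no energies; score it first")
    n = len(ensemble)
    if n_keep > n:
        logger.warning("n_keep=%d exceeds ensemble size %d; keeping all", n_keep, n)
        n_keep = n
    order = np.argsort(ensemble.energies, kind="stable")[:n_keep]
    kept = Chem.Mol(ensemble.mol)
    kept.RemoveAllConformers()
    for new_id, old in enumerate(order):
        conf = Chem.Conformer(ensemble.mol.GetConformer(int(old)))
        conf.SetId(new_id)
        kept.AddConformer(conf, assignId=False)
    return ConformerEnsemble(mol=kept, spec=ensemble.spec, seed=ensemble.seed,
                             energies=ensemble.energies[order], sorted_by_energy=True)
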