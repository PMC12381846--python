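"""Synthetic dihedral-mixture fixtures.

Ground-truth rotamer wells (stated means, stds, weights) are sampled as
wrapped normals and placed on ideal tetrahedral geometry in the canonical
reference frame, producing a :class:`ChiSampleMatrix` exactly like the one
the conformer pipeline extracts — so every fitting and conversion stage can
be exercised with no chemistry backend at all.  At well widths up to ~30
degrees a wrapped normal is numerically indistinguishable from a von Mises
for this purpose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml

from .dihedral_geometry import ChiSampleMatrix, ReferenceFrame, wrap_angle
from .errors import GeometryError
from .residue_model import ChiDefinition

#: ideal sp3 carbon geometry used unless overridden
DEFAULT_BOND_LENGTH = 1.53      # Angstrom, C-C
DEFAULT_BOND_ANGLE = 109.47     # degrees, tetrahedral


@dataclass(frozen=True)
class SyntheticWellSpec:
    """One ground-truth well of an N-chi synthetic mixture."""

    chi_means: tuple[float, ...]
    chi_stds: tuple[float, ...]
    weight: float

    def __post_init__(self):
        if len(self.chi_means) != len(self.chi_stds):
            raise ValueError("chi_means and chi_stds lengths differ")
        if any(s <= 0 for s in self.chi_stds):
            raise ValueError("stds must be positive")
        if not 0 < self.weight <= 1:
            raise ValueError("weight must lie in (0, 1]")

    @property
    def n_chi(self) -> int:
        return len(self.chi_means)


def _check_wells(wells: Sequence[SyntheticWellSpec]) -> int:
    if not wells:
        raise ValueError("need at least one well")
    n_chi = wells[0].n_chi
    if any(w.n_chi != n_chi for w in wells):
        raise ValueError("all wells must share the chi count")
    total = sum(w.weight for w in wells)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"well weights must sum to 1, got {total}")
    return n_chi


def sample_dihedrals(wells: Sequence[SyntheticWellSpec],
                     n: int,
                     seed: int) -> np.ndarray:
    """Draw n rows of per-chi angles (degrees, wrapped to (-180, 180]).

    A well is chosen per row by weight, then each chi is drawn from a
    wrapped normal around that well's mean.  Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    n_chi = _check_wells(wells)
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(wells), size=n, p=[w.weight for w in wells])
    out = np.empty((n, n_chi))
    for k in range(n_chi):
        means = np.array([w.chi_means[k] for w in wells])[labels]
        stds = np.array([w.chi_stds[k] for w in wells])[labels]
        raw = rng.normal(means, stds)
        out[:, k] = np.vectorize(wrap_angle)(raw)
    return out


def dihedrals_to_cartesian_samples(angles: np.ndarray,
                                   bond_length: float = DEFAULT_BOND_LENGTH,
                                   bond_angle: float = DEFAULT_BOND_ANGLE
                                   ) -> ChiSampleMatrix:
    """Place fourth atoms on the ideal-geometry cone at the given dihedrals.

    This is the exact inverse of the extraction step on ideal geometry:
    round-tripping through the frame dihedral recovers the input angles to
    floating-point precision.
    """
    if bond_length <= 0:
        raise GeometryError("bond length must be positive")
    if not 0.0 < bond_angle < 180.0:
        raise GeometryError("bond angle must lie strictly between 0 and 180 degrees")
    angles = np.atleast_2d(np.asarray(angles, dtype=float))
    n, n_chi = angles.shape
    frame = ReferenceFrame.from_internal(bond_length, bond_length, bond_angle)
    # direction of c->d makes (180 - bond_angle) with +Z, dihedral sets azimuth
    polar = np.radians(180.0 - bond_angle)
    rho = bond_length * np.sin(polar)
    z = bond_length + bond_length * np.cos(polar)
    X = np.empty((n, 3 * n_chi))
    rad = np.radians(angles)
    for k in range(n_chi):
        X[:, 3 * k] = rho * np.cos(rad[:, k])
        X[:, 3 * k + 1] = rho * np.sin(rad[:, k])
        X[:, 3 * k + 2] = z
    chi_defs = [ChiDefinition(quadruple=(0, 1, 2, 3), index=k + 1)
                for k in range(n_chi)]
    return ChiSampleMatrix(samples=X, chi_defs=chi_defs,
                           frames=[frame] * n_chi)


def sample_cartesian(wells: Sequence[SyntheticWellSpec],
                     n: int,
                     seed: int,
                     bond_length: float = DEFAULT_BOND_LENGTH,
                     bond_angle: float = DEFAULT_BOND_ANGLE) -> ChiSampleMatrix:
    """Convenience: sample dihedrals and lift them onto ideal geometry."""
    return dihedrals_to_cartesian_samples(sample_dihedrals(wells, n, seed),
                                          bond_length, bond_angle)


def wells_from_yaml(source) -> tuple[list[SyntheticWellSpec], dict]:
    """Load a fixture spec from YAML text, a stream, or a path.

    Layout::

        wells:
          - means: [-60, 180]
            stds: [10, 12]
            weight: 0.5
          ...
        n: 1000        # optional extras returned in the second element
        seed: 1
    """
    if hasattr(source, "read"):
        data = yaml.safe_load(source)
    elif isinstance(source, str) and "\n" in source:
        data = yaml.safe_load(source)
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh)
    wells = [SyntheticWellSpec(chi_means=tuple(float(x) for x in w["means"]),
                               chi_stds=tuple(float(x) for x in w["stds"]),
                               weight=float(w["weight"]))
             for w in data["wells"]]
    _check_wells(wells)
    extras = {k: v for k, v in data.items() if k != "wells"}
    return wells, extras
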