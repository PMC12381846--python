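"""Canonical reference frames and Cartesian <-> dihedral conversion.

Gaussians are a poor model for angles because dihedral space is periodic.
The pipeline therefore never fits angles directly: each chi quadruple
(a, b, c, d) is rigidly superposed so that its central b-c bond lies on the
Z axis and atom a lies in the x > 0 half of the XZ plane, and the fourth
atom's XYZ position in that frame is what gets fitted.  In this frame the
dihedral is simply ``atan2(y, x)`` of the fourth atom, with 0 degrees at the
a-atom half-plane (cis) and the conventional IUPAC sign.

Fitted Gaussian peaks come back as a Cartesian mean and per-axis standard
deviations; :func:`cartesian_peak_to_dihedral` converts them to an angular
mean/std by intersecting the one-sigma XY ellipse with the tangential
direction at the mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GeometryError

if TYPE_CHECKING:  # pragma: no cover
    from .conformers import ConformerEnsemble
    from .residue_model import ChiDefinition

logger = logging.getLogger(__name__)

#: Angles below this XY radius (in Angstrom) are considered degenerate.
_XY_EPS = 1e-10

#: Default floor for converted dihedral standard deviations, degrees.
#: Zero-width wells break off-rotamer scoring downstream.
STD_FLOOR_DEG = 1.0


@dataclass(frozen=True)
class ReferenceFrame:
    """Target coordinates for the first three atoms of a chi quadruple.

    Atom b sits at the origin, atom c on +Z at the b-c bond length, and
    atom a in the x > 0 half of the XZ plane.
    """

    coords: np.ndarray  # shape (3, 3): rows a, b, c

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3, 3):
            raise GeometryError(f"frame needs 3 atom positions, got shape {c.shape}")
        a, b, z = c
        if abs(a[1]) > 1e-8 or not np.allclose(b, 0, atol=1e-8) or abs(z[0]) > 1e-8 or abs(z[1]) > 1e-8:
            raise GeometryError("frame atoms violate the canonical constraints "
                                "(b at origin, c on Z, a in the XZ plane)")
        if a[0] <= 0:
            raise GeometryError("frame atom a must lie in the x > 0 half-plane")
        object.__setattr__(self, "coords", c)

    @classmethod
    def from_internal(cls, r_ab: float, r_bc: float, angle_abc_deg: float) -> "ReferenceFrame":
        """Build a frame from ideal internal coordinates.

        ``angle_abc_deg`` is the a-b-c bond angle; a tetrahedral center has
        109.47 degrees.
        """
        if r_ab <= 0 or r_bc <= 0:
            raise GeometryError("bond lengths must be positive")
        if not 0.0 < angle_abc_deg < 180.0:
            raise GeometryError("bond angle must lie strictly between 0 and 180 degrees")
        th = np.radians(angle_abc_deg)
        a = np.array([r_ab * np.sin(th), 0.0, r_ab * np.cos(th)])
        b = np.zeros(3)
        c = np.array([0.0, 0.0, r_bc])
        return cls(np.vstack([a, b, c]))

    @classmethod
    def from_quadruple(cls, quad_coords: np.ndarray) -> "ReferenceFrame":
        """Build the frame matching a quadruple's own a-b bond, b-c bond and
        a-b-c angle, so superposing that quadruple onto it is exact."""
        q = np.asarray(quad_coords, dtype=float)
        a, b, c = q[0], q[1], q[2]
        v_ab, v_cb = a - b, c - b
        r_ab, r_bc = np.linalg.norm(v_ab), np.linalg.norm(v_cb)
        if r_ab < _XY_EPS or r_bc < _XY_EPS:
            raise GeometryError("coincident frame atoms")
        cos_t = np.clip(np.dot(v_ab, v_cb) / (r_ab * r_bc), -1.0, 1.0)
        ang = np.degrees(np.arccos(cos_t))
        if ang < 1e-6 or ang > 180 - 1e-6:
            raise GeometryError("collinear a, b, c: dihedral undefined")
        return cls.from_internal(r_ab, r_bc, ang)


def superpose_quadruple(quad_coords: np.ndarray, frame: ReferenceFrame) -> np.ndarray:
    """Kabsch-superpose atoms a, b, c of a quadruple onto the frame and
    return the fourth atom's transformed position.

    The transform is the RMSD-minimizing proper rotation plus translation
    (no reflection).  When the quadruple's internal geometry matches the
    frame's, the superposition is exact and the fourth atom's
    ``atan2(y, x)`` equals the textbook signed dihedral of the quadruple.
    """
    q = np.asarray(quad_coords, dtype=float)
    if q.shape != (4, 3):
        raise GeometryError(f"expected 4x3 coordinates, got {q.shape}")
    p = q[:3]
    v1, v2 = p[0] - p[1], p[2] - p[1]
    cross = np.linalg.norm(np.cross(v1, v2))
    if cross < 1e-9 * max(np.linalg.norm(v1) * np.linalg.norm(v2), _XY_EPS):
        raise GeometryError("collinear a, b, c: dihedral undefined")
    p_cen = p.mean(axis=0)
    f_cen = frame.coords.mean(axis=0)
    rot, _ = Rotation.align_vectors(frame.coords - f_cen, p - p_cen)
    return rot.apply(q[3] - p_cen) + f_cen


def dihedral_from_point(p: Sequence[float], frame: ReferenceFrame | None = None) -> float:
    """Dihedral angle (degrees, in (-180, 180]) of a frame-space point.

    The canonical frame fixes the formula to ``atan2(y, x)``; the ``frame``
    argument is accepted for interface symmetry but does not change the
    result.
    """
    p = np.asarray(p, dtype=float)
    if np.hypot(p[0], p[1]) < _XY_EPS:
        raise GeometryError("point lies on the frame's Z axis: dihedral undefined")
    ang = float(np.degrees(np.arctan2(p[1], p[0])))
    return 180.0 if ang <= -180.0 else ang


def wrap_angle(a: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a <= -180.0 else a


def circular_difference(a: float, b: float) -> float:
    """Unsigned circular distance between two angles in degrees, in [0, 180]."""
    d = abs(a - b) % 360.0
    return 360.0 - d if d > 180.0 else d


@dataclass
class ChiSampleMatrix:
    """Per-conformer fourth-atom positions in the canonical frame.

    One row per conformer; columns grouped in chi order, three (x, y, z)
    per chi, so the row length is 3 * n_chi.
    """

    samples: np.ndarray  # (n_conformers, 3 * n_chi)
    chi_defs: Sequence["ChiDefinition"]
    frames: Sequence[ReferenceFrame] = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        n_chi = len(self.chi_defs)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3 * n_chi:
            raise ValueError(
                f"sample matrix must be (n, {3 * n_chi}) for {n_chi} chi angles, "
                f"got {self.samples.shape}")

    @property
    def n_conformers(self) -> int:
        return self.samples.shape[0]

    @property
    def n_chi(self) -> int:
        return len(self.chi_defs)

    def chi_block(self, chi_index: int) -> np.ndarray:
        """The (n, 3) Cartesian block for one chi (1-based index)."""
        k = chi_index - 1
        if not 0 <= k < self.n_chi:
            raise IndexError(f"chi index {chi_index} out of range 1..{self.n_chi}")
        return self.samples[:, 3 * k:3 * k + 3]

    def chi_angles(self, chi_index: int) -> np.ndarray:
        """Dihedral angles (degrees) of one chi for every conformer."""
        blk = self.chi_block(chi_index)
        return np.degrees(np.arctan2(blk[:, 1], blk[:, 0]))

    def to_csv(self, path) -> None:
        header = ",".join(f"chi{k+1}_{ax}" for k in range(self.n_chi) for ax in "xyz")
        np.savetxt(path, self.samples, delimiter=",", header=header, comments="")


def extract_chi_samples(ensemble: "ConformerEnsemble",
                        chi_defs: Sequence["ChiDefinition"],
                        frames: Sequence[ReferenceFrame] | None = None) -> ChiSampleMatrix:
    """Superpose every conformer's chi quadruples into the canonical frames.

    Frames default to the geometry of the first conformer's quadruples, so
    every conformer of the ensemble is measured against one fixed target
    (small internal-geometry jitter then shows up as sub-degree angular
    noise, which the mixture fit absorbs).
    """
    if not chi_defs:
        raise GeometryError("no chi definitions: nothing to extract")
    coords = ensemble.coordinates
    if not coords:
        raise GeometryError("empty ensemble")
    if frames is None:
        first = coords[0]
        frames = [ReferenceFrame.from_quadruple(first[list(cd.quadruple)])
                  for cd in chi_defs]
    n = len(coords)
    X = np.empty((n, 3 * len(chi_defs)))
    for r, xyz in enumerate(coords):
        for k, (cd, fr) in enumerate(zip(chi_defs, frames)):
            try:
                X[r, 3 * k:3 * k + 3] = superpose_quadruple(xyz[list(cd.quadruple)], fr)
            except GeometryError as exc:
                raise GeometryError(
                    f"conformer {r}, chi {cd.index}: {exc}") from exc
    return ChiSampleMatrix(samples=X, chi_defs=list(chi_defs), frames=list(frames))


def cartesian_peak_to_dihedral(mean: Sequence[float],
                               stds: Sequence[float],
                               frame: ReferenceFrame | None = None,
                               std_floor: float = STD_FLOOR_DEG) -> tuple[float, float]:
    """Convert one Gaussian peak's Cartesian (mean, per-axis std) to an
    angular (mean, std) pair in degrees.

    The angular mean is the dihedral of the Cartesian mean.  The angular
    std follows the one-sigma-ellipse construction: take the unit vector v
    in the XY plane orthogonal to the origin->mean XY direction, find t > 0
    with (t*vx/sx)^2 + (t*vy/sy)^2 = 1, and report the circular difference
    between the dihedral at mean_xy + t*v and the mean dihedral.  The Z
    components never enter.
    """
    mean = np.asarray(mean, dtype=float)
    stds = np.asarray(stds, dtype=float)
    if np.any(stds < 0):
        raise ValueError("standard deviations must be non-negative")
    mx, my = mean[0], mean[1]
    r = np.hypot(mx, my)
    if r < _XY_EPS:
        raise GeometryError("peak mean lies on the frame's Z axis: dihedral undefined")
    mean_angle = dihedral_from_point(mean)
    sx, sy = stds[0], stds[1]
    v = np.array([-my, mx]) / r  # tangential unit vector, +t root
    denom = (v[0] / sx) ** 2 + (v[1] / sy) ** 2 if sx > 0 and sy > 0 else np.inf
    if not np.isfinite(denom) or denom <= 0:
        logger.warning("degenerate XY std for peak at %.1f deg; applying %.1f deg floor",
                       mean_angle, std_floor)
        return mean_angle, std_floor
    t = 1.0 / np.sqrt(denom)
    edge = np.array([mx + t * v[0], my + t * v[1]])
    edge_angle = float(np.degrees(np.arctan2(edge[1], edge[0])))
    std = circular_difference(edge_angle, mean_angle)
    return mean_angle, max(std, std_floor)
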