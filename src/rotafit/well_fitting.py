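"""Bayesian Gaussian mixture fitting and rotamer-well assembly.

The full chi distribution is fitted in Cartesian space: every conformer
contributes a 3N-dimensional row (fourth-atom XYZ per chi), and a
Dirichlet-process Gaussian mixture with diagonal covariance is initialized
with 10^N components so superfluous components can shrink away.  Peaks
below the density threshold are discarded and the survivors renormalized.

Each chi is then binned independently with a one-dimensional mixture over
that chi's dihedral angles (recentered at the largest circular gap so no
cluster straddles the wrap-around seam).  Every surviving 3N-D peak is
assigned, chi by chi, to the nearest bin mean; peaks landing on the same
assignment vector are merged by a weight-proportional average of their
Cartesian means and variances, and the merged peaks become the final
rotamer wells.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import BayesianGaussianMixture

from .dihedral_geometry import (
    STD_FLOOR_DEG,
    ChiSampleMatrix,
    ReferenceFrame,
    cartesian_peak_to_dihedral,
    circular_difference,
    wrap_angle,
)
from .errors import EmptyLibraryError, FitError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CartesianPeak:
    """One fitted Gaussian component in 3N-dimensional Cartesian space."""

    mean: np.ndarray       # (3N,), Angstrom
    variances: np.ndarray  # (3N,), Angstrom^2, diagonal covariance
    weight: float

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "variances", np.asarray(self.variances, dtype=float))
        if self.mean.shape != self.variances.shape:
            raise ValueError("mean and variances must have the same shape")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be strictly positive")

    @property
    def n_chi(self) -> int:
        return self.mean.shape[0] // 3

    def chi_mean(self, k: int) -> np.ndarray:
        return self.mean[3 * k:3 * k + 3]

    def chi_stds(self, k: int) -> np.ndarray:
        return np.sqrt(self.variances[3 * k:3 * k + 3])


@dataclass(frozen=True)
class DihedralWell:
    """One rotamer well: per-chi angular mean/std plus its density."""

    chi_means: tuple[float, ...]   # degrees, each in (-180, 180]
    chi_stds: tuple[float, ...]    # degrees, > 0
    density: float                 # (0, 1]
    bin_assignment: tuple[int, ...]  # 1-based per-chi bin indices

    def __post_init__(self):
        if not (len(self.chi_means) == len(self.chi_stds) == len(self.bin_assignment)):
            raise ValueError("chi_means, chi_stds and bin_assignment lengths differ")
        if any(s <= 0 for s in self.chi_stds):
            raise ValueError("chi standard deviations must be positive")

    @property
    def n_chi(self) -> int:
        return len(self.chi_means)


@dataclass(frozen=True)
class ChiBin:
    """One per-chi bin: angular mean/std and the bin's own density."""

    mean: float
    std: float
    density: float


@dataclass
class FitConfig:
    """Mixture-fitting knobs.

    The initial component count for the full fit is
    ``init_peaks_exponent_base ** n_chi`` (capped by ``max_components_cap``
    and the sample count, which the sklearn backend requires); per-chi bin
    fits start from ``per_chi_components`` components.  ``density_threshold``
    is the minimum surviving peak weight.  All randomness flows from
    ``seed``.
    """

    seed: int = 0
    density_threshold: float = 0.005
    init_peaks_exponent_base: int = 10
    per_chi_components: int = 10
    covariance_mode: str = "diag"
    max_components_cap: int = 1000
    max_iter: int = 500
    per_chi_max_iter: int = 2000
    #: the 1-D marginal fits are restart-selected (best evidence lower
    #: bound) to escape split-cluster local optima of the EM ascent
    per_chi_n_init: int = 5
    per_chi_init: str = "random_from_data"
    tol: float = 1e-3
    reg_covar: float = 1e-6
    weight_concentration_prior: float | None = None
    n_retries: int = 3
    std_floor_deg: float = STD_FLOOR_DEG
    #: fit per-chi bins on the 3-D Cartesian fourth-atom samples instead of
    #: gap-recentered 1-D angles (angle space is the default).
    per_chi_cartesian: bool = False
    verbose_log: str | None = None

    def __post_init__(self):
        if not 0.0 < self.density_threshold < 1.0:
            raise ValueError("density_threshold must lie in (0, 1)")
        if self.init_peaks_exponent_base < 1:
            raise ValueError("initial components must be at least 1")
        if self.covariance_mode != "diag":
            raise ValueError("only diagonal covariance is supported")


def _fit_bgmm(X: np.ndarray, n_components: int, config: FitConfig,
              max_iter: int, n_init: int = 1,
              init_params: str = "kmeans") -> BayesianGaussianMixture:
    """Fit with retries on non-convergence, deterministically per seed."""
    last_exc: Exception | None = None
    for attempt in range(config.n_retries + 1):
        seed = (config.seed + 100_003 * attempt) % (2 ** 31)
        model = BayesianGaussianMixture(
            n_components=n_components,
            covariance_type="diag",
            weight_concentration_prior_type="dirichlet_process",
            weight_concentration_prior=config.weight_concentration_prior,
            random_state=seed,
            max_iter=max_iter,
            tol=config.tol,
            reg_covar=config.reg_covar,
            n_init=n_init,
            init_params=init_params,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            try:
                model.fit(X)
            except Exception as exc:  # numerical blow-up: retry with new seed
                last_exc = exc
                continue
        if model.converged_:
            if attempt:
                logger.info("mixture converged on retry %d", attempt)
            return model
        logger.warning("mixture did not converge (attempt %d)", attempt + 1)
    if last_exc is not None:
        raise FitError(f"mixture fitting failed: {last_exc}") from last_exc
    raise FitError(
        f"mixture fitting did not converge after {config.n_retries + 1} attempts")


def fit_cartesian_bgmm(samples: ChiSampleMatrix | np.ndarray,
                       config: FitConfig) -> list[CartesianPeak]:
    """Fit the 3N-dimensional Dirichlet-process mixture and return its
    components as :class:`CartesianPeak` objects (weights sum to 1)."""
    X = samples.samples if isinstance(samples, ChiSampleMatrix) else np.asarray(samples, float)
    if X.shape[0] < 2:
        raise FitError("need at least 2 samples to fit a mixture")
    n_chi = X.shape[1] // 3
    n_components = min(config.init_peaks_exponent_base ** n_chi,
                       config.max_components_cap,
                       X.shape[0])
    model = _fit_bgmm(X, n_components, config, config.max_iter)
    peaks = [CartesianPeak(mean=m, variances=v, weight=float(w))
             for m, v, w in zip(model.means_, model.covariances_, model.weights_)]
    if config.verbose_log:
        with open(config.verbose_log, "w") as fh:
            json.dump({"n_components_init": n_components,
                       "n_iter": int(model.n_iter_),
                       "weights": [p.weight for p in peaks]}, fh, indent=2)
    return peaks


def prune_peaks(peaks: Sequence[CartesianPeak],
                threshold: float) -> list[CartesianPeak]:
    """Drop peaks below the density threshold and renormalize survivors."""
    if not peaks:
        raise EmptyLibraryError("no peaks to prune")
    kept = [p for p in peaks if p.weight >= threshold]
    if not kept:
        raise EmptyLibraryError(
            f"all {len(peaks)} peaks fell below density {threshold}; "
            "try a lower threshold")
    total = sum(p.weight for p in kept)
    return [CartesianPeak(mean=p.mean, variances=p.variances, weight=p.weight / total)
            for p in kept]


def _recenter_angles(angles: np.ndarray) -> tuple[np.ndarray, float]:
    """Shift circular data so the cut point falls in the middle of the
    largest empty gap; returns (shifted angles in [0, 360), cut)."""
    s = np.sort(angles)
    gaps = np.diff(np.concatenate([s, s[:1] + 360.0]))
    i = int(np.argmax(gaps))
    cut = (s[i] + gaps[i] / 2.0) % 360.0
    return (angles - cut) % 360.0, cut


def fit_per_chi_bins(samples: ChiSampleMatrix,
                     chi_index: int,
                     config: FitConfig) -> list[ChiBin]:
    """Fit one chi's marginal distribution and return its bins sorted by
    ascending mean angle (bin indices are 1-based in that order).

    Default: a one-dimensional mixture over the chi's dihedral angles,
    recentered at the largest circular gap so no well straddles the
    +-180 seam.  With ``config.per_chi_cartesian`` the fit runs on the
    chi's 3-D fourth-atom samples instead and bins are converted through
    the one-sigma-ellipse construction.
    """
    threshold = config.density_threshold
    if config.per_chi_cartesian:
        X = samples.chi_block(chi_index)
        n_comp = min(config.per_chi_components, X.shape[0])
        model = _fit_bgmm(X, n_comp, config, config.per_chi_max_iter,
                          n_init=config.per_chi_n_init,
                          init_params=config.per_chi_init)
        frame = samples.frames[chi_index - 1] if samples.frames else None
        bins = []
        total = 0.0
        for m, v, w in zip(model.means_, model.covariances_, model.weights_):
            if w < threshold:
                continue
            ang, std = cartesian_peak_to_dihedral(m, np.sqrt(v), frame,
                                                  std_floor=config.std_floor_deg)
            bins.append(ChiBin(mean=ang, std=std, density=float(w)))
            total += w
    else:
        angles = samples.chi_angles(chi_index)
        shifted, cut = _recenter_angles(angles)
        n_comp = min(config.per_chi_components, shifted.shape[0])
        model = _fit_bgmm(shifted.reshape(-1, 1), n_comp, config,
                          config.per_chi_max_iter,
                          n_init=config.per_chi_n_init,
                          init_params=config.per_chi_init)
        bins = []
        total = 0.0
        for m, v, w in zip(model.means_[:, 0], model.covariances_[:, 0], model.weights_):
            if w < threshold:
                continue
            bins.append(ChiBin(mean=wrap_angle(m + cut),
                               std=max(float(np.sqrt(v)), config.std_floor_deg),
                               density=float(w)))
            total += w
    if not bins:
        raise EmptyLibraryError(f"no bins above density {threshold} for chi {chi_index}")
    bins = [ChiBin(mean=b.mean, std=b.std, density=b.density / total) for b in bins]
    return sorted(bins, key=lambda b: b.mean)


def _peak_chi_angle(peak: CartesianPeak, k: int) -> float:
    m = peak.chi_mean(k)
    return float(np.degrees(np.arctan2(m[1], m[0])))


def assign_and_merge(peaks: Sequence[CartesianPeak],
                     per_chi_bins: Sequence[Sequence[ChiBin]],
                     frames: Sequence[ReferenceFrame] | None = None,
                     std_floor: float = STD_FLOOR_DEG) -> list[DihedralWell]:
    """Assign every peak a per-chi bin and merge same-assignment peaks.

    Assignment is nearest-bin by circular distance per chi (ties go to the
    lower bin index).  Peaks sharing the full assignment vector merge via
    weight-proportional averages of Cartesian means and variances; the
    merged peaks are then converted to angular wells.  Output is sorted by
    descending density; densities sum to 1 when the input weights do.
    """
    if not peaks:
        raise EmptyLibraryError("no peaks to assign")
    n_chi = peaks[0].n_chi
    if len(per_chi_bins) != n_chi:
        raise ValueError("need one bin list per chi")
    if any(not b for b in per_chi_bins):
        raise EmptyLibraryError("empty bin list for some chi")

    groups: dict[tuple[int, ...], list[CartesianPeak]] = {}
    for p in peaks:
        key = []
        for k in range(n_chi):
            ang = _peak_chi_angle(p, k)
            dists = [circular_difference(ang, b.mean) for b in per_chi_bins[k]]
            key.append(int(np.argmin(dists)) + 1)  # argmin takes the first = lower index
        groups.setdefault(tuple(key), []).append(p)

    wells: list[DihedralWell] = []
    for key, members in groups.items():
        w = np.array([p.weight for p in members])
        total = w.sum()
        frac = w / total
        mean = np.einsum("i,ij->j", frac, np.stack([p.mean for p in members]))
        var = np.einsum("i,ij->j", frac, np.stack([p.variances for p in members]))
        chi_means, chi_stds = [], []
        for k in range(n_chi):
            frame = frames[k] if frames else None
            ang, std = cartesian_peak_to_dihedral(mean[3 * k:3 * k + 3],
                                                  np.sqrt(var[3 * k:3 * k + 3]),
                                                  frame, std_floor=std_floor)
            chi_means.append(ang)
            chi_stds.append(std)
        wells.append(DihedralWell(chi_means=tuple(chi_means),
                                  chi_stds=tuple(chi_stds),
                                  density=float(total),
                                  bin_assignment=key))
    return sorted(wells, key=lambda well: -well.density)


def fit_wells(samples: ChiSampleMatrix, config: FitConfig) -> tuple[
        list[DihedralWell], list[list[ChiBin]]]:
    """Full fitting stage: 3N-D mixture -> prune -> per-chi bins -> wells."""
    peaks = fit_cartesian_bgmm(samples, config)
    peaks = prune_peaks(peaks, config.density_threshold)
    bins = [fit_per_chi_bins(samples, k + 1, config) for k in range(samples.n_chi)]
    wells = assign_and_merge(peaks, bins, samples.frames or None,
                             std_floor=config.std_floor_deg)
    return wells, bins
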