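"""Synthetic inputs: voxel phantoms, fiber populations and load curves.

The study this package models acquired three kinds of raw data — 3-D
contrast-enhanced micro-CT volumes of a tensioned ligament bundle,
per-strain tables of segmented fiber geometry, and load-cell stress-strain
curves.  None of these are deposited, so this module generates all three
synthetically with known ground truth:

* :func:`generate_phantom` voxelises straight cylindrical fibers (bright)
  inside a non-fibrous matrix cylinder (slightly dimmer, reproducing the
  low fiber/matrix contrast of PTA-stained tissue) on a dark background,
  plus Gaussian noise, at the study's 9 um voxel size and 0-255 gray range;
* :func:`sample_fiber_population` draws per-fiber orientation/volume tables
  directly, and :func:`reorient_affine` advances them in strain with
  incompressible affine kinematics (``tan theta' = tan theta / lam**1.5``),
  the standard parameter-free stand-in for the fiber realignment observed
  under load;
* :func:`generate_load_curve` evaluates the recruitment model forward and
  optionally perturbs it with additive and/or multiplicative Gaussian noise.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    DEFAULT_LAMBDA_GRID,
    DEFAULT_N_THETA,
    DEFAULT_N_XI,
    LoadCurve,
    ModelParams,
    sigma_curve,
)
from .segmentation import VoxelVolume

__all__ = [
    "OrientationSampler",
    "orientation_sampler",
    "lognormal_volume_sampler",
    "PhantomConfig",
    "GroundTruthFiber",
    "BundleGeometry",
    "generate_phantom",
    "truth_label_volume",
    "match_labels",
    "sample_fiber_population",
    "reorient_affine",
    "generate_load_curve",
]

TRUTH_COLUMNS = [
    "fiber_id",
    "centroid_z_mm",
    "centroid_y_mm",
    "centroid_x_mm",
    "theta_true_deg",
    "phi_true_deg",
    "radius_mm",
    "length_mm",
    "volume_true_mm3",
    "n_voxels",
]


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrientationSampler:
    """Named distribution over (theta, phi) in degrees.

    ``sample(n, rng)`` returns ``(theta_deg, phi_deg)`` arrays with
    ``theta in [0, 90]`` and ``phi in [0, 180)``.
    """

    name: str
    params: dict
    _draw: Callable = field(repr=False, compare=False)

    def sample(self, n: int, rng: np.random.Generator):
        theta, phi = self._draw(n, rng)
        return np.asarray(theta, dtype=float), np.asarray(phi, dtype=float)


def orientation_sampler(name: str, **params) -> OrientationSampler:
    """Factory for the named orientation distributions.

    ``constant(theta_deg, phi_deg)`` — degenerate;
    ``uniform_solid_angle(theta_max_deg=90)`` — uniform over the spherical
    cap (theta drawn with the sin-theta density);
    ``truncated_normal(mean_deg, sd_deg)`` — theta from a normal truncated
    to [0, 90], phi uniform.
    """
    if name == "constant":
        th0 = float(params.get("theta_deg", 0.0))
        ph0 = float(params.get("phi_deg", 0.0))
        if not 0 <= th0 <= 90:
            raise ValueError("theta_deg must be in [0, 90]")

        def draw(n, rng):
            return np.full(n, th0), np.full(n, ph0 % 180.0)

    elif name == "uniform_solid_angle":
        tmax = float(params.get("theta_max_deg", 90.0))
        if not 0 < tmax <= 90:
            raise ValueError("theta_max_deg must be in (0, 90]")

        def draw(n, rng):
            u = rng.uniform(np.cos(np.radians(tmax)), 1.0, n)
            return np.degrees(np.arccos(u)), rng.uniform(0.0, 180.0, n)

    elif name == "truncated_normal":
        mean = float(params["mean_deg"])
        sd = float(params["sd_deg"])
        if sd <= 0:
            raise ValueError("sd_deg must be positive")

        def draw(n, rng):
            a, b = (0.0 - mean) / sd, (90.0 - mean) / sd
            th = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
            return th, rng.uniform(0.0, 180.0, n)

    else:
        raise ValueError(f"unknown orientation sampler {name!r}")
    return OrientationSampler(name, dict(params), draw)


def lognormal_volume_sampler(median_mm3: float = 1e-4, sigma: float = 0.8) -> Callable:
    """Right-skewed fiber volumes, as segmented fiber populations show."""
    if median_mm3 <= 0 or sigma <= 0:
        raise ValueError("median_mm3 and sigma must be positive")

    def draw(n, rng):
        return median_mm3 * np.exp(sigma * rng.standard_normal(n))

    return draw


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruthFiber:
    """Geometry of one generated fiber (truth for segmentation validation)."""

    fiber_id: int
    centroid_mm: tuple[float, float, float]  # (z, y, x), z = loading axis
    theta_true_deg: float
    phi_true_deg: float
    radius_mm: float
    length_mm: float

    @property
    def volume_true_mm3(self) -> float:
        return float(np.pi * self.radius_mm**2 * self.length_mm)

    @property
    def direction(self) -> np.ndarray:
        t = np.radians(self.theta_true_deg)
        p = np.radians(self.phi_true_deg)
        return np.array([np.cos(t), np.sin(t) * np.sin(p), np.sin(t) * np.cos(p)])


@dataclass(frozen=True)
class BundleGeometry:
    """Rest length, cross-section and volume of the tested bundle."""

    L0_mm: float
    A_tot_mm2: float

    def __post_init__(self) -> None:
        if self.L0_mm <= 0 or self.A_tot_mm2 <= 0:
            raise ValueError("bundle dimensions must be positive")

    def v_tot(self, lam: float = 1.0) -> float:
        """Current bundle volume ``A_tot * L0 * lam`` at stretch ``lam``."""
        if lam < 1:
            raise ValueError("lam must be >= 1")
        return self.A_tot_mm2 * self.L0_mm * lam


@dataclass(frozen=True)
class PhantomConfig:
    """Phantom geometry, contrast and noise.

    Defaults emulate the study's imaging conditions: 9 um voxels, 0-255
    gray levels with background near 0 and a matrix signal only somewhat
    below the fiber signal, fiber diameters around the ~111 um average
    thickness seen in the reconstructions, and fibers mostly aligned with
    the loading axis (axis 0 of the volume).
    """

    shape: tuple[int, int, int] = (256, 256, 256)
    voxel_size_mm: float = 0.009
    n_fibers: int = 20
    radius_range_mm: tuple[float, float] = (0.035, 0.055)
    length_range_mm: tuple[float, float] = (1.5, 1.9)
    orientation: OrientationSampler = field(
        default_factory=lambda: orientation_sampler(
            "truncated_normal", mean_deg=10.0, sd_deg=6.0
        )
    )
    intensity_background: float = 5.0
    intensity_matrix: float = 150.0
    intensity_fiber: float = 200.0
    noise_sd: float = 5.0
    matrix_radius_fraction: float | None = 0.45
    avoid_overlap: bool = False
    min_separation_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be >= 0")
        if not (
            self.intensity_fiber > self.intensity_matrix > self.intensity_background
        ):
            raise ValueError(
                "intensities must satisfy fiber > matrix > background"
            )
        if self.radius_range_mm[0] <= 0 or self.radius_range_mm[1] < self.radius_range_mm[0]:
            raise ValueError("invalid radius_range_mm")
        if self.length_range_mm[0] <= 0 or self.length_range_mm[1] < self.length_range_mm[0]:
            raise ValueError("invalid length_range_mm")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def replace(self, **kwargs) -> "PhantomConfig":
        return replace(self, **kwargs)


def _rasterize(
    fiber: GroundTruthFiber, shape, voxel_size: float
) -> tuple[tuple[slice, ...], np.ndarray]:
    """Bounding-box slice and inside-mask of a finite cylinder."""
    c = np.asarray(fiber.centroid_mm)
    d = fiber.direction
    half = np.abs(d) * fiber.length_mm / 2 + fiber.radius_mm + 2 * voxel_size
    lo = np.maximum(np.floor((c - half) / voxel_size).astype(int), 0)
    hi = np.minimum(np.ceil((c + half) / voxel_size).astype(int) + 1, shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
    pts = (np.stack(grids, axis=-1) + 0.5) * voxel_size - c
    t = pts @ d
    perp2 = np.einsum("...i,...i", pts, pts) - t * t
    inside = (perp2 <= fiber.radius_mm**2) & (np.abs(t) <= fiber.length_mm / 2)
    return sl, inside


def _segment_distance(c1, d1, l1, c2, d2, l2, n: int = 33) -> float:
    """Approximate min distance between two fiber axes (sampled)."""
    t = np.linspace(-0.5, 0.5, n)
    p1 = c1[None, :] + np.outer(t * l1, d1)
    p2 = c2[None, :] + np.outer(t * l2, d2)
    return float(np.min(np.linalg.norm(p1[:, None] - p2[None, :], axis=2)))


def _matrix_geometry(config: PhantomConfig):
    """Centre (y, x) and radius of the matrix cylinder, in mm."""
    ny, nx = config.shape[1], config.shape[2]
    centre = np.array([ny / 2, nx / 2]) * config.voxel_size_mm
    radius = config.matrix_radius_fraction * min(ny, nx) * config.voxel_size_mm
    return centre, radius


def _inside_matrix(fiber: GroundTruthFiber, centre, radius) -> bool:
    """Both endpoints (plus the fiber radius) within the matrix cylinder."""
    c = np.asarray(fiber.centroid_mm)
    d = fiber.direction
    for sign in (-1.0, 1.0):
        end = c + sign * d * fiber.length_mm / 2
        if np.hypot(end[1] - centre[0], end[2] - centre[1]) + fiber.radius_mm > radius:
            return False
    return True


def _place_fibers(config: PhantomConfig, rng: np.random.Generator):
    extent = np.asarray(config.shape) * config.voxel_size_mm
    diagonal = float(np.linalg.norm(extent))
    matrix = (
        _matrix_geometry(config) if config.matrix_radius_fraction is not None else None
    )
    fibers: list[GroundTruthFiber] = []
    max_tries = 200 * max(config.n_fibers, 1)
    tries = 0
    while len(fibers) < config.n_fibers:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {config.n_fibers} fibers in {max_tries} tries "
                "(volume too crowded for the requested separation)"
            )
        tries += 1
        theta, phi = config.orientation.sample(1, rng)
        radius = rng.uniform(*config.radius_range_mm)
        length = rng.uniform(*config.length_range_mm)
        if radius <= 0:
            raise ValueError("fiber radius must be positive")
        if length > diagonal:
            raise ValueError(
                f"fiber length {length} mm exceeds the volume diagonal {diagonal:.3f} mm"
            )
        cand = GroundTruthFiber(
            fiber_id=len(fibers) + 1,
            centroid_mm=(0.0, 0.0, 0.0),
            theta_true_deg=float(theta[0]),
            phi_true_deg=float(phi[0]),
            radius_mm=radius,
            length_mm=length,
        )
        d = cand.direction
        margin = np.abs(d) * length / 2 + radius
        if np.any(extent - 2 * margin <= 0):
            continue  # does not fit at this orientation; redraw
        centre = rng.uniform(margin, extent - margin)
        cand = replace(cand, centroid_mm=tuple(centre))
        # fibers belong to the bundle: keep them inside the matrix cylinder
        if matrix is not None and not _inside_matrix(cand, *matrix):
            continue
        if config.avoid_overlap:
            ok = True
            for other in fibers:
                dmin = _segment_distance(
                    centre, d, length,
                    np.asarray(other.centroid_mm), other.direction, other.length_mm,
                )
                if dmin < radius + other.radius_mm + config.min_separation_mm:
                    ok = False
                    break
            if not ok:
                continue
        fibers.append(cand)
    return fibers


def generate_phantom(config: PhantomConfig):
    """Voxelise the phantom; returns ``(volume, truth_table)``.

    The truth table (one row per fiber) carries the generating geometry and
    the realised voxel count; ``truth.attrs['overlap_fraction']`` reports
    the fraction of fiber voxels claimed by more than one fiber (fibers may
    overlap unless ``config.avoid_overlap``).  Identical seeds give
    bit-identical volumes.
    """
    rng = np.random.default_rng(config.seed)
    fibers = _place_fibers(config, rng)
    vol = np.full(config.shape, config.intensity_background, dtype=np.float64)
    if config.matrix_radius_fraction is not None:
        ny, nx = config.shape[1], config.shape[2]
        yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        ry = (yy - ny / 2 + 0.5) * config.voxel_size_mm
        rx = (xx - nx / 2 + 0.5) * config.voxel_size_mm
        r_matrix = config.matrix_radius_fraction * min(ny, nx) * config.voxel_size_mm
        vol[:, np.hypot(ry, rx) <= r_matrix] = config.intensity_matrix
    claimed = np.zeros(config.shape, dtype=np.uint8)
    counts = []
    for fiber in fibers:
        sl, inside = _rasterize(fiber, config.shape, config.voxel_size_mm)
        vol[sl][inside] = config.intensity_fiber
        claimed[sl][inside] += 1
        counts.append(int(inside.sum()))
    overlap = float((claimed > 1).sum() / (claimed > 0).sum()) if fibers else 0.0
    if config.noise_sd > 0:
        vol += rng.normal(0.0, config.noise_sd, size=config.shape)
    truth = pd.DataFrame(
        {
            "fiber_id": [f.fiber_id for f in fibers],
            "centroid_z_mm": [f.centroid_mm[0] for f in fibers],
            "centroid_y_mm": [f.centroid_mm[1] for f in fibers],
            "centroid_x_mm": [f.centroid_mm[2] for f in fibers],
            "theta_true_deg": [f.theta_true_deg for f in fibers],
            "phi_true_deg": [f.phi_true_deg for f in fibers],
            "radius_mm": [f.radius_mm for f in fibers],
            "length_mm": [f.length_mm for f in fibers],
            "volume_true_mm3": [f.volume_true_mm3 for f in fibers],
            "n_voxels": counts,
        },
        columns=TRUTH_COLUMNS,
    )
    truth.attrs["overlap_fraction"] = overlap
    truth.attrs["seed"] = config.seed
    return VoxelVolume(vol, config.voxel_size_mm, loading_axis=0), truth


def truth_label_volume(
    truth: pd.DataFrame, shape: Sequence[int], voxel_size_mm: float
) -> np.ndarray:
    """Re-rasterise the truth table into a label volume (later fibers win)."""
    labels = np.zeros(tuple(shape), dtype=np.uint16)
    for row in truth.itertuples(index=False):
        fiber = GroundTruthFiber(
            fiber_id=int(row.fiber_id),
            centroid_mm=(row.centroid_z_mm, row.centroid_y_mm, row.centroid_x_mm),
            theta_true_deg=row.theta_true_deg,
            phi_true_deg=row.phi_true_deg,
            radius_mm=row.radius_mm,
            length_mm=row.length_mm,
        )
        sl, inside = _rasterize(fiber, tuple(shape), voxel_size_mm)
        labels[sl][inside] = fiber.fiber_id
    return labels


def match_labels(truth_labels: np.ndarray, predicted: np.ndarray) -> pd.DataFrame:
    """Best-overlap match of each truth fiber to a predicted label.

    Returns one row per truth fiber: the predicted label with the largest
    voxel overlap (0 if none), overlap size, and both object sizes.  Callers
    decide on one-to-one acceptance from the overlap columns.
    """
    if truth_labels.shape != predicted.shape:
        raise ValueError("label volumes must share a shape")
    mask = truth_labels > 0
    t = truth_labels[mask].astype(np.int64)
    p = predicted[mask].astype(np.int64)
    n_pred = int(predicted.max()) + 1
    pair_counts = np.bincount(t * n_pred + p, minlength=(t.max() + 1) * n_pred)
    pair_counts = pair_counts.reshape(-1, n_pred)
    pred_sizes = np.bincount(predicted.ravel(), minlength=n_pred)
    rows = []
    for tid in np.unique(t):
        overlaps = pair_counts[tid].copy()
        overlaps[0] = 0  # background does not count as a match
        best = int(overlaps.argmax())
        rows.append(
            {
                "fiber_id": int(tid),
                "matched_label": best,
                "overlap_voxels": int(overlaps[best]),
                "truth_voxels": int(pair_counts[tid].sum()),
                "pred_voxels": int(pred_sizes[best]) if best else 0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fiber populations and strain series
# ---------------------------------------------------------------------------

def sample_fiber_population(
    n: int,
    orientation: OrientationSampler,
    volume_sampler: Callable | None = None,
    seed: int | None = None,
    fiber_length_mm: float = 1.0,
) -> pd.DataFrame:
    """Draw a per-fiber table of orientations, volumes and areas.

    ``mean_cross_area_mm2`` is derived as volume / fiber length, with a
    single nominal length for the population.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if fiber_length_mm <= 0:
        raise ValueError("fiber_length_mm must be positive")
    rng = np.random.default_rng(seed)
    theta, phi = orientation.sample(n, rng)
    if np.any(theta < 0) or np.any(theta > 90):
        raise ValueError("orientation sampler produced theta outside [0, 90]")
    if volume_sampler is None:
        volume_sampler = lognormal_volume_sampler()
    volumes = np.asarray(volume_sampler(n, rng), dtype=float)
    if np.any(volumes <= 0):
        raise ValueError("volume sampler produced non-positive volumes")
    return pd.DataFrame(
        {
            "theta_deg": theta,
            "phi_deg": phi % 180.0,
            "volume_mm3": volumes,
            "mean_cross_area_mm2": volumes / fiber_length_mm,
        }
    )


def reorient_affine(table: pd.DataFrame, lam: float) -> pd.DataFrame:
    """Affine incompressible reorientation: ``tan theta' = tan theta / lam**1.5``.

    The loading axis is a fixed point, transverse fibers (theta = 90) stay
    transverse, and theta decreases monotonically with stretch — the
    alignment trend real fiber populations show.  Azimuths and volumes are
    unchanged.
    """
    if lam < 1:
        raise ValueError(f"stretch ratio must be >= 1, got {lam}")
    out = table.copy()
    if lam == 1:
        return out
    th = np.radians(table["theta_deg"].to_numpy(dtype=float))
    out["theta_deg"] = np.degrees(np.arctan2(np.sin(th), lam**1.5 * np.cos(th)))
    return out


# ---------------------------------------------------------------------------
# load curves
# ---------------------------------------------------------------------------

def generate_load_curve(
    params: ModelParams,
    P: Callable | None = None,
    nu: Callable | None = None,
    lam_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    noise_sd: float = 0.0,
    rel_noise_sd: float = 0.0,
    seed: int | None = None,
    n_theta: int = DEFAULT_N_THETA,
    n_xi: int = DEFAULT_N_XI,
) -> LoadCurve:
    """Forward-model stress curve with optional Gaussian noise.

    ``noise_sd`` is additive (MPa); ``rel_noise_sd`` is multiplicative
    (fraction of each stress value).  With both zero the curve equals
    :func:`ligafib.model.sigma_curve` exactly at every grid point.
    """
    if noise_sd < 0 or rel_noise_sd < 0:
        raise ValueError("noise levels must be >= 0")
    curve = sigma_curve(lam_grid, params, P, nu, n_theta=n_theta, n_xi=n_xi)
    stress = curve.stress
    if noise_sd > 0 or rel_noise_sd > 0:
        rng = np.random.default_rng(seed)
        stress = stress * (1.0 + rel_noise_sd * rng.standard_normal(len(stress)))
        stress = stress + noise_sd * rng.standard_normal(len(stress))
    return LoadCurve(curve.lam, stress)
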