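"""Empirical orientation and volume-fraction distributions.

Per-strain fiber tables (one row per segmented fiber, with inclination
``theta`` to the loading axis, transverse azimuth ``phi``, volume and mean
cross-sectional area) are converted into the two empirical inputs of the
constitutive model:

* ``P(theta; lam)`` — orientation density per steradian on a theta-bin
  grid, normalised so that ``2*pi * sum_i P_i sin(theta_i) dtheta_i = 1``
  (azimuthal symmetry is assumed, hence the ``2*pi``);
* ``nu(theta; lam)`` — fiber volume per bin divided by the bundle volume
  ``V_tot = A_tot * L0 * lam``.

Summary statistics mirror the ones reported for the two study specimens:
per-strain skewness of the theta and volume distributions, fiber counts and
their coefficient of variation across strain levels, and the fraction of
segmented objects retained as fibers.

Fiber tables are plain :class:`pandas.DataFrame` objects with columns
``theta_deg``, ``phi_deg``, ``volume_mm3`` and (optionally)
``mean_cross_area_mm2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "default_theta_edges",
    "AngularDistribution",
    "VolumeFractionMap",
    "SummaryStats",
    "build_angular_distribution",
    "build_volume_fraction",
    "skewness",
    "count_stats",
    "angular_density_family",
    "volume_fraction_family",
]

_NORM_TOL = 1e-6


def default_theta_edges(n_bins: int = 9) -> np.ndarray:
    """Equal-width theta bins over [0, 90] degrees."""
    return np.linspace(0.0, 90.0, n_bins + 1)


def _check_edges(edges: np.ndarray) -> np.ndarray:
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("theta_edges_deg must be strictly increasing, length >= 2")
    if edges[0] < 0 or edges[-1] > 90:
        raise ValueError("theta bins must lie within [0, 90] degrees")
    return edges


def _solid_angle_weights(edges_deg: np.ndarray) -> np.ndarray:
    """2*pi * sin(theta_mid) * dtheta (radians) per bin."""
    e = np.radians(edges_deg)
    mid = 0.5 * (e[:-1] + e[1:])
    return 2.0 * np.pi * np.sin(mid) * np.diff(e)


@dataclass
class AngularDistribution:
    """Orientation density P(theta) at one stretch level.

    ``density`` is per steradian on the given bins; the constructor enforces
    the hemisphere normalisation.
    """

    theta_edges_deg: np.ndarray
    density: np.ndarray
    lam: float = 1.0

    def __post_init__(self) -> None:
        self.theta_edges_deg = _check_edges(self.theta_edges_deg)
        self.density = np.asarray(self.density, dtype=float)
        if self.density.shape != (len(self.theta_edges_deg) - 1,):
            raise ValueError("density must have one value per theta bin")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        if self.lam < 1:
            raise ValueError("lam must be >= 1")
        total = float(self.density @ _solid_angle_weights(self.theta_edges_deg))
        if abs(total - 1.0) > _NORM_TOL:
            raise ValueError(
                f"angular distribution not normalised: solid-angle mass {total!r}"
            )

    @property
    def theta_mid_deg(self) -> np.ndarray:
        return 0.5 * (self.theta_edges_deg[:-1] + self.theta_edges_deg[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "theta_lo_deg": self.theta_edges_deg[:-1],
                "theta_hi_deg": self.theta_edges_deg[1:],
                "P_per_sr": self.density,
            }
        )


@dataclass
class VolumeFractionMap:
    """Per-bin fiber volume fraction nu(theta) at one stretch level."""

    theta_edges_deg: np.ndarray
    nu: np.ndarray
    lam: float = 1.0
    v_tot: float = 1.0

    def __post_init__(self) -> None:
        self.theta_edges_deg = _check_edges(self.theta_edges_deg)
        self.nu = np.asarray(self.nu, dtype=float)
        if self.nu.shape != (len(self.theta_edges_deg) - 1,):
            raise ValueError("nu must have one value per theta bin")
        if np.any(self.nu < 0):
            raise ValueError("nu must be non-negative")
        if self.v_tot <= 0:
            raise ValueError("v_tot must be positive")
        if self.nu.sum() > 1.0 + 1e-9:
            raise ValueError("total volume fraction exceeds 1")

    @property
    def theta_mid_deg(self) -> np.ndarray:
        return 0.5 * (self.theta_edges_deg[:-1] + self.theta_edges_deg[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "theta_lo_deg": self.theta_edges_deg[:-1],
                "theta_hi_deg": self.theta_edges_deg[1:],
                "nu": self.nu,
            }
        )


def _bin_thetas(theta_deg: np.ndarray, edges: np.ndarray) -> np.ndarray:
    counts, _ = np.histogram(theta_deg, bins=edges)
    return counts


def build_angular_distribution(
    table: pd.DataFrame,
    theta_edges_deg: Sequence[float] | None = None,
    lam: float = 1.0,
) -> AngularDistribution:
    """Histogram fiber inclinations into a normalised orientation density.

    Each bin's density is ``(count/N) / (2*pi*sin(theta_mid)*dtheta)`` so the
    discrete hemisphere normalisation holds exactly by construction.
    """
    if len(table) == 0:
        raise ValueError("cannot build an angular distribution from an empty table")
    edges = _check_edges(
        default_theta_edges() if theta_edges_deg is None else np.asarray(theta_edges_deg)
    )
    theta = table["theta_deg"].to_numpy(dtype=float)
    if np.any(theta < edges[0]) or np.any(theta > edges[-1]):
        raise ValueError("theta values outside the bin range")
    counts = _bin_thetas(theta, edges)
    density = counts / counts.sum() / _solid_angle_weights(edges)
    return AngularDistribution(edges, density, lam)


def build_volume_fraction(
    table: pd.DataFrame,
    v_tot: float,
    theta_edges_deg: Sequence[float] | None = None,
    lam: float = 1.0,
) -> VolumeFractionMap:
    """Per-bin fiber volume divided by the bundle volume ``v_tot``."""
    edges = _check_edges(
        default_theta_edges() if theta_edges_deg is None else np.asarray(theta_edges_deg)
    )
    theta = table["theta_deg"].to_numpy(dtype=float)
    vol = table["volume_mm3"].to_numpy(dtype=float)
    if v_tot < vol.sum():
        raise ValueError(
            f"v_tot ({v_tot}) is smaller than the total fiber volume ({vol.sum()})"
        )
    nu, _ = np.histogram(theta, bins=edges, weights=vol)
    return VolumeFractionMap(edges, nu / v_tot, lam, v_tot)


def skewness(values, adjusted: bool = False) -> float:
    """Fisher-Pearson moment coefficient of skewness g1 = m3 / m2**1.5.

    ``adjusted=True`` returns the sample-size-corrected G1 instead.  Raises
    for fewer than three values or a constant sample.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("skewness requires at least 3 values")
    if np.std(x) == 0:
        raise ValueError("skewness is undefined for a constant sample")
    return float(stats.skew(x, bias=not adjusted))


@dataclass
class SummaryStats:
    """Per-strain fiber statistics across a strain series."""

    lam_levels: np.ndarray
    fiber_counts: np.ndarray
    count_cv: float
    theta_skewness: np.ndarray
    volume_skewness: np.ndarray
    fiber_fraction: float | None = None

    def to_dict(self) -> dict:
        d = {
            "lam_levels": list(map(float, self.lam_levels)),
            "fiber_counts": list(map(int, self.fiber_counts)),
            "count_cv": float(self.count_cv),
            "theta_skewness": list(map(float, self.theta_skewness)),
            "volume_skewness": list(map(float, self.volume_skewness)),
        }
        if self.fiber_fraction is not None:
            d["fiber_fraction"] = float(self.fiber_fraction)
        return d


def count_stats(
    tables: Mapping[float, pd.DataFrame],
    artifact_counts: Mapping[float, int] | None = None,
) -> SummaryStats:
    """Counts, count CV and skewness summaries across strain levels.

    ``tables`` maps stretch level -> fiber table (artifacts already
    excluded).  The coefficient of variation uses the sample standard
    deviation (ddof=1).  If per-level artifact counts are supplied, the
    pooled fiber fraction fibers/(fibers+artifacts) is reported too.
    """
    if len(tables) < 2:
        raise ValueError("count_stats requires at least two strain levels")
    lams = np.array(sorted(tables))
    counts = np.array([len(tables[l]) for l in lams])
    cv = float(np.std(counts, ddof=1) / np.mean(counts)) if np.mean(counts) else 0.0
    th_skew = np.array(
        [skewness(tables[l]["theta_deg"].to_numpy()) for l in lams]
    )
    vol_skew = np.array(
        [skewness(tables[l]["volume_mm3"].to_numpy()) for l in lams]
    )
    fraction = None
    if artifact_counts is not None:
        n_fib = int(counts.sum())
        n_art = int(sum(artifact_counts.get(l, 0) for l in lams))
        fraction = n_fib / (n_fib + n_art) if (n_fib + n_art) else None
    return SummaryStats(lams, counts, cv, th_skew, vol_skew, fraction)


# ---------------------------------------------------------------------------
# strain-interpolated families for the stress integral
# ---------------------------------------------------------------------------

class _StrainFamily:
    """Bin-constant in theta, piecewise-linear in the recruitment stretch.

    Between measured stretch levels the per-bin values are interpolated
    linearly; outside the measured range they are held constant (the
    protocol gives no information beyond the scanned strain window).
    """

    def __init__(self, edges_deg: np.ndarray, lams: np.ndarray, values: np.ndarray):
        self.edges_rad = np.radians(edges_deg)
        self.lams = lams
        self.values = values  # (n_levels, n_bins)

    def _eval(self, theta_rad, xi):
        theta_rad, xi = np.broadcast_arrays(
            np.asarray(theta_rad, dtype=float), np.asarray(xi, dtype=float)
        )
        bins = np.clip(
            np.searchsorted(self.edges_rad, theta_rad, side="right") - 1,
            0,
            len(self.edges_rad) - 2,
        )
        if len(self.lams) == 1:
            return self.values[0, bins]
        x = np.clip(xi, self.lams[0], self.lams[-1])
        j = np.clip(
            np.searchsorted(self.lams, x, side="right") - 1, 0, len(self.lams) - 2
        )
        w = (x - self.lams[j]) / (self.lams[j + 1] - self.lams[j])
        return self.values[j, bins] * (1.0 - w) + self.values[j + 1, bins] * w


def _stack_levels(items, attr: str):
    lams = np.array([it.lam for it in items])
    order = np.argsort(lams)
    lams = lams[order]
    if len(np.unique(lams)) != len(lams):
        raise ValueError("duplicate stretch levels")
    edges = items[order[0]].theta_edges_deg
    for i in order:
        if not np.array_equal(items[i].theta_edges_deg, edges):
            raise ValueError("all levels must share the same theta bins")
    values = np.stack([getattr(items[i], attr) for i in order])
    return edges, lams, values


def angular_density_family(
    distributions: Sequence[AngularDistribution],
) -> Callable:
    """Callable ``P(theta_rad, xi)`` built from per-stretch histograms."""
    edges, lams, values = _stack_levels(list(distributions), "density")
    fam = _StrainFamily(edges, lams, values)

    def P(theta_rad, xi):
        return fam._eval(theta_rad, xi)

    P.__name__ = "angular_density_family"
    return P


def volume_fraction_family(maps: Sequence[VolumeFractionMap]) -> Callable:
    """Callable ``nu(xi, theta_rad)`` built from per-stretch maps."""
    edges, lams, values = _stack_levels(list(maps), "nu")
    fam = _StrainFamily(edges, lams, values)

    def nu(xi, theta_rad):
        return fam._eval(theta_rad, xi)

    nu.__name__ = "volume_fraction_family"
    return nu
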