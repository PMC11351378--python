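"""Probabilistic fiber-recruitment constitutive model.

A ligament bundle is modelled as ``N0`` fibers that engage progressively as
the bundle is stretched.  The stretch at which a fiber becomes taut (its
*recruitment stretch* ``xi``) is a random variable with a Weibull density

    R(xi) = (beta/delta) * ((xi-gamma)/delta)**(beta-1)
            * exp(-((xi-gamma)/delta)**beta),      xi > gamma,

where ``beta`` (shape) controls the structure of recruitment (``beta < 1``:
many fibers recruited immediately, monotone decreasing rate; ``beta > 1``:
rate rises to an interior maximum), ``delta`` (scale) sets the spread of
recruitment stretches and ``gamma`` is the onset stretch (1 = rest length).

Each fiber is inclined at an angle ``theta`` to the loading axis, so its
axial stretch at bundle stretch ``lambda`` is ``lambda*cos(theta)``.  With a
linear single-fiber stress law of modulus ``E_f``, the engineering stress of
the bundle is the orientation- and recruitment-weighted integral

    sigma(lam) = 2*pi*N0*E_f * int_0^{pi/2} int_{max(1,gamma)}^{lam cos th}
                 R(xi) P(theta, xi) (lam cos th - xi) nu(xi, theta)
                 cos^2 th sin th  dxi dtheta,

with the inner integral empty whenever ``lam*cos(theta) <= max(1, gamma)``.
``P`` is the orientation density over the hemisphere (normalised with the
``sin(theta)`` solid-angle factor) and ``nu`` the volume fraction occupied by
fibers of that orientation; both may depend on the recruitment stretch to
express reorientation under load.

Only the product ``N0*E_f`` is identifiable from a stress-strain curve, so
``N0`` defaults to 1 and the fitted modulus is an effective fiber modulus.

The double integral is evaluated by composite trapezoid quadrature on
uniform grids (181 theta-nodes x 401 xi-nodes by default).  The lower
xi-node of each inner panel is shifted a quarter-step into the support so
that the integrable edge singularity of the Weibull density at
``xi -> gamma+`` for ``beta < 1`` is never evaluated at the singular point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "ModelParams",
    "RecruitmentDistribution",
    "LoadCurve",
    "weibull_density",
    "weibull_mode",
    "uniform_orientation_density",
    "constant_volume_fraction",
    "QuadraturePlan",
    "sigma",
    "sigma_curve",
]

#: Stretch levels at which the study protocol acquired data
#: (engineering strains 0, 1, 2, 3, 4, 6 and 8 %).
DEFAULT_LAMBDA_GRID: tuple[float, ...] = (1.00, 1.01, 1.02, 1.03, 1.04, 1.06, 1.08)

# Default quadrature resolution for the stress integral.
DEFAULT_N_THETA = 181
DEFAULT_N_XI = 401


# ---------------------------------------------------------------------------
# parameters and recruitment density
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParams:
    """Parameters of the recruitment model.

    Attributes
    ----------
    E_f : float
        Effective fiber Young's modulus in MPa (>= 0).
    beta : float
        Weibull shape parameter (> 0), dimensionless.
    delta : float
        Weibull scale parameter (> 0), in stretch units.
    gamma : float
        Recruitment onset stretch (>= 1).  Fibers cannot be recruited below
        the rest length, so the default is 1.
    N0 : float
        Fiber count scale (> 0).  Only ``N0*E_f`` is identifiable.
    """

    E_f: float
    beta: float
    delta: float
    gamma: float = 1.0
    N0: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.E_f, self.beta, self.delta, self.gamma, self.N0]).all():
            raise ValueError("model parameters must be finite")
        if self.E_f < 0:
            raise ValueError(f"E_f must be >= 0, got {self.E_f}")
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if self.gamma < 1:
            raise ValueError(f"gamma must be >= 1, got {self.gamma}")
        if self.N0 <= 0:
            raise ValueError(f"N0 must be > 0, got {self.N0}")

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "E_f_MPa": self.E_f,
            "beta": self.beta,
            "delta": self.delta,
            "gamma": self.gamma,
            "N0": self.N0,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(
            E_f=float(d["E_f_MPa"]),
            beta=float(d["beta"]),
            delta=float(d["delta"]),
            gamma=float(d.get("gamma", 1.0)),
            N0=float(d.get("N0", 1.0)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def weibull_density(xi, params: ModelParams):
    """Recruitment density R(xi); zero at and below the onset stretch.

    Vectorised over ``xi``; scalar input returns a float.
    """
    xi_arr = np.asarray(xi, dtype=float)
    u = (xi_arr - params.gamma) / params.delta
    out = np.zeros_like(u)
    pos = u > 0
    up = u[pos]
    out[pos] = (params.beta / params.delta) * up ** (params.beta - 1.0) * np.exp(
        -(up ** params.beta)
    )
    if np.isscalar(xi) or xi_arr.ndim == 0:
        return float(out)
    return out


def weibull_mode(params: ModelParams) -> float:
    """Location of the density maximum: gamma + delta*((beta-1)/beta)**(1/beta).

    For ``beta <= 1`` the density is decreasing on its support and the mode
    collapses onto the onset stretch ``gamma``.
    """
    if params.beta <= 1:
        return params.gamma
    return params.gamma + params.delta * ((params.beta - 1) / params.beta) ** (
        1.0 / params.beta
    )


@dataclass(frozen=True)
class RecruitmentDistribution:
    """Evaluable Weibull recruitment distribution."""

    params: ModelParams

    def pdf(self, xi):
        return weibull_density(xi, self.params)

    def cdf(self, xi):
        xi_arr = np.asarray(xi, dtype=float)
        u = np.clip((xi_arr - self.params.gamma) / self.params.delta, 0.0, None)
        out = 1.0 - np.exp(-(u ** self.params.beta))
        return float(out) if np.isscalar(xi) else out

    def mode(self) -> float:
        return weibull_mode(self.params)

    def normalization(self) -> float:
        """Quadrature of the density over its support (should be 1)."""
        from scipy.integrate import quad

        upper = self.params.gamma + 20.0 * self.params.delta
        val, _ = quad(self.pdf, self.params.gamma, upper, limit=200)
        return val


# ---------------------------------------------------------------------------
# load curves
# ---------------------------------------------------------------------------

@dataclass
class LoadCurve:
    """Paired stretch / engineering-stress samples.

    ``lam`` is the stretch ratio L/L0 (dimensionless, >= 1, ascending) and
    ``stress`` the engineering stress F/A_tot in MPa.
    """

    lam: np.ndarray
    stress: np.ndarray

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.lam.shape != self.stress.shape or self.lam.ndim != 1:
            raise ValueError("lam and stress must be equal-length 1-D arrays")
        if np.any(np.diff(self.lam) < 0):
            raise ValueError("lam must be sorted ascending")
        if np.any(self.lam < 1):
            raise ValueError("stretch ratios must be >= 1")

    def __len__(self) -> int:
        return len(self.lam)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"lambda": self.lam, "stress_MPa": self.stress}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "LoadCurve":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["lambda"].to_numpy(), df["stress_MPa"].to_numpy())


# ---------------------------------------------------------------------------
# orientation inputs
# ---------------------------------------------------------------------------

def uniform_orientation_density() -> Callable:
    """Orientation density of fibers uniform over the hemisphere.

    Constant ``P = 1/(2*pi)`` per steradian, so that
    ``int_0^{2pi} int_0^{pi/2} P sin(theta) dtheta dphi = 1``.
    """

    def P(theta_rad, xi):
        return np.broadcast_arrays(
            np.full_like(np.asarray(theta_rad, dtype=float), 1.0 / (2.0 * np.pi)),
            np.asarray(xi, dtype=float),
        )[0]

    P.__name__ = "uniform_orientation_density"
    return P


def constant_volume_fraction(value: float = 1.0) -> Callable:
    """Volume fraction independent of orientation and strain."""
    if value < 0:
        raise ValueError("volume fraction must be >= 0")

    def nu(xi, theta_rad):
        return np.broadcast_arrays(
            np.full_like(np.asarray(xi, dtype=float), float(value)),
            np.asarray(theta_rad, dtype=float),
        )[0]

    nu.__name__ = f"constant_volume_fraction({value})"
    return nu


# ---------------------------------------------------------------------------
# quadrature
# ---------------------------------------------------------------------------

class QuadraturePlan:
    """Precomputed quadrature nodes and weights for a fixed stretch grid.

    The orientation density ``P(theta, xi)`` and volume fraction
    ``nu(xi, theta)`` do not depend on the model parameters, so their node
    values (together with the trapezoid weights and the geometric factors
    ``cos^2 theta sin theta`` and the lever arm ``lam cos theta - xi``) are
    folded into a single weight array at construction.  Evaluating the model
    for a parameter triple then reduces to one vectorised pass over the
    recruitment density.  This is what makes multi-start fitting affordable.
    """

    def __init__(
        self,
        lam_grid: Sequence[float],
        P: Callable | None = None,
        nu: Callable | None = None,
        gamma: float = 1.0,
        n_theta: int = DEFAULT_N_THETA,
        n_xi: int = DEFAULT_N_XI,
    ) -> None:
        lam_grid = np.asarray(lam_grid, dtype=float)
        if lam_grid.ndim != 1 or len(lam_grid) == 0:
            raise ValueError("lam_grid must be a non-empty 1-D sequence")
        if np.any(lam_grid < 1):
            raise ValueError("stretch ratios must be >= 1")
        if gamma < 1:
            raise ValueError("gamma must be >= 1")
        if n_theta < 3 or n_xi < 3:
            raise ValueError("need at least 3 quadrature nodes per axis")
        if P is None:
            P = uniform_orientation_density()
        if nu is None:
            nu = constant_volume_fraction(1.0)

        self.lam_grid = lam_grid
        self.gamma = float(gamma)
        self.n_theta = int(n_theta)
        self.n_xi = int(n_xi)

        theta = np.linspace(0.0, np.pi / 2.0, n_theta)
        w_theta = np.full(n_theta, np.pi / 2.0 / (n_theta - 1))
        w_theta[[0, -1]] *= 0.5
        w_xi = np.full(n_xi, 1.0 / (n_xi - 1))
        w_xi[[0, -1]] *= 0.5
        jj = np.arange(n_xi)

        lo = max(1.0, self.gamma)
        xis, wts, lidx = [], [], []
        for l, lam in enumerate(lam_grid):
            hi = lam * np.cos(theta)
            for i in range(n_theta):
                if hi[i] <= lo:
                    continue  # empty inner integral below the recruitment onset
                h = (hi[i] - lo) / (n_xi - 1)
                xi = lo + jj * h
                xi[0] = lo + 0.25 * h  # open rule at the support edge
                geom = np.cos(theta[i]) ** 2 * np.sin(theta[i]) * w_theta[i]
                w = (
                    (hi[i] - xi)
                    * w_xi
                    * (hi[i] - lo)
                    * np.asarray(P(theta[i], xi), dtype=float)
                    * np.asarray(nu(xi, theta[i]), dtype=float)
                    * geom
                )
                xis.append(xi)
                wts.append(w)
                lidx.append(np.full(n_xi, l))
        if xis:
            xi_nodes = np.concatenate(xis)
            self._log_u = np.log(xi_nodes - self.gamma)
            self._weights = np.concatenate(wts)
            self._lam_index = np.concatenate(lidx)
        else:  # all grid points at or below the onset stretch
            self._log_u = np.empty(0)
            self._weights = np.empty(0)
            self._lam_index = np.empty(0, dtype=int)

    def evaluate(self, params: ModelParams) -> np.ndarray:
        """Stress at every grid stretch, in MPa."""
        if params.gamma != self.gamma:
            raise ValueError(
                f"plan was built for gamma={self.gamma}, got params.gamma={params.gamma}"
            )
        if self._log_u.size == 0:
            return np.zeros(len(self.lam_grid))
        beta, delta = params.beta, params.delta
        t = self._log_u - np.log(delta)
        # R = (beta/delta) * exp((beta-1)*t - exp(beta*t)); clamp the inner
        # exponent so u**beta overflow maps to density zero, not inf.
        log_r = (beta - 1.0) * t - np.exp(np.minimum(beta * t, 700.0))
        r = (beta / delta) * np.exp(np.maximum(log_r, -745.0))
        out = np.bincount(
            self._lam_index, weights=r * self._weights, minlength=len(self.lam_grid)
        )
        return 2.0 * np.pi * params.N0 * params.E_f * out


def sigma(
    lam: float,
    params: ModelParams,
    P: Callable | None = None,
    nu: Callable | None = None,
    n_theta: int = DEFAULT_N_THETA,
    n_xi: int = DEFAULT_N_XI,
) -> float:
    """Engineering stress of the bundle at stretch ``lam`` (MPa).

    ``P(theta, xi)`` is the orientation density per steradian (default:
    uniform over the hemisphere) and ``nu(xi, theta)`` the volume fraction
    (default: 1).  Raises ``ValueError`` for ``lam < 1``.
    """
    if lam < 1:
        raise ValueError(f"stretch ratio must be >= 1, got {lam}")
    plan = QuadraturePlan([lam], P, nu, gamma=params.gamma, n_theta=n_theta, n_xi=n_xi)
    return float(plan.evaluate(params)[0])


def sigma_curve(
    lam_grid: Sequence[float],
    params: ModelParams,
    P: Callable | None = None,
    nu: Callable | None = None,
    n_theta: int = DEFAULT_N_THETA,
    n_xi: int = DEFAULT_N_XI,
) -> LoadCurve:
    """Forward model evaluated on a stretch grid; returns a LoadCurve."""
    lam_grid = np.asarray(lam_grid, dtype=float)
    if np.any(np.diff(lam_grid) < 0):
        raise ValueError("lam_grid must be sorted ascending")
    plan = QuadraturePlan(
        lam_grid, P, nu, gamma=params.gamma, n_theta=n_theta, n_xi=n_xi
    )
    return LoadCurve(lam_grid, plan.evaluate(params))
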