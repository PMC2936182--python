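"""TG-43 brachytherapy dosimetry formalism.

Implements the line-source geometry factor G_L(r, theta), air kerma strength
S_K from an in-air kerma-versus-distance curve, the dose rate constant
Lambda = D(1 cm, 90 deg) / S_K, the radial dose function g_L(r), the
anisotropy function F(r, theta), and the polar/Cartesian conversion used by
the in-water measurement protocol.

Angles are degrees at every public interface (radians internally); the
transverse axis is theta_0 = 90 deg.  Distances in cm, dose rates in any
consistent per-history or per-time unit, S_K in the same unit times cm^2.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DoseTable",
    "KermaCurve",
    "KermaStrength",
    "TG43Dataset",
    "geometry_factor",
    "air_kerma_strength",
    "dose_rate_constant",
    "radial_dose_function",
    "anisotropy_function",
    "polar_to_cartesian",
    "cartesian_to_polar",
]

THETA0 = 90.0


@dataclass
class DoseTable:
    """Tallied dose rate on (r, theta) points.

    ``values`` are per-history (or per-time) dose rates, ``rel_err`` the
    relative standard errors.  Points are matched with a 1e-6 cm / 1e-6 deg
    tolerance.
    """

    r: np.ndarray  # cm
    theta: np.ndarray  # degrees
    values: np.ndarray
    rel_err: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.rel_err = np.asarray(self.rel_err, dtype=float)

    def lookup(self, r: float, theta: float):
        """(value, rel_err) at a tally point; KeyError if absent."""
        m = (np.abs(self.r - r) < 1e-6) & (np.abs(self.theta - theta) < 1e-6)
        if not np.any(m):
            raise KeyError(f"no tally point at r={r} cm, theta={theta} deg")
        i = int(np.flatnonzero(m)[0])
        return float(self.values[i]), float(self.rel_err[i])


@dataclass
class KermaCurve:
    """In-air kerma versus transverse-axis distance."""

    distance: np.ndarray  # cm
    kerma: np.ndarray  # per history
    rel_err: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.distance = np.asarray(self.distance, dtype=float)
        self.kerma = np.asarray(self.kerma, dtype=float)
        self.rel_err = np.asarray(self.rel_err, dtype=float)


@dataclass
class KermaStrength:
    value: float  # kerma unit * cm^2
    uncertainty: float
    distances: np.ndarray
    method: str = "air-attenuation-corrected linear extrapolation to d=0"
    residuals: np.ndarray | None = None
    failed: bool = False


@dataclass
class TG43Dataset:
    """Bundle of the TG-43 deliverables for one source."""

    dose_rate_constant: float
    dose_rate_constant_unc: float
    gl: dict  # r -> value
    gl_err: dict
    f: dict  # (r, theta) -> value
    f_err: dict
    active_length: float
    normalization_radius: float = 1.0
    provenance: dict = field(default_factory=dict)


# ------------------------------------------------------------ geometry factor

def _beta(r, theta_rad, half_l):
    """Angle subtended by the active line at (r, theta), via the numerically
    stable difference of arctangents of projections onto the line ends."""
    x = r * np.sin(theta_rad)  # perpendicular distance to the long axis
    z = r * np.cos(theta_rad)
    return np.arctan2(z + half_l, x) - np.arctan2(z - half_l, x)


def geometry_factor(r, theta, L):
    """Line-source geometry factor G_L(r, theta) in cm^-2.

    beta / (L r sin(theta)) off-axis, with the on-axis limit
    1 / (r^2 - L^2/4).  Raises for on-axis points with r <= L/2.
    """
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    scalar = r.ndim == 0 and theta.ndim == 0
    r, theta = np.broadcast_arrays(np.atleast_1d(r), np.atleast_1d(theta))
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    if np.any((theta < 0) | (theta > 180)):
        raise ValueError("theta must lie in [0, 180] degrees")
    th = np.deg2rad(theta)
    half_l = L / 2.0
    sin_th = np.sin(th)
    on_axis = np.abs(sin_th) < 1e-9
    if np.any(on_axis & (r <= half_l)):
        raise ValueError("on-axis geometry factor requires r > L/2")
    out = np.empty_like(r)
    off = ~on_axis
    out[off] = _beta(r[off], th[off], half_l) / (L * r[off] * sin_th[off])
    out[on_axis] = 1.0 / (r[on_axis] ** 2 - half_l**2)
    return float(out[0]) if scalar else out


# --------------------------------------------------------- air kerma strength

def air_kerma_strength(
    curve: KermaCurve,
    air,
    spectrum=None,
    window=(10.0, 100.0),
    mu_air_cm: float | None = None,
) -> KermaStrength:
    """Air kerma strength by the corrected-extrapolation method.

    Each in-air kerma value in the fit window is corrected for attenuation
    and scatter of the primary by air (multiplication by exp(+mu_air d) with
    the spectrum-averaged linear attenuation coefficient of air); the
    corrected K(d) d^2 is then fit linearly in d and extrapolated to d = 0,
    the intercept being S_K and the residual slope absorbing remaining
    scatter build-up.

    Parameters
    ----------
    air : MaterialTable for dry air (used when ``mu_air_cm`` not given).
    spectrum : PhotonSpectrum for the fluence-weighted mean attenuation
        coefficient; defaults to evaluating at 0.355 MeV.
    """
    m = (curve.distance >= window[0]) & (curve.distance <= window[1])
    d = curve.distance[m]
    k = curve.kerma[m]
    if d.size < 3:
        raise ValueError("need at least 3 distances in the fit window")
    if mu_air_cm is None:
        if spectrum is not None:
            mu_mass = np.sum(
                spectrum.weights * air(spectrum.energies, "total")
            )
        else:
            mu_mass = air(0.355, "total")
        mu_air_cm = mu_mass * air.density
    corrected = k * np.exp(mu_air_cm * d)
    y = corrected * d**2
    coeffs, cov = np.polyfit(d, y, 1, cov=True)
    intercept = coeffs[1]
    unc = float(np.sqrt(cov[1, 1]))
    resid = y - np.polyval(coeffs, d)
    return KermaStrength(
        value=float(intercept),
        uncertainty=unc,
        distances=d,
        residuals=resid,
        failed=bool(intercept <= 0),
    )


def dose_rate_constant(dose: DoseTable, sk: KermaStrength):
    """Lambda = D(1 cm, 90 deg) / S_K with quadrature-combined uncertainty."""
    d1, rel = dose.lookup(1.0, THETA0)
    lam = d1 / sk.value
    rel_sk = sk.uncertainty / sk.value if sk.value else np.inf
    return lam, lam * float(np.hypot(rel, rel_sk))


# ------------------------------------------------- radial dose / anisotropy

def radial_dose_function(dose: DoseTable, L: float, normalization_radius: float = 1.0):
    """g_L(r) on the transverse axis, Eq.-style dual ratio with the line-source
    geometry factor; exactly 1 at the normalization radius.

    Returns (dict r -> g_L, dict r -> rel_err).
    """
    mask = np.abs(dose.theta - THETA0) < 1e-6
    r = dose.r[mask]
    v = dose.values[mask]
    err = dose.rel_err[mask]
    if not np.any(np.abs(r - normalization_radius) < 1e-6):
        raise ValueError(
            f"dose table lacks the normalization radius {normalization_radius} cm"
        )
    i0 = int(np.flatnonzero(np.abs(r - normalization_radius) < 1e-6)[0])
    g0 = geometry_factor(normalization_radius, THETA0, L)
    gl, gl_err = {}, {}
    for i, ri in enumerate(r):
        val = (v[i] * g0) / (v[i0] * geometry_factor(ri, THETA0, L))
        if i == i0:
            val, e = 1.0, 0.0
        else:
            e = float(np.hypot(err[i], err[i0]))
        gl[float(ri)] = float(val)
        gl_err[float(ri)] = e
    return gl, gl_err


def anisotropy_function(dose: DoseTable, r: float, L: float):
    """F(r, theta) at fixed radius; exactly 1 at theta = 90 deg.

    Returns (dict theta -> F, dict theta -> rel_err).
    """
    mask = np.abs(dose.r - r) < 1e-6
    th = dose.theta[mask]
    v = dose.values[mask]
    err = dose.rel_err[mask]
    ref = np.abs(th - THETA0) < 1e-6
    if not np.any(ref):
        raise ValueError(f"dose table lacks the 90 deg reference at r={r} cm")
    i0 = int(np.flatnonzero(ref)[0])
    g0 = geometry_factor(r, THETA0, L)
    f, f_err = {}, {}
    for i, t in enumerate(th):
        if i == i0:
            f[float(t)], f_err[float(t)] = 1.0, 0.0
            continue
        val = (v[i] * g0) / (v[i0] * geometry_factor(r, t, L))
        f[float(t)] = float(val)
        f_err[float(t)] = float(np.hypot(err[i], err[i0]))
    return f, f_err


# ------------------------------------------------------- coordinate mapping

def polar_to_cartesian(r, theta):
    """(r, theta) -> (X, Y): X = r sin(theta) is the chamber-applicator
    separation, Y = -r cos(theta) the source off-axis travel."""
    th = np.deg2rad(np.asarray(theta, dtype=float))
    r = np.asarray(r, dtype=float)
    return r * np.sin(th), -r * np.cos(th)


def cartesian_to_polar(x, y):
    """Inverse of :func:`polar_to_cartesian` for r > 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = np.hypot(x, y)
    theta = np.rad2deg(np.arctan2(x, -y))
    return r, theta
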