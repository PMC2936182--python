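"""Measurement-side analysis for the 0.1-cc thimble-chamber experiment.

Dose is recovered from a corrected chamber signal through a purely
multiplicative chain

    D_w = N_DW * M_u * P_d * N_n(r) * N_Q,

where ``N_DW`` is the absorbed-dose-to-water calibration factor, ``M_u`` the
temperature/pressure-corrected reading, ``P_d`` the displacement factor for
the cavity (0.991 for the 0.1-cc chamber), ``N_n(r)`` the nonuniformity
correction for the steep near-source gradient, and ``N_Q`` a beam-quality
factor (default 1).

From corrected doses the module derives the tissue attenuation factor
alpha(r) = D_water / D_air, the radial dose function by the
tissue-attenuation-factor route g_L = f(r) alpha(r) / (f(1) alpha(1)) and by
depth dose with dual normalization (r_N = 1 or 5 cm), the anisotropy
function from (X, Y)-positioned readings, and inter-method agreement
statistics.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import tg43

__all__ = [
    "ChamberReading",
    "CorrectionSet",
    "corrected_dose",
    "tissue_attenuation_factor",
    "gl_from_taf",
    "gl_from_depth_dose",
    "anisotropy_from_readings",
    "method_agreement",
    "combine_repeats",
]


@dataclass(frozen=True)
class ChamberReading:
    """One collected chamber signal.

    Position is either a transverse distance ``r`` (cm) or Cartesian
    ``(x, y)`` coordinates of the source relative to the chamber (the
    measurement-jig convention); medium is ``water`` or ``air``.
    """

    signal: float
    medium: str = "water"
    r: float | None = None
    x: float | None = None
    y: float | None = None
    theta: float = 90.0
    repeat: int = 0
    room_scatter_corrected: bool = True

    def __post_init__(self):
        if self.medium not in ("water", "air"):
            raise ValueError("medium must be 'water' or 'air'")
        if self.signal <= 0:
            raise ValueError("signal must be positive")
        if self.r is None:
            if self.x is None or self.y is None:
                raise ValueError("give either r or (x, y)")
            r, th = tg43.cartesian_to_polar(self.x, self.y)
            object.__setattr__(self, "r", float(r))
            object.__setattr__(self, "theta", float(th))
        if self.r <= 0:
            raise ValueError("r must be positive")


@dataclass(frozen=True)
class CorrectionSet:
    """Multiplicative correction chain for the 0.1-cc chamber.

    ``nonuniformity`` holds the tabulated N_n anchors; interpolation is
    log-linear in r between anchors, N_n = 1 beyond the last anchor, and a
    domain error below the first (no extrapolation toward the source).
    ``f_factors`` are exposure-to-dose conversion anchors: constant 0.960 at
    r <= 1 cm, linear to 0.930 across (1, 5] cm, constant 0.930 beyond.
    """

    n_dw: float = 1.0  # cGy per unit signal
    p_d: float = 0.991  # displacement factor, 0.1-cc chamber
    n_q: float = 1.0  # beam quality factor
    room_scatter: float = 1.0  # multiplicative factor on air readings
    nonuniformity: tuple = ((1.0, 1.107), (2.0, 1.033), (5.0, 1.006), (8.0, 1.0044))
    f_factors: tuple = ((1.0, 0.960), (5.0, 0.930), (10.0, 0.930), (20.0, 0.930))

    def __post_init__(self):
        for name in ("n_dw", "p_d", "n_q", "room_scatter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        r, v = self._nn_arrays()
        if np.any(np.diff(v) > 0):
            raise ValueError("N_n must be non-increasing with r")

    def _nn_arrays(self):
        arr = np.asarray(self.nonuniformity, dtype=float)
        return arr[:, 0], arr[:, 1]

    def n_n(self, r):
        """Nonuniformity factor at distance r (cm); log-linear between
        anchors, 1.0 beyond the table, error below it."""
        radii, vals = self._nn_arrays()
        r_arr = np.atleast_1d(np.asarray(r, dtype=float))
        if np.any(r_arr < radii[0] - 1e-12):
            raise ValueError(
                f"r below the nonuniformity table ({radii[0]} cm); "
                "no extrapolation toward the source"
            )
        out = np.where(
            r_arr > radii[-1],
            1.0,
            np.exp(np.interp(np.log(r_arr), np.log(radii), np.log(vals))),
        )
        # beyond the last anchor the correction has converged to unity
        return float(out[0]) if np.isscalar(r) else out

    def f_factor(self, r):
        """Exposure-to-dose conversion factor at r (cm): plateau / linear
        transition / plateau."""
        arr = np.asarray(self.f_factors, dtype=float)
        f1, f5 = arr[0, 1], arr[1, 1]
        r_arr = np.atleast_1d(np.asarray(r, dtype=float))
        out = np.where(
            r_arr <= 1.0, f1,
            np.where(r_arr >= 5.0, f5, f1 + (f5 - f1) * (r_arr - 1.0) / 4.0),
        )
        return float(out[0]) if np.isscalar(r) else out

    def product(self, r):
        """Full Eq.-chain product excluding the raw signal."""
        return self.n_dw * self.p_d * self.n_n(r) * self.n_q


def corrected_dose(reading: ChamberReading, corrections: CorrectionSet) -> float:
    """Absorbed dose to water (cGy) from one in-water reading."""
    if reading.medium != "water":
        raise ValueError("corrected_dose applies to in-water readings")
    return reading.signal * corrections.product(reading.r)


def combine_repeats(doses) -> tuple:
    """Mean dose and standard error over repeated readings (no outlier
    rejection)."""
    d = np.asarray(doses, dtype=float)
    if d.size == 0:
        raise ValueError("no doses to combine")
    se = d.std(ddof=1) / np.sqrt(d.size) if d.size > 1 else 0.0
    return float(d.mean()), float(se)


def tissue_attenuation_factor(water_dose: float, air_dose: float) -> float:
    """alpha(r) = dose in water / dose in air at the same distance."""
    if air_dose <= 0:
        raise ZeroDivisionError("air dose must be positive")
    if water_dose <= 0:
        raise ValueError("water dose must be positive")
    return water_dose / air_dose


def gl_from_taf(alpha: dict, corrections: CorrectionSet | None = None) -> dict:
    """Radial dose function from tissue attenuation factors:
    g_L(r) = f(r) alpha(r) / (f(1) alpha(1))."""
    corrections = corrections or CorrectionSet()
    if not any(abs(r - 1.0) < 1e-9 for r in alpha):
        raise ValueError("tissue-attenuation method needs the 1-cm anchor")
    a1 = alpha[min(alpha, key=lambda r: abs(r - 1.0))]
    f1 = corrections.f_factor(1.0)
    return {
        float(r): float(corrections.f_factor(r) * a / (f1 * a1))
        for r, a in sorted(alpha.items())
    }


def gl_from_depth_dose(doses: dict, L: float, normalization_radius: float = 1.0):
    """Radial dose function from measured transverse-axis doses with the
    line-source geometry factor; ``normalization_radius`` in {1, 5} cm by
    protocol but any tabulated radius is accepted.

    Returns (g_L dict, metadata dict recording the normalization used).
    """
    radii = np.array(sorted(doses))
    if not np.any(np.abs(radii - normalization_radius) < 1e-9):
        raise ValueError(f"no dose at the normalization radius "
                         f"{normalization_radius} cm")
    d = np.array([doses[r] for r in radii])
    table = tg43.DoseTable(radii, np.full_like(radii, 90.0), d,
                           np.zeros_like(radii))
    gl, _ = tg43.radial_dose_function(table, L, normalization_radius)
    return gl, {"normalization_radius": normalization_radius, "L": L}


def anisotropy_from_readings(
    readings, corrections: CorrectionSet, L: float, r: float | None = None
):
    """F(r, theta) from corrected in-water readings at one radius.

    Readings positioned as (X, Y) are resolved through the polar/Cartesian
    conversion; repeats at the same angle are averaged.  Requires a 90-deg
    reference reading.
    """
    by_angle: dict = {}
    for rd in readings:
        if r is not None and abs(rd.r - r) > 0.05:
            continue
        by_angle.setdefault(round(rd.theta, 3), []).append(
            corrected_dose(rd, corrections)
        )
    if r is None:
        r = float(np.mean([rd.r for rd in readings]))
    angles = sorted(by_angle)
    if not any(abs(a - 90.0) < 0.5 for a in angles):
        raise ValueError("anisotropy extraction needs a 90-degree reference")
    a90 = min(angles, key=lambda a: abs(a - 90.0))
    d90, _ = combine_repeats(by_angle[a90])
    g90 = tg43.geometry_factor(r, 90.0, L)
    out = {}
    for a in angles:
        da, _ = combine_repeats(by_angle[a])
        out[float(a)] = float(da * g90 / (d90 * tg43.geometry_factor(r, a, L)))
    out[float(a90)] = 1.0
    return out


def method_agreement(tables: dict, metric: str = "pairwise", radii=None):
    """Agreement statistics between named g_L tables on their common r grid.

    metric='pairwise': per-radius max over table pairs of |A/B - 1|.
    metric='half-range': per-radius (max - min) / (2 mean) over all tables.
    Returns (per-radius dict in percent, max deviation in percent).
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables")
    common = None
    for t in tables.values():
        keys = {round(float(r), 6) for r in t}
        common = keys if common is None else common & keys
    if radii is not None:
        common &= {round(float(r), 6) for r in radii}
    common = sorted(common)
    if len(common) < 2:
        raise ValueError("tables share fewer than 2 radii")
    names = list(tables)
    per_r = {}
    for r in common:
        vals = np.array([tables[n][r] for n in names], dtype=float)
        if metric == "pairwise":
            dev = max(
                abs(vals[i] / vals[j] - 1.0)
                for i in range(len(vals)) for j in range(len(vals)) if i != j
            )
        elif metric == "half-range":
            dev = (vals.max() - vals.min()) / (2.0 * vals.mean())
        else:
            raise ValueError(f"unknown metric {metric!r}")
        per_r[r] = 100.0 * dev
    return per_r, max(per_r.values())
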