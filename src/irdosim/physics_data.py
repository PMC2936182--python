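"""Packaged physical constants for photon transport and kerma conversion.

Two container types are provided:

``PhotonSpectrum``
    A discrete emission-line spectrum (energy in MeV, photons per decay),
    normalized internally to sampling weights.  The packaged default is a
    bare :sup:`192`Ir line set (gammas plus the K x-ray groups).

``MaterialTable``
    A per-material energy grid of mass attenuation coefficients split by
    interaction channel (photoelectric, incoherent, coherent) together with
    the mass energy-absorption coefficient.  Interpolation is log-log with a
    hard error outside the tabulated grid.

All energies are MeV, all coefficients cm^2/g, densities g/cm^3.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PhotonSpectrum",
    "MaterialTable",
    "CHANNELS",
    "load_material",
    "load_spectrum",
    "interpolate_coefficient",
    "build_mixture_table",
    "sample_emission_energy",
]

CHANNELS = ("photoelectric", "incoherent", "coherent", "total", "mu_en")

_COLUMN = {
    "photoelectric": "mu_photoelectric",
    "incoherent": "mu_incoherent",
    "coherent": "mu_coherent",
    "total": "mu_total",
    "mu_en": "mu_en",
}


class EnergyOutOfRangeError(ValueError):
    """Query energy outside the tabulated grid (no silent extrapolation)."""


@dataclass(frozen=True)
class PhotonSpectrum:
    """Discrete photon emission spectrum.

    Parameters
    ----------
    energies : array of line energies, MeV, strictly increasing.
    intensities : photons per decay for each line (need not sum to 1).
    """

    energies: np.ndarray
    intensities: np.ndarray
    weights: np.ndarray = field(init=False)

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        p = np.asarray(self.intensities, dtype=float)
        if e.size == 0:
            raise ValueError("empty spectrum")
        if e.ndim != 1 or p.shape != e.shape:
            raise ValueError("energies and intensities must be 1-D and matching")
        if np.any(e <= 0):
            raise ValueError("line energies must be strictly positive")
        if np.any(np.diff(e) <= 0):
            raise ValueError("line energies must be strictly increasing")
        if np.any(p < 0) or p.sum() <= 0:
            raise ValueError("intensities must be non-negative with positive sum")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "intensities", p)
        object.__setattr__(self, "weights", p / p.sum())

    @property
    def mean_energy(self) -> float:
        """Intensity-weighted mean photon energy, MeV."""
        return float(np.sum(self.weights * self.energies))

    @property
    def photons_per_decay(self) -> float:
        return float(self.intensities.sum())

    def __len__(self) -> int:
        return self.energies.size


@dataclass(frozen=True)
class MaterialTable:
    """Photon interaction coefficients for one material.

    ``channels`` maps channel name -> cm^2/g array on ``energies``; the
    ``total`` channel is the sum of the three physical channels and ``mu_en``
    is the mass energy-absorption coefficient.
    """

    name: str
    density: float  # g/cm^3
    energies: np.ndarray  # MeV, strictly increasing
    channels: dict

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        if np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if self.density <= 0:
            raise ValueError("density must be positive")
        ch = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for k in CHANNELS:
            if k not in ch:
                raise ValueError(f"missing channel {k!r}")
            if ch[k].shape != e.shape:
                raise ValueError(f"channel {k!r} shape mismatch")
            if np.any(ch[k] <= 0):
                raise ValueError(f"channel {k!r} must be positive everywhere")
        s = ch["photoelectric"] + ch["incoherent"] + ch["coherent"]
        if np.any(np.abs(s / ch["total"] - 1) > 5e-3):
            raise ValueError("channel sum deviates from total by more than 0.5%")
        if np.any(ch["mu_en"] > ch["total"] * (1 + 1e-12)):
            raise ValueError("mu_en must not exceed total mu at any grid energy")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "channels", ch)

    def __call__(self, energy, channel: str = "total"):
        return interpolate_coefficient(self, energy, channel)

    def with_density(self, density: float) -> "MaterialTable":
        """Same composition at a different bulk density (e.g. compacted cable)."""
        return MaterialTable(self.name, density, self.energies, self.channels)


def interpolate_coefficient(table: MaterialTable, energy, channel: str = "total"):
    """Log-log interpolated mass coefficient (cm^2/g) at ``energy`` (MeV).

    Exact at grid nodes; raises ``EnergyOutOfRangeError`` outside the grid.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; one of {CHANNELS}")
    e = np.asarray(energy, dtype=float)
    grid = table.energies
    if np.any(e < grid[0]) or np.any(e > grid[-1]):
        raise EnergyOutOfRangeError(
            f"energy outside [{grid[0]:g}, {grid[-1]:g}] MeV for {table.name}"
        )
    vals = np.exp(
        np.interp(np.log(e), np.log(grid), np.log(table.channels[channel]))
    )
    return float(vals) if np.isscalar(energy) else vals


def build_mixture_table(
    components: Sequence[tuple], density: float, name: str = "mixture"
) -> MaterialTable:
    """Mass-fraction-weighted mixture of ``(MaterialTable, fraction)`` pairs.

    Coefficients combine linearly on the merged energy grid (restricted to the
    overlap of the component grids); the bulk density is taken as given.
    """
    tables = [c[0] for c in components]
    fracs = np.array([c[1] for c in components], dtype=float)
    if np.any(fracs < 0):
        raise ValueError("mass fractions must be non-negative")
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"mass fractions sum to {fracs.sum()!r}, expected 1")
    if len(tables) == 1:
        t = tables[0]
        return MaterialTable(name, density, t.energies, t.channels)
    lo = max(t.energies[0] for t in tables)
    hi = min(t.energies[-1] for t in tables)
    e = np.unique(np.concatenate([t.energies for t in tables]))
    e = e[(e >= lo) & (e <= hi)]
    channels = {}
    for k in CHANNELS:
        acc = np.zeros_like(e)
        for t, w in zip(tables, fracs):
            acc += w * interpolate_coefficient(t, e, k)
        channels[k] = acc
    # re-tie total to the channel sum so the invariant holds exactly
    channels["total"] = (
        channels["photoelectric"] + channels["incoherent"] + channels["coherent"]
    )
    channels["mu_en"] = np.minimum(channels["mu_en"], channels["total"])
    return MaterialTable(name, density, e, channels)


def sample_emission_energy(spectrum: PhotonSpectrum, rng: np.random.Generator, size=None):
    """Draw emission line energies with probabilities equal to the normalized
    weights; reproducible for a given ``rng`` state."""
    idx = rng.choice(spectrum.energies.size, size=size, p=spectrum.weights)
    return spectrum.energies[idx]


# ------------------------------------------------------------------ packaged data

def _data_path(fname: str):
    return resources.files("irdosim").joinpath("data", fname)


def load_manifest() -> dict:
    with _data_path("manifest.json").open() as fh:
        return json.load(fh)


def load_material(name: str, density: float | None = None) -> MaterialTable:
    """Load a packaged material table by name (``water``, ``dry_air``,
    ``steel316L``, ``Ir``, ``Pt``)."""
    path = _data_path(f"{name}.csv")
    if not path.is_file():
        raise FileNotFoundError(f"no packaged material table {name!r}")
    rho = None
    with path.open() as fh:
        for line in fh:
            if line.startswith("# density_g_cm3:"):
                rho = float(line.split(":")[1])
            if not line.startswith("#"):
                break
    import pandas as pd

    with path.open() as fh:
        raw = pd.read_csv(fh, comment="#")
    channels = {k: raw[_COLUMN[k]].to_numpy() for k in CHANNELS}
    return MaterialTable(
        name, density if density is not None else float(rho),
        raw["energy_MeV"].to_numpy(), channels,
    )


def load_spectrum(path=None) -> PhotonSpectrum:
    """Load the packaged bare 192Ir line spectrum, or a user two-column
    (energy_MeV, intensity) CSV/text file with ``#`` comments."""
    if path is None:
        path = _data_path("ir192_spectrum.csv")
        with path.open("rb") as fh:
            arr = np.loadtxt(fh, delimiter=",", comments="#")
    else:
        arr = np.loadtxt(path, delimiter=",", comments="#")
    arr = np.atleast_2d(arr)
    order = np.argsort(arr[:, 0])
    return PhotonSpectrum(arr[order, 0], arr[order, 1])


def core_alloy(density: float = 21.76) -> MaterialTable:
    """Ir70/Pt30 active-core alloy at its effective density."""
    return build_mixture_table(
        [(load_material("Ir"), 0.7), (load_material("Pt"), 0.3)],
        density, name="Ir70Pt30",
    )
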