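"""Analog photon Monte Carlo with collision-kerma tallies on ring grids.

The engine reproduces the two runs of the comparative-dosimetry workflow at
desk scale: a water-phantom dose run (finite 60 cm x 60 cm cylinder) and an
in-air kerma run (large air cylinder, transverse-axis scoring from 1 to
100 cm).  Transport is analog: exponential free paths from the material
total attenuation coefficient, channel selection proportional to the channel
cross sections, photoelectric termination (local deposit), Klein-Nishina
incoherent scattering, and coherent scattering with an approximate
form-factor angular model.  No electron transport: collision kerma stands in
for absorbed dose (charged-particle equilibrium).

Tallies are per emitted photon in MeV/g; TG-43 quantities are ratios, so no
absolute activity normalization is required.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .physics_data import MaterialTable, PhotonSpectrum, load_material, load_spectrum, core_alloy
from .source_model import SourceGeometry
from .tg43 import DoseTable, KermaCurve

__all__ = [
    "TallyGrid",
    "TransportProblem",
    "RunConfig",
    "sample_klein_nishina",
    "run_water_dose",
    "run_air_kerma",
    "default_radial_distances",
    "default_anisotropy_angles",
]

_NG = 256
_E_LO, _E_HI = 1e-3, 1.5
_COH_NE = 48


def default_radial_distances():
    return np.array([0.8, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0,
                     10.0, 12.0, 15.0, 18.0, 20.0])


def default_anisotropy_angles():
    return np.array([10.0, 20.0, 30.0, 45.0, 60.0, 90.0,
                     120.0, 135.0, 150.0, 160.0, 170.0])


@dataclass
class TallyGrid:
    """Non-overlapping annular scoring cells inside a cylindrical phantom.

    Each cell c occupies s in [s_lo, s_hi] x z in [z_lo, z_hi] (cm); ``points``
    maps requested (r, theta) locations to cell indices so several logical
    points may share one physical cell.
    """

    s_lo: np.ndarray
    s_hi: np.ndarray
    z_lo: np.ndarray
    z_hi: np.ndarray
    points: list  # (r, theta, cell_index)
    phantom_radius: float
    phantom_half_height: float
    medium: str = "water"

    def __post_init__(self):
        for name in ("s_lo", "s_hi", "z_lo", "z_hi"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.volumes <= 0):
            raise ValueError("cell volumes must be positive")
        if (np.any(self.s_hi > self.phantom_radius)
                or np.any(np.abs(self.z_lo) > self.phantom_half_height)
                or np.any(np.abs(self.z_hi) > self.phantom_half_height)):
            raise ValueError("tally cell outside phantom bounds")
        n = self.s_lo.size
        for i in range(n):
            for j in range(i + 1, n):
                if (self.s_lo[i] < self.s_hi[j] and self.s_lo[j] < self.s_hi[i]
                        and self.z_lo[i] < self.z_hi[j]
                        and self.z_lo[j] < self.z_hi[i]):
                    raise ValueError(f"tally cells {i} and {j} overlap")

    @property
    def volumes(self):
        return (np.pi * (self.s_hi**2 - self.s_lo**2) * (self.z_hi - self.z_lo))

    @property
    def n_cells(self):
        return self.s_lo.size


def _radial_cell_sizes(r):
    """Desk-scale transverse-axis cell extents (dz, dr) at radius r."""
    dz = 0.1
    dr = min(max(0.02, 0.02 * r), 0.4)
    return dz, dr


def build_tally_grid(
    radial_r=None,
    aniso: dict | None = None,
    phantom_radius: float = 30.0,
    phantom_half_height: float = 30.0,
    medium: str = "water",
) -> TallyGrid:
    """Grid covering transverse-axis radii and polar (r, theta) fans.

    ``aniso`` maps radius -> iterable of polar angles (degrees).  Cells are
    kept small relative to the local dose gradient; a polar point at 90 deg
    reuses the transverse cell at the same radius.
    """
    s_lo, s_hi, z_lo, z_hi, points = [], [], [], [], []

    def add_cell(s0, s1, z0, z1):
        s_lo.append(s0)
        s_hi.append(s1)
        z_lo.append(z0)
        z_hi.append(z1)
        return len(s_lo) - 1

    radial_index = {}
    if radial_r is not None:
        for r in np.asarray(radial_r, dtype=float):
            dz, dr = _radial_cell_sizes(r)
            ci = add_cell(r - dr / 2, r + dr / 2, -dz / 2, dz / 2)
            radial_index[float(r)] = ci
            points.append((float(r), 90.0, ci))
    for r, thetas in (aniso or {}).items():
        r = float(r)
        for th in np.asarray(thetas, dtype=float):
            if abs(th - 90.0) < 1e-9 and r in radial_index:
                points.append((r, 90.0, radial_index[r]))
                continue
            ext = min(0.07 * r, 0.35)
            s_c = r * np.sin(np.deg2rad(th))
            z_c = r * np.cos(np.deg2rad(th))
            s0 = max(s_c - ext / 2, 0.0)
            ci = add_cell(s0, s_c + ext / 2, z_c - ext / 2, z_c + ext / 2)
            points.append((r, float(th), ci))
    return TallyGrid(
        np.array(s_lo), np.array(s_hi), np.array(z_lo), np.array(z_hi),
        points, phantom_radius, phantom_half_height, medium,
    )


def build_air_grid(
    distances=None, phantom_radius=500.0, phantom_half_height=500.0
) -> TallyGrid:
    """Transverse-axis ring cells in the large air cylinder."""
    if distances is None:
        distances = np.array([1.0, 2.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0,
                              60.0, 70.0, 80.0, 90.0, 100.0])
    s_lo, s_hi, z_lo, z_hi, points = [], [], [], [], []
    for d in np.asarray(distances, dtype=float):
        dr = min(max(0.05 * d, 0.1), 2.0)
        dz = min(max(0.1 * d, 0.1), 2.0)
        s_lo.append(d - dr / 2)
        s_hi.append(d + dr / 2)
        z_lo.append(-dz / 2)
        z_hi.append(dz / 2)
        points.append((float(d), 90.0, len(s_lo) - 1))
    return TallyGrid(
        np.array(s_lo), np.array(s_hi), np.array(z_lo), np.array(z_hi),
        points, phantom_radius, phantom_half_height, medium="dry_air",
    )


# --------------------------------------------------------------- materials

_MAT_ORDER = ("medium", "core_alloy", "capsule_steel", "cable_steel", "gap_air")


@dataclass
class TransportProblem:
    """Materials, geometry and options resampled onto the fast energy grid."""

    geometry: SourceGeometry
    grid: TallyGrid
    spectrum: PhotonSpectrum
    medium_table: MaterialTable
    include_coherent: bool = True
    cutoff: float = 1e-3  # MeV, photon transport cutoff
    mode: int = 0  # 0 analog, 1 primary-only, 2 streaming
    use_geometry: bool = True
    arrays: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.arrays = self._prepare()

    def _material_tables(self):
        steel = load_material("steel316L")
        gap = load_material("dry_air")
        if self.geometry.gap_material == "vacuum":
            gap = gap.with_density(1e-20)
        return {
            "medium": self.medium_table,
            "core_alloy": core_alloy(),
            "capsule_steel": steel,
            "cable_steel": steel.with_density(5.6),
            "gap_air": gap,
        }

    def _prepare(self):
        egrid = np.geomspace(_E_LO, _E_HI, _NG)
        tables = self._material_tables()
        n_mat = len(_MAT_ORDER)
        mu_tot = np.zeros((n_mat, _NG))
        cum_pe = np.zeros((n_mat, _NG))
        cum_inc = np.zeros((n_mat, _NG))
        zeff = {"medium": 7.42 if self.grid.medium == "water" else 7.64,
                "core_alloy": 77.3, "capsule_steel": 25.8,
                "cable_steel": 25.8, "gap_air": 7.64}
        coh_e = np.geomspace(_E_LO, _E_HI, _COH_NE)
        coh_tab = np.zeros((n_mat, _COH_NE, 33))
        for m, name in enumerate(_MAT_ORDER):
            t = tables[name]
            pe = t(egrid, "photoelectric") * t.density
            inc = t(egrid, "incoherent") * t.density
            coh = t(egrid, "coherent") * t.density
            if not self.include_coherent:
                coh = np.zeros_like(coh)
            tot = pe + inc + coh
            mu_tot[m] = tot
            cum_pe[m] = pe / tot
            cum_inc[m] = (pe + inc) / tot
            coh_tab[m] = _coherent_inverse_cdf(coh_e, zeff[name])
        muen_med = tables["medium"](egrid, "mu_en")

        radii, zplanes = self.geometry.surfaces()
        regs = self.geometry.regions
        mat_index = dict(medium=0, core_alloy=1, capsule_steel=2,
                         cable_steel=3, gap_air=4)
        reg_mat = np.array([mat_index[r.material] for r in regs], dtype=np.int64)

        spec_cdf = np.cumsum(self.spectrum.weights)
        spec_cdf[-1] = 1.0
        zb_lo, zb_hi = self.geometry.bounding_z
        return dict(
            spec_e=self.spectrum.energies.copy(), spec_cdf=spec_cdf,
            log_e0=np.log(_E_LO),
            inv_dlog=(_NG - 1) / (np.log(_E_HI) - np.log(_E_LO)),
            ng=_NG, mu_tot=mu_tot, cum_pe=cum_pe, cum_inc=cum_inc,
            muen_med=np.asarray(muen_med),
            coh_e_log0=np.log(_E_LO),
            coh_inv_dlog=(_COH_NE - 1) / (np.log(_E_HI) - np.log(_E_LO)),
            coh_tab=coh_tab,
            reg_rmin2=np.array([r.r_min**2 for r in regs]),
            reg_rmax2=np.array([r.r_max**2 for r in regs]),
            reg_zmin=np.array([r.z_min for r in regs]),
            reg_zmax=np.array([r.z_max for r in regs]),
            reg_mat=reg_mat,
            radii=radii, zplanes=zplanes,
            rb=self.geometry.bounding_radius, zb_lo=zb_lo, zb_hi=zb_hi,
            core_radius=self.geometry.core_radius,
            core_half_z=self.geometry.core_half_length,
            medium_mat=0,
            rp=self.grid.phantom_radius, hp=self.grid.phantom_half_height,
            cz_lo=self.grid.z_lo, cz_hi=self.grid.z_hi,
            cs_lo2=self.grid.s_lo**2, cs_hi2=self.grid.s_hi**2,
            inv_vol=1.0 / self.grid.volumes,
            e_cut=self.cutoff, mode=self.mode,
            use_geom=1 if self.use_geometry else 0,
        )


def _coherent_inverse_cdf(energies, zeff, nq=33):
    """Quantiles of cos(theta) for Thomson x form-factor^2 coherent
    scattering; screened hydrogenic form factor with scale ~ Z^(1/3)."""
    mu = np.linspace(-1.0, 1.0, 1501)
    out = np.zeros((energies.size, nq))
    q_half = 0.0036 * zeff ** (1.0 / 3.0)  # MeV-equivalent momentum scale
    quantiles = np.linspace(0.0, 1.0, nq)
    for i, e in enumerate(energies):
        x = e * np.sqrt(np.maximum(0.0, (1.0 - mu) / 2.0))
        ff = 1.0 / (1.0 + (x / q_half) ** 2) ** 2
        pdf = (1.0 + mu**2) * ff**2
        cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2)])
        cdf /= cdf[-1]
        out[i] = np.interp(quantiles, cdf, mu)
    return out


# ------------------------------------------------------------------ running

@dataclass
class RunConfig:
    histories: int
    seed: int
    batches: int = 10
    include_coherent: bool = True
    cutoff: float = 1e-3
    mode: int = 0
    use_geometry: bool = True

    def __post_init__(self):
        if self.histories < 10_000:
            raise ValueError("need at least 1e4 histories")
        if self.batches < 2:
            raise ValueError("need at least 2 batches for error estimates")


def _batch_seeds(master_seed: int, batches: int):
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31 - 1) + 1 for s in ss.generate_state(batches)]


def run_tallies(problem: TransportProblem, config: RunConfig):
    """Run batched histories; returns (mean, rel_err, mean_col, rel_err_col)
    per cell, per emitted photon, MeV/g."""
    a = problem.arrays
    per_batch = config.histories // config.batches
    seeds = _batch_seeds(config.seed, config.batches)
    track = np.zeros((config.batches, problem.grid.n_cells))
    coll = np.zeros_like(track)
    for b, seed in enumerate(seeds):
        track[b], coll[b] = _kernels.run_batch(
            per_batch, seed,
            a["spec_e"], a["spec_cdf"],
            a["log_e0"], a["inv_dlog"], a["ng"],
            a["mu_tot"], a["cum_pe"], a["cum_inc"], a["muen_med"],
            a["coh_e_log0"], a["coh_inv_dlog"], a["coh_tab"],
            a["reg_rmin2"], a["reg_rmax2"], a["reg_zmin"], a["reg_zmax"],
            a["reg_mat"],
            a["radii"], a["zplanes"], a["rb"], a["zb_lo"], a["zb_hi"],
            a["core_radius"], a["core_half_z"], a["medium_mat"],
            a["rp"], a["hp"],
            a["cz_lo"], a["cz_hi"], a["cs_lo2"], a["cs_hi2"], a["inv_vol"],
            a["e_cut"], a["mode"], a["use_geom"],
        )

    def summarize(batch_vals):
        mean = batch_vals.mean(axis=0)
        se = batch_vals.std(axis=0, ddof=1) / np.sqrt(config.batches)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(mean > 0, se / mean, np.inf)
        return mean, rel

    m, r = summarize(track)
    mc, rc = summarize(coll)
    return m, r, mc, rc


def sample_klein_nishina(energy: float, rng_or_seed, n: int = 1):
    """Sample the Klein-Nishina distribution at ``energy`` (MeV).

    Returns (scattered energies, cos polar angles), each length ``n``.
    """
    if energy <= 0:
        raise ValueError("energy must be positive")
    if isinstance(rng_or_seed, np.random.Generator):
        seed = int(rng_or_seed.integers(1, 2**31 - 1))
    else:
        seed = int(rng_or_seed)
    return _kernels.kn_sample_many(float(energy), int(n), seed)


def _result_meta(problem, config):
    return dict(
        histories=config.histories, seed=config.seed, batches=config.batches,
        mode=config.mode, medium=problem.grid.medium,
        include_coherent=problem.include_coherent,
        cutoff_MeV=problem.cutoff, engine="irdosim-analog-1",
    )


def run_water_dose(
    geometry: SourceGeometry | None = None,
    config: RunConfig | None = None,
    radial_r=None,
    aniso: dict | None = None,
    spectrum: PhotonSpectrum | None = None,
    grid: TallyGrid | None = None,
) -> DoseTable:
    """Water-phantom dose run: per-cell collision kerma per emitted photon
    at the requested transverse radii and polar fans.

    The phantom is the bounded 60 cm x 60 cm water cylinder; defaults cover
    the transverse axis 0.8-20 cm and an anisotropy fan at r = 5 cm.
    """
    geometry = geometry or SourceGeometry()
    config = config or RunConfig(histories=200_000, seed=1)
    if grid is None:
        if radial_r is None:
            radial_r = default_radial_distances()
        if aniso is None:
            aniso = {5.0: default_anisotropy_angles()}
        grid = build_tally_grid(radial_r=radial_r, aniso=aniso)
    spectrum = spectrum or load_spectrum()
    problem = TransportProblem(
        geometry, grid, spectrum, load_material("water"),
        include_coherent=config.include_coherent, cutoff=config.cutoff,
        mode=config.mode, use_geometry=config.use_geometry,
    )
    mean, rel, mean_col, rel_col = run_tallies(problem, config)
    r = np.array([p[0] for p in grid.points])
    th = np.array([p[1] for p in grid.points])
    ci = np.array([p[2] for p in grid.points], dtype=int)
    meta = _result_meta(problem, config)
    meta["collision_estimator"] = mean_col[ci]
    meta["collision_rel_err"] = rel_col[ci]
    return DoseTable(r, th, mean[ci], rel[ci], meta=meta)


def run_air_kerma(
    geometry: SourceGeometry | None = None,
    config: RunConfig | None = None,
    distances=None,
    spectrum: PhotonSpectrum | None = None,
) -> KermaCurve:
    """In-air kerma run on the transverse axis in the large air cylinder."""
    geometry = geometry or SourceGeometry(medium="dry_air")
    config = config or RunConfig(histories=200_000, seed=1)
    grid = build_air_grid(distances=distances)
    spectrum = spectrum or load_spectrum()
    problem = TransportProblem(
        geometry, grid, spectrum, load_material("dry_air"),
        include_coherent=config.include_coherent, cutoff=config.cutoff,
        mode=config.mode, use_geometry=config.use_geometry,
    )
    mean, rel, _, _ = run_tallies(problem, config)
    d = np.array([p[0] for p in grid.points])
    ci = np.array([p[2] for p in grid.points], dtype=int)
    return KermaCurve(d, mean[ci], rel[ci], meta=_result_meta(problem, config))
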