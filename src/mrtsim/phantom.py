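"""Voxelised Monte Carlo photon transport in the scanned phantom.

The phantom is a homogeneous slab (solid water by default) with its entrance
face at 34.16 m from the source.  Coordinates are phantom-local: X is depth
from the entrance face (0..140 mm), Y horizontal and Z vertical, both
centred on the beam axis.  The vertical scan is emulated the way the
time-dependent geometry does it: primary i enters with the phantom offset
z_i = -H/2 + i*(H/n) for a field height H, which is equivalent to displacing
the photon by z_i in the phantom frame.

Photon histories alternate free flights sampled from the total linear
attenuation coefficient with interactions partitioned into photoelectric
(full local transfer to an electron), Compton (Klein-Nishina energy/angle
sampling, kinematic electron), and Rayleigh (direction change only,
Thomson-like angular law).  Electrons deposit either locally or uniformly
along a straight CSDA-range track ("csda" mode, needed when voxels are small
compared to the electron range).  Each history conserves energy exactly up
to floating-point rounding: everything entering is accounted either as a
deposit inside the phantom or as escaped energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .attenuation import get_material, linear_attenuation, partial_mass_attenuation
from .beamline import PhaseSpace
from .errors import ConfigurationError, GeometryError

__all__ = [
    "PhantomConfig",
    "ScoringMesh",
    "ScanConfig",
    "DoseGrid",
    "scan_speed",
    "transport",
    "scale_dose",
    "electron_deposit",
    "csda_range",
    "save_dose_grid",
    "load_dose_grid",
]

_MEC2_KEV = 510.99895
_ELEMENTARY_CHARGE = 1.602176634e-19  # C
_KEV_TO_J = 1.602176634e-16

#: photons below this energy are absorbed on the spot (their mean free path
#: is well below the smallest scoring voxel pitch that matters here)
_PHOTON_FLOOR_KEV = 5.0


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomConfig:
    dimensions: tuple[float, float, float] = (140.0, 100.0, 100.0)  # mm, (X, Y, Z)
    material: str = "solid_water"
    entrance_plane_distance: float = 34.16  # m from the source
    surrounding_medium: str = "air"

    def __post_init__(self):
        if min(self.dimensions) <= 0:
            raise ConfigurationError("phantom dimensions must be positive")
        get_material(self.material)  # must exist


@dataclass(frozen=True)
class ScoringMesh:
    """Voxel mesh inside the phantom.

    offset is the lower corner of the mesh in phantom coordinates
    (x from the entrance face, y and z from the beam axis).  Voxels are
    half-open [lower, upper) along every axis.
    """

    voxel_size: tuple[float, float, float]
    extent: tuple[float, float, float]
    offset: tuple[float, float, float]

    def __post_init__(self):
        for v, e in zip(self.voxel_size, self.extent):
            if v <= 0 or e <= 0:
                raise ConfigurationError("voxel size and extent must be positive")
            n = e / v
            if abs(n - round(n)) > 1e-6:
                raise ConfigurationError("voxel size must divide the mesh extent")

    @classmethod
    def bb(cls) -> "ScoringMesh":
        """Broadbeam preset: 2 x 2 x 5 mm voxels over the full phantom."""
        return cls(voxel_size=(2.0, 2.0, 5.0), extent=(140.0, 100.0, 100.0), offset=(0.0, -50.0, -50.0))

    @classmethod
    def mb(cls) -> "ScoringMesh":
        """Microbeam preset: 1 x 0.01 x 0.1 mm voxels over 140 x 2 x 2 mm, centred."""
        return cls(voxel_size=(1.0, 0.01, 0.1), extent=(140.0, 2.0, 2.0), offset=(0.0, -1.0, -1.0))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(int(round(e / v)) for e, v in zip(self.extent, self.voxel_size))

    def edges(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.offset[axis] + self.voxel_size[axis] * np.arange(n + 1)

    def centers(self, axis: int) -> np.ndarray:
        e = self.edges(axis)
        return 0.5 * (e[:-1] + e[1:])

    def voxel_volume_cm3(self) -> float:
        vx, vy, vz = self.voxel_size
        return vx * vy * vz * 1e-3  # mm^3 -> cm^3


@dataclass(frozen=True)
class ScanConfig:
    """Vertical-scan delivery parameters."""

    scan_speed: float = 10.0  # mm/s
    field_height: float = 20.0  # mm
    field_width: float = 20.0  # mm
    prescribed_dose: float | None = None  # Gy
    intrinsic_dose_rate: float | None = None  # Gy/s
    bda_height: float | None = None  # mm

    def __post_init__(self):
        if self.scan_speed <= 0:
            raise ConfigurationError("scan speed must be positive")
        if self.field_height < 0 or self.field_width < 0:
            raise ConfigurationError("field dimensions cannot be negative")

    @property
    def beam_on_time(self) -> float:
        """Effective beam-on time, field height / scan speed (s)."""
        return self.field_height / self.scan_speed


def scan_speed(dose_rate: float, bda_height: float, dose: float) -> float:
    """Scan speed nu_z = (D_rate * h) / D delivering `dose` with BDA height h."""
    if dose_rate <= 0 or bda_height <= 0 or dose <= 0:
        raise ValueError("dose rate, BDA height and dose must all be positive")
    return dose_rate * bda_height / dose


# ---------------------------------------------------------------------------
# Dose grid
# ---------------------------------------------------------------------------


@dataclass
class DoseGrid:
    """Voxelised energy deposit / dose with geometry metadata."""

    mesh: ScoringMesh
    phantom: PhantomConfig
    energy_deposit: np.ndarray  # keV per voxel
    energy_uncertainty: np.ndarray  # keV per voxel, 95% CL (0 if single batch)
    n_primaries: int
    energy_in: float = 0.0  # keV entering the phantom
    energy_deposited_total: float = 0.0  # keV deposited anywhere in the phantom
    energy_escaped: float = 0.0  # keV leaving the phantom
    dose: np.ndarray | None = None  # Gy, set by scale_dose
    uncertainty: np.ndarray | None = None  # Gy, 95% CL
    provenance: dict = field(default_factory=dict)
    # optional per-primary ledger (keep_history_ledger=True): entering,
    # deposited-in-phantom, and escaped energy per history, keV (weighted)
    history_in: np.ndarray | None = None
    history_deposited: np.ndarray | None = None
    history_escaped: np.ndarray | None = None

    @property
    def voxel_mass_kg(self) -> float:
        return self.mesh.voxel_volume_cm3() * get_material(self.phantom.material).density * 1e-3

    def values(self) -> np.ndarray:
        """Dose if scaled, otherwise raw energy deposit."""
        return self.dose if self.dose is not None else self.energy_deposit

    def errors(self) -> np.ndarray:
        return self.uncertainty if self.dose is not None else self.energy_uncertainty


def scale_dose(grid: DoseGrid, ring_current: float, beam_on_time: float,
               n_simulated: float, k_w: float = 1.0) -> DoseGrid:
    """Convert energy deposits to absolute dose.

    dose = (E_v / m_v) * (I_ring * t_exp / e) / n_simulated * K_w, with E_v in
    joules and the ring current converted to an electron count through the
    elementary charge.  n_simulated is the equivalent number of simulated
    source electrons the transported primaries represent.
    """
    if n_simulated <= 0:
        raise ValueError("number of simulated electrons must be positive")
    if beam_on_time < 0 or ring_current <= 0:
        raise ValueError("ring current must be positive and beam-on time non-negative")
    electrons = (ring_current * 1e-3) * beam_on_time / _ELEMENTARY_CHARGE
    factor = _KEV_TO_J / grid.voxel_mass_kg * electrons / n_simulated * k_w
    out = replace(grid)
    out.dose = grid.energy_deposit * factor
    out.uncertainty = grid.energy_uncertainty * factor
    out.provenance = dict(grid.provenance, k_w=k_w, ring_current_mA=ring_current,
                          beam_on_time_s=beam_on_time, n_simulated=n_simulated)
    return out


# ---------------------------------------------------------------------------
# Electron model
# ---------------------------------------------------------------------------

# CSDA range in water, g/cm^2 (continuous slowing-down approximation);
# for the low-Z media used here the per-mass range is material-insensitive.
_CSDA_E_KEV = np.array([10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0, 150.0, 200.0, 300.0])
_CSDA_G_CM2 = np.array([2.52e-4, 8.57e-4, 1.76e-3, 2.92e-3, 4.32e-3, 5.90e-3,
                        9.90e-3, 1.431e-2, 2.82e-2, 4.49e-2, 8.42e-2])


def csda_range(energy_kev, material: str = "water") -> np.ndarray:
    """CSDA electron range in mm for the given medium."""
    mat = get_material(material)
    if mat.density <= 0:
        raise ConfigurationError("CSDA range undefined in vacuum")
    e = np.asarray(energy_kev, dtype=float)
    r = np.exp(np.interp(np.log(np.clip(e, 1.0, None)), np.log(_CSDA_E_KEV), np.log(_CSDA_G_CM2)))
    out = r / mat.density * 10.0  # g/cm^2 -> cm -> mm
    return float(out) if np.ndim(energy_kev) == 0 else out


def electron_deposit(energy: float, position, direction, mode: str,
                     material: str = "solid_water", n_substeps: int = 32):
    """Deposit events for a single electron: list of (position_mm, energy_keV).

    mode "local" deposits at the interaction site; mode "csda" spreads the
    energy uniformly along a straight track of the CSDA range.
    """
    if mode not in ("local", "csda"):
        raise ConfigurationError(f"unknown electron transport mode {mode!r}")
    if energy <= 0:
        return []
    position = np.asarray(position, dtype=float)
    if mode == "local":
        return [(position, float(energy))]
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    r = csda_range(energy, material)
    steps = (np.arange(n_substeps) + 0.5) / n_substeps
    return [(position + s * r * direction, float(energy) / n_substeps) for s in steps]


# ---------------------------------------------------------------------------
# Sampling helpers (vectorised)
# ---------------------------------------------------------------------------


def _sample_compton_eps(rng: np.random.Generator, energy_kev: np.ndarray) -> np.ndarray:
    """Sample the Compton energy ratio eps = E'/E from Klein-Nishina."""
    k = energy_kev / _MEC2_KEV
    eps_min = 1.0 / (1.0 + 2.0 * k)
    a1 = -np.log(eps_min)
    a2 = 0.5 * (1.0 - eps_min**2)
    eps = np.empty_like(k)
    todo = np.ones(k.size, dtype=bool)
    while todo.any():
        idx = np.nonzero(todo)[0]
        u1, u2, u3 = rng.random((3, idx.size))
        use_log = u1 < a1[idx] / (a1[idx] + a2[idx])
        cand = np.where(use_log,
                        eps_min[idx] * np.exp(a1[idx] * u2),
                        np.sqrt(eps_min[idx] ** 2 + (1.0 - eps_min[idx] ** 2) * u2))
        t = (1.0 - cand) / (k[idx] * cand)
        sin2 = t * (2.0 - t)
        g = 1.0 - cand * sin2 / (1.0 + cand**2)
        accept = u3 <= g
        eps[idx[accept]] = cand[accept]
        todo[idx[accept]] = False
    return eps


def _sample_thomson_cos(rng: np.random.Generator, n: int) -> np.ndarray:
    """Sample cos(theta) from the (1 + cos^2) Thomson angular law."""
    out = np.empty(n)
    todo = np.ones(n, dtype=bool)
    while todo.any():
        m = int(todo.sum())
        c = 2.0 * rng.random(m) - 1.0
        accept = rng.random(m) <= 0.5 * (1.0 + c**2)
        idx = np.nonzero(todo)[0]
        out[idx[accept]] = c[accept]
        todo[idx[accept]] = False
    return out


def _rotate(direction: np.ndarray, cos_t: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate unit vectors by polar angle theta and azimuth phi."""
    d = direction
    # helper axis least aligned with d
    helper = np.zeros_like(d)
    use_x = np.abs(d[:, 0]) < 0.9
    helper[use_x, 0] = 1.0
    helper[~use_x, 1] = 1.0
    u = np.cross(helper, d)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(d, u)
    sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 0.0))
    new = (cos_t[:, None] * d
           + sin_t[:, None] * (np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * v))
    return new / np.linalg.norm(new, axis=1, keepdims=True)


def _exit_distance(pos: np.ndarray, d: np.ndarray, dims) -> np.ndarray:
    """Distance (mm) along d from pos to the phantom boundary."""
    X, Y, Z = dims
    lo = np.array([0.0, -0.5 * Y, -0.5 * Z])
    hi = np.array([X, 0.5 * Y, 0.5 * Z])
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo[None, :] - pos) / d
        t2 = (hi[None, :] - pos) / d
    tmax = np.where(d != 0.0, np.maximum(t1, t2), np.inf)
    return np.min(tmax, axis=1)


# ---------------------------------------------------------------------------
# The transport driver
# ---------------------------------------------------------------------------


class _Scorer:
    """Accumulates deposits into the mesh and the conservation ledger."""

    def __init__(self, mesh: ScoringMesh, dims, n_primaries: int, n_batches: int,
                 batch_of: np.ndarray | None):
        self.mesh = mesh
        self.dims = dims
        self.shape = mesh.shape
        self.grid = np.zeros(int(np.prod(self.shape)))
        self.n_batches = n_batches
        self.batch_of = batch_of
        self.batch_grid = (np.zeros((n_batches, self.grid.size)) if n_batches > 1 else None)
        self.e_dep = np.zeros(n_primaries)
        self.e_esc = np.zeros(n_primaries)

    def _inside_phantom(self, pos):
        X, Y, Z = self.dims
        return ((pos[:, 0] >= 0.0) & (pos[:, 0] <= X)
                & (np.abs(pos[:, 1]) <= 0.5 * Y) & (np.abs(pos[:, 2]) <= 0.5 * Z))

    def deposit(self, pos: np.ndarray, energy_w: np.ndarray, pid: np.ndarray):
        """Deposit weighted energies at positions; splits phantom/escape."""
        inside = self._inside_phantom(pos)
        np.add.at(self.e_dep, pid[inside], energy_w[inside])
        np.add.at(self.e_esc, pid[~inside], energy_w[~inside])
        if not inside.any():
            return
        p, e, ids = pos[inside], energy_w[inside], pid[inside]
        off = np.asarray(self.mesh.offset)
        vox = np.asarray(self.mesh.voxel_size)
        ijk = np.floor((p - off[None, :]) / vox[None, :]).astype(np.int64)
        ok = np.all((ijk >= 0) & (ijk < np.asarray(self.shape)[None, :]), axis=1)
        if not ok.any():
            return
        ijk, e, ids = ijk[ok], e[ok], ids[ok]
        flat = (ijk[:, 0] * self.shape[1] + ijk[:, 1]) * self.shape[2] + ijk[:, 2]
        np.add.at(self.grid, flat, e)
        if self.batch_grid is not None:
            b = self.batch_of[ids]
            np.add.at(self.batch_grid, (b, flat), e)

    def escape(self, energy_w: np.ndarray, pid: np.ndarray):
        np.add.at(self.e_esc, pid, energy_w)


def transport(
    psf: PhaseSpace,
    phantom: PhantomConfig,
    mesh: ScoringMesh,
    scan: ScanConfig,
    n: int,
    seed: int,
    *,
    electron_mode: str | None = None,
    deposit_threshold: float = 1.0,
    n_batches: int = 1,
    chunk_size: int = 2_000_000,
    csda_substeps: int = 32,
    max_generations: int = 64,
    keep_history_ledger: bool = False,
) -> DoseGrid:
    """Track n primaries from the PSF through the scanned phantom.

    electron_mode None selects "csda" when the smallest voxel pitch is below
    0.5 mm (microbeam meshes) and "local" otherwise.
    """
    if len(psf) == 0:
        raise ValueError("phase space is empty")
    if n <= 0:
        raise ValueError("number of primaries must be positive")
    # mesh must fit inside the phantom
    X, Y, Z = phantom.dimensions
    lo = np.asarray(mesh.offset)
    hi = lo + np.asarray(mesh.extent)
    if (lo[0] < -1e-9 or hi[0] > X + 1e-9 or lo[1] < -0.5 * Y - 1e-9
            or hi[1] > 0.5 * Y + 1e-9 or lo[2] < -0.5 * Z - 1e-9 or hi[2] > 0.5 * Z + 1e-9):
        raise GeometryError("scoring mesh extends outside the phantom")
    if electron_mode is None:
        electron_mode = "csda" if min(mesh.voxel_size) < 0.5 else "local"
    if electron_mode not in ("local", "csda"):
        raise ConfigurationError(f"unknown electron transport mode {electron_mode!r}")

    mat = get_material(phantom.material)
    vacuum = mat.density <= 0.0
    rng = np.random.default_rng(seed)

    resampled = n > len(psf)
    if n == len(psf):
        sel = np.arange(n)
    else:
        sel = rng.choice(len(psf), size=n, replace=resampled)

    # fast attenuation lookup tables for the phantom medium
    if not vacuum:
        e_grid = np.geomspace(2.0, 400.0, 800)
        mu_tot_grid = linear_attenuation(mat, e_grid)
        photo, incoh, coh = partial_mass_attenuation(mat, e_grid)
        p_photo_grid = photo / (photo + incoh + coh)
        p_coh_grid = coh / (photo + incoh + coh)
        ln_e_grid = np.log(e_grid)

        def mu_of(e):
            return np.interp(np.log(e), ln_e_grid, mu_tot_grid)

        def channel_probs(e):
            ln = np.log(e)
            return np.interp(ln, ln_e_grid, p_photo_grid), np.interp(ln, ln_e_grid, p_coh_grid)

    batch_of = None
    if n_batches > 1:
        batch_of = (np.arange(n) * n_batches // n).astype(np.int64)
    scorer = _Scorer(mesh, phantom.dimensions, n, n_batches, batch_of)

    # scan offsets: the phantom translation is emulated per primary
    offsets = -0.5 * scan.field_height + np.arange(n) * (scan.field_height / n) if scan.field_height > 0 else np.zeros(n)

    drift_mm = (phantom.entrance_plane_distance - psf.distance_m) * 1e3
    if drift_mm < 0:
        raise GeometryError("phantom entrance lies upstream of the PSF plane")

    def deposit_electrons(pos, d, e_w, pid, e_true):
        """Score electron energy (weighted) with the configured model."""
        if electron_mode == "local":
            scorer.deposit(pos, e_w, pid)
            return
        r = csda_range(e_true, phantom.material)  # mm
        step_e = e_w / csda_substeps
        for j in range(csda_substeps):
            frac = (j + 0.5) / csda_substeps
            scorer.deposit(pos + (frac * r)[:, None] * d, step_e, pid)

    e_in = np.zeros(n)
    for start in range(0, n, int(chunk_size)):
        stop = min(start + int(chunk_size), n)
        ids = np.arange(start, stop)
        src = sel[ids]

        dx = psf.dx[src]
        pos = np.stack([
            np.zeros(stop - start),
            psf.y[src] + psf.dy[src] / dx * drift_mm,
            psf.z[src] + psf.dz[src] / dx * drift_mm + offsets[ids],
        ], axis=1)
        d = np.stack([dx, psf.dy[src], psf.dz[src]], axis=1)
        energy = psf.energy[src].copy()
        weight = psf.weight[src].copy()
        pid = ids.copy()
        e_in[ids] = energy * weight

        # photons entering outside the face never enter the phantom
        on_face = (np.abs(pos[:, 1]) <= 0.5 * Y) & (np.abs(pos[:, 2]) <= 0.5 * Z)
        scorer.escape(energy[~on_face] * weight[~on_face], pid[~on_face])
        pos, d, energy, weight, pid = pos[on_face], d[on_face], energy[on_face], weight[on_face], pid[on_face]

        if vacuum:
            scorer.escape(energy * weight, pid)
            continue

        for _ in range(max_generations):
            if energy.size == 0:
                break
            mu = mu_of(energy)  # 1/cm
            s = -np.log(rng.random(energy.size)) / mu * 10.0  # mm
            t_exit = _exit_distance(pos, d, phantom.dimensions)
            escaped = s >= t_exit
            scorer.escape(energy[escaped] * weight[escaped], pid[escaped])
            keep = ~escaped
            pos = pos[keep] + s[keep, None] * d[keep]
            d, energy, weight, pid = d[keep], energy[keep], weight[keep], pid[keep]
            if energy.size == 0:
                break

            p_photo, p_coh = channel_probs(energy)
            u = rng.random(energy.size)
            is_photo = u < p_photo
            is_coh = (~is_photo) & (u < p_photo + p_coh)
            is_compton = ~(is_photo | is_coh)

            # photoelectric: all energy to a forward electron
            if is_photo.any():
                deposit_electrons(pos[is_photo], d[is_photo],
                                  energy[is_photo] * weight[is_photo],
                                  pid[is_photo], energy[is_photo])

            # Rayleigh: direction change only
            if is_coh.any():
                m = int(is_coh.sum())
                cos_t = _sample_thomson_cos(rng, m)
                phi = 2.0 * np.pi * rng.random(m)
                d[is_coh] = _rotate(d[is_coh], cos_t, phi)

            # Compton: Klein-Nishina split between scattered photon and electron
            if is_compton.any():
                e0 = energy[is_compton]
                eps = _sample_compton_eps(rng, e0)
                k = e0 / _MEC2_KEV
                cos_t = 1.0 - (1.0 - eps) / (k * eps)
                cos_t = np.clip(cos_t, -1.0, 1.0)
                phi = 2.0 * np.pi * rng.random(e0.size)
                d_old = d[is_compton]
                d_new = _rotate(d_old, cos_t, phi)
                e_electron = e0 * (1.0 - eps)
                # electron direction from momentum conservation
                pe = e0[:, None] * d_old - (e0 * eps)[:, None] * d_new
                pe_norm = np.linalg.norm(pe, axis=1, keepdims=True)
                pe = np.where(pe_norm > 1e-12, pe / np.maximum(pe_norm, 1e-300), d_old)
                deposit_electrons(pos[is_compton], pe,
                                  e_electron * weight[is_compton],
                                  pid[is_compton], e_electron)
                d[is_compton] = d_new
                energy[is_compton] = e0 * eps

            # retire photons below threshold (or the table floor): local deposit
            survive = is_coh | is_compton
            low = survive & (energy < max(deposit_threshold, _PHOTON_FLOOR_KEV))
            if low.any():
                scorer.deposit(pos[low], energy[low] * weight[low], pid[low])
            cont = survive & ~low
            pos, d, energy, weight, pid = pos[cont], d[cont], energy[cont], weight[cont], pid[cont]

        if energy.size:  # generation cap: force local deposit, keeping the ledger exact
            scorer.deposit(pos, energy * weight, pid)

    grid = scorer.grid.reshape(mesh.shape)
    if n_batches > 1:
        bsum = scorer.batch_grid.reshape((n_batches,) + mesh.shape)
        unc = 1.96 * np.std(bsum, axis=0, ddof=1) * math.sqrt(n_batches)
    else:
        unc = np.zeros_like(grid)

    return DoseGrid(
        mesh=mesh,
        phantom=phantom,
        energy_deposit=grid,
        energy_uncertainty=unc,
        n_primaries=n,
        energy_in=float(e_in.sum()),
        energy_deposited_total=float(scorer.e_dep.sum()),
        energy_escaped=float(scorer.e_esc.sum()),
        provenance={
            "seed": seed,
            "electron_mode": electron_mode,
            "resampled": resampled,
            "material": phantom.material,
            "scan_field_height_mm": scan.field_height,
            "deposit_threshold_keV": deposit_threshold,
        },
        history_in=e_in if keep_history_ledger else None,
        history_deposited=scorer.e_dep if keep_history_ledger else None,
        history_escaped=scorer.e_esc if keep_history_ledger else None,
    )


# ---------------------------------------------------------------------------
# Dose grid input/output
# ---------------------------------------------------------------------------


def save_dose_grid(path, grid: DoseGrid) -> None:
    """Write a dose grid to HDF5 with geometry and provenance attributes."""
    import h5py

    with h5py.File(str(path), "w") as fh:
        fh.create_dataset("energy_deposit_keV", data=grid.energy_deposit)
        fh.create_dataset("energy_uncertainty_keV", data=grid.energy_uncertainty)
        if grid.dose is not None:
            fh.create_dataset("dose_Gy", data=grid.dose)
            fh.create_dataset("uncertainty_Gy", data=grid.uncertainty)
        for ax, name in enumerate(("x", "y", "z")):
            fh.create_dataset(f"edges_{name}_mm", data=grid.mesh.edges(ax))
        fh.attrs["voxel_size_mm"] = grid.mesh.voxel_size
        fh.attrs["extent_mm"] = grid.mesh.extent
        fh.attrs["offset_mm"] = grid.mesh.offset
        fh.attrs["phantom_dimensions_mm"] = grid.phantom.dimensions
        fh.attrs["phantom_material"] = grid.phantom.material
        fh.attrs["n_primaries"] = grid.n_primaries
        fh.attrs["energy_in_keV"] = grid.energy_in
        fh.attrs["energy_deposited_keV"] = grid.energy_deposited_total
        fh.attrs["energy_escaped_keV"] = grid.energy_escaped
        for k, v in grid.provenance.items():
            fh.attrs[f"prov_{k}"] = v


def load_dose_grid(path) -> DoseGrid:
    import h5py

    with h5py.File(str(path), "r") as fh:
        mesh = ScoringMesh(voxel_size=tuple(fh.attrs["voxel_size_mm"]),
                           extent=tuple(fh.attrs["extent_mm"]),
                           offset=tuple(fh.attrs["offset_mm"]))
        phantom = PhantomConfig(dimensions=tuple(fh.attrs["phantom_dimensions_mm"]),
                                material=str(fh.attrs["phantom_material"]))
        grid = DoseGrid(
            mesh=mesh,
            phantom=phantom,
            energy_deposit=fh["energy_deposit_keV"][:],
            energy_uncertainty=fh["energy_uncertainty_keV"][:],
            n_primaries=int(fh.attrs["n_primaries"]),
            energy_in=float(fh.attrs["energy_in_keV"]),
            energy_deposited_total=float(fh.attrs["energy_deposited_keV"]),
            energy_escaped=float(fh.attrs["energy_escaped_keV"]),
            provenance={k[5:]: v for k, v in fh.attrs.items() if k.startswith("prov_")},
        )
        if "dose_Gy" in fh:
            grid.dose = fh["dose_Gy"][:]
            grid.uncertainty = fh["uncertainty_Gy"][:]
    return grid
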