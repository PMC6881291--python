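"""Analytical wiggler x-ray source model.

The storage-ring wiggler is modelled as a sequence of bending-magnet sources:
the sinusoidal field B(z) = B_peak sin(2 pi z / lambda) is sampled along the
magnetic length and every sample radiates the universal bending-magnet
(Schwinger) spectrum for its local field,

    d2N / (dE dz)  proportional to  |B(z)| G1(E / E_c(B)) / E,
    G1(y) = y * integral_y^inf K_{5/3}(x) dx,

with critical energy E_c[keV] = 0.665 B[T] E_ring[GeV]^2.  Because the
downstream beam-defining aperture subtends a horizontal fan that is narrow
compared with the wiggler deflection angle K/gamma, only trajectory points
whose instantaneous direction falls inside the fan contribute to the
transported beam; the pole sum therefore carries an optional horizontal
acceptance mask (emission at angle theta comes from points where the electron
direction equals theta, i.e. where |B| = B_peak sqrt(1 - (theta gamma/K)^2)).

Photon sampling draws energies from the binned spectrum, vertical angles from
the energy-dependent synchrotron opening (a Gaussian of RMS ~ (0.57/gamma)
(E_c/E)^0.43) and horizontal angles uniformly across the accepted fan, with
linear polarisation in the orbital plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import kve, ndtr, ndtri

__all__ = [
    "MachineConfig",
    "WigglerConfig",
    "Spectrum",
    "DivergenceModel",
    "PhotonBatch",
    "critical_energy",
    "source_spectrum",
    "sample_photons",
    "default_energy_grid",
]

_MEC2_GEV = 0.000510999
_ELEMENTARY_CHARGE = 1.602176634e-19  # C


@dataclass(frozen=True)
class MachineConfig:
    """Storage-ring parameters."""

    ring_current: float = 200.1  # mA, continuous top-up
    ring_energy: float = 3.032  # GeV

    def __post_init__(self):
        if self.ring_current <= 0 or self.ring_energy <= 0:
            raise ValueError("ring current and energy must be positive")

    @property
    def gamma(self) -> float:
        return self.ring_energy / _MEC2_GEV


@dataclass(frozen=True)
class WigglerConfig:
    """Insertion-device parameters."""

    peak_field: float = 3.0  # T
    period: float = 52.0  # mm
    n_periods: int = 30
    magnetic_length: float = 1.56  # m
    min_photon_energy: float = 40.0  # keV, photons below are not produced

    def __post_init__(self):
        if self.peak_field <= 0:
            raise ValueError("peak field must be positive")
        if self.min_photon_energy < 0:
            raise ValueError("minimum photon energy cannot be negative")
        if abs(self.period * self.n_periods / 1000.0 - self.magnetic_length) > 0.05 * self.magnetic_length:
            raise ValueError("period * n_periods inconsistent with magnetic length (>5%)")

    def deflection_parameter(self, ring_energy_gev: float) -> float:
        """Wiggler K; the maximum trajectory angle is K/gamma."""
        return 0.0934 * self.period * self.peak_field


@dataclass
class Spectrum:
    """Binned photon fluence versus energy.

    fluence_per_bin is photons per second per bin through the modelled
    aperture when ``absolute`` is true, otherwise arbitrary units.
    """

    energy_bin_edges: np.ndarray
    fluence_per_bin: np.ndarray
    label: str = ""
    absolute: bool = False

    def __post_init__(self):
        self.energy_bin_edges = np.asarray(self.energy_bin_edges, dtype=float)
        self.fluence_per_bin = np.asarray(self.fluence_per_bin, dtype=float)
        if self.energy_bin_edges.ndim != 1 or self.energy_bin_edges.size < 2:
            raise ValueError("need at least one energy bin")
        if np.any(np.diff(self.energy_bin_edges) <= 0):
            raise ValueError("energy bin edges must be strictly increasing")
        if self.fluence_per_bin.shape != (self.energy_bin_edges.size - 1,):
            raise ValueError("fluence array does not match bin edges")
        if np.any(self.fluence_per_bin < 0):
            raise ValueError("fluence must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.energy_bin_edges[:-1] + self.energy_bin_edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.energy_bin_edges)

    @property
    def total(self) -> float:
        return float(self.fluence_per_bin.sum())

    def scaled(self, factor: float, label: str | None = None) -> "Spectrum":
        return Spectrum(self.energy_bin_edges.copy(), self.fluence_per_bin * factor,
                        label if label is not None else self.label, self.absolute)

    # -- two-column text round trip ------------------------------------
    def save_txt(self, path, **provenance) -> None:
        with open(path, "w") as fh:
            fh.write(f"# label: {self.label}\n")
            fh.write(f"# absolute: {self.absolute}\n")
            for key, val in provenance.items():
                fh.write(f"# {key}: {val}\n")
            fh.write("# columns: energy_keV fluence (row i covers [edge_i, edge_i+1))\n")
            fh.write(f"# first_edge_keV: {float(self.energy_bin_edges[0])!r}\n")
            for edge, flu in zip(self.energy_bin_edges[1:], self.fluence_per_bin):
                fh.write(f"{float(edge)!r}\t{float(flu)!r}\n")

    @classmethod
    def load_txt(cls, path) -> "Spectrum":
        label, absolute, first_edge = "", False, None
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line[1:].strip()
                    if body.startswith("label:"):
                        label = body.split(":", 1)[1].strip()
                    elif body.startswith("absolute:"):
                        absolute = body.split(":", 1)[1].strip() == "True"
                    elif body.startswith("first_edge_keV:"):
                        first_edge = float(body.split(":", 1)[1])
                    continue
                parts = line.split()
                rows.append((float(parts[0]), float(parts[1])))
        if first_edge is None or not rows:
            raise ValueError(f"malformed spectrum file {path}")
        edges = np.concatenate([[first_edge], [r[0] for r in rows]])
        return cls(edges, np.array([r[1] for r in rows]), label=label, absolute=absolute)


def critical_energy(machine: MachineConfig, field_t: float) -> float:
    """Critical energy of bending-magnet radiation, keV.

    E_c = 0.665 * B[T] * E_ring[GeV]^2.
    """
    if field_t <= 0:
        raise ValueError("magnetic field must be positive")
    if machine.ring_energy <= 0:
        raise ValueError("ring energy must be positive")
    return 0.665 * field_t * machine.ring_energy**2


# ---------------------------------------------------------------------------
# Universal bending-magnet function G1(y) = y * int_y^inf K_{5/3}(x) dx.
# Evaluated once on a log grid via an exponentially scaled Bessel quadrature
# (kve avoids under/overflow), then interpolated through the smooth factor
# H(y) = e^y * int_y^inf K_{5/3} dx, so G1 = y e^{-y} H(y).
# ---------------------------------------------------------------------------

_G1_CACHE: dict[str, np.ndarray] = {}


def _h_table():
    if "y" not in _G1_CACHE:
        y = np.geomspace(0.01, 120.0, 800)
        s = np.concatenate([[0.0], np.geomspace(1e-8, 120.0, 6000)])
        integrand = kve(5.0 / 3.0, y[:, None] + s[None, :]) * np.exp(-s)[None, :]
        _G1_CACHE["y"] = y
        _G1_CACHE["lnH"] = np.log(np.trapezoid(integrand, s, axis=1))
    return _G1_CACHE["y"], _G1_CACHE["lnH"]


def schwinger_g1(y) -> np.ndarray:
    """G1(y) for the bending-magnet spectral shape."""
    y_arr = np.atleast_1d(np.asarray(y, dtype=float))
    yg, lnh = _h_table()
    h = np.exp(np.interp(np.log(np.clip(y_arr, yg[0], yg[-1])), np.log(yg), lnh))
    with np.errstate(under="ignore"):
        out = y_arr * np.exp(-np.clip(y_arr, None, 700.0)) * h
    out[y_arr >= 120.0] = 0.0
    if np.ndim(y) == 0:
        return float(out[0])
    return out


def default_energy_grid(e_min: float = 40.0, e_max: float = 300.0, step: float = 0.5) -> np.ndarray:
    """Default spectrum binning: 0.5 keV bins over the treatment-beam range."""
    n = int(round((e_max - e_min) / step))
    return e_min + step * np.arange(n + 1)


def source_spectrum(
    machine: MachineConfig,
    wiggler: WigglerConfig,
    bins: np.ndarray | None = None,
    *,
    n_z_samples: int = 256,
    horizontal_acceptance: float | None = None,
    label: str | None = None,
) -> Spectrum:
    """Pole-sum wiggler spectrum on the given energy grid.

    horizontal_acceptance is the half-angle (rad) of the accepted horizontal
    fan; None integrates over the full wiggler emission.  Fluence is photons
    per second through the fan (vertically integrated), linear in ring
    current and in the number of periods.
    """
    if bins is None:
        bins = default_energy_grid(max(wiggler.min_photon_energy, 1.0))
    bins = np.asarray(bins, dtype=float)
    if bins.size < 2:
        raise ValueError("energy bin grid must contain at least one bin")
    centers = 0.5 * (bins[:-1] + bins[1:])
    widths = np.diff(bins)

    # sample |B| over one period; phases cover a quarter period by symmetry
    phase = (np.arange(n_z_samples) + 0.5) / n_z_samples * 2.0 * np.pi
    b_local = wiggler.peak_field * np.abs(np.sin(phase))
    if horizontal_acceptance is not None:
        k_defl = wiggler.deflection_parameter(machine.ring_energy)
        theta_max = k_defl / machine.gamma
        traj_angle = theta_max * np.cos(phase)
        keep = np.abs(traj_angle) <= horizontal_acceptance
        b_local = b_local[keep]
    b_local = b_local[b_local > 1e-9]
    if b_local.size == 0:
        raise ValueError("horizontal acceptance excludes the whole pole sum")

    dz = wiggler.magnetic_length / (wiggler.n_periods * n_z_samples)  # m per z sample
    # photons / s / keV / m of trajectory:
    #   2.457e13 * E_GeV * I_A * G1 / (0.001 E_keV)  per mrad, times
    #   dtheta/dz = 1000 * B / (3.3356 * E_GeV) mrad/m
    const = 2.457e13 * (machine.ring_current * 1e-3) * 1000.0 / (0.001 * 3.3356)
    ec = 0.665 * b_local * machine.ring_energy**2
    y = centers[:, None] / ec[None, :]
    g1 = schwinger_g1(y.ravel()).reshape(y.shape)
    flux_density = const * (g1 * b_local[None, :]).sum(axis=1) / centers
    fluence = flux_density * widths * dz * wiggler.n_periods
    fluence[centers < wiggler.min_photon_energy] = 0.0

    if label is None:
        label = f"wiggler B={wiggler.peak_field:g} T, I={machine.ring_current:g} mA (raw source)"
    return Spectrum(bins, fluence, label=label, absolute=True)


# ---------------------------------------------------------------------------
# Photon sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DivergenceModel:
    """Angular envelope of the source as accepted by the beamline.

    The vertical RMS angle uses the standard synchrotron-radiation opening
    (0.57/gamma)(E_c/E)^0.43; the horizontal fan is flat.  A vertical window
    (radians, symmetric about the orbit plane) restricts sampling to the
    angles a downstream slit can accept; the per-batch acceptance fraction is
    recorded so absolute fluence bookkeeping survives the restriction.
    """

    gamma: float
    critical_energy_kev: float
    horizontal_half_angle: float  # rad
    vertical_scale: float = 0.57
    vertical_exponent: float = 0.43
    vertical_window: float | None = None  # rad, half-height of sampling window

    def vertical_sigma(self, energy_kev) -> np.ndarray:
        e = np.asarray(energy_kev, dtype=float)
        return (self.vertical_scale / self.gamma) * (self.critical_energy_kev / e) ** self.vertical_exponent


@dataclass
class PhotonBatch:
    """Photons at the source plane: energies, small-angle directions, weights.

    Positions are implicitly (0, 0) at the source (point-source model);
    dy/dz are horizontal/vertical direction tangents.
    """

    energy: np.ndarray
    dy: np.ndarray
    dz: np.ndarray
    weight: np.ndarray
    acceptance: float = 1.0  # fraction of full vertical emission represented

    def __len__(self) -> int:
        return self.energy.size

    @property
    def direction(self) -> np.ndarray:
        """(n, 3) unit vectors, x along the beam axis."""
        d = np.stack([np.ones_like(self.dy), self.dy, self.dz], axis=1)
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    @property
    def polarisation(self) -> np.ndarray:
        """(n, 3) unit vectors in the orbital (x-y) plane, orthogonal to direction."""
        d = self.direction
        yhat = np.zeros_like(d)
        yhat[:, 1] = 1.0
        pol = yhat - d * d[:, 1:2]
        return pol / np.linalg.norm(pol, axis=1, keepdims=True)


def sample_photons(
    spectrum: Spectrum,
    n: int,
    seed: int | np.random.Generator,
    divergence_model: DivergenceModel,
) -> PhotonBatch:
    """Draw n photons from the spectrum with the stated angular envelope."""
    if n <= 0:
        raise ValueError("number of photons must be positive")
    if spectrum.total <= 0:
        raise ValueError("cannot sample from an all-zero spectrum")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    p = spectrum.fluence_per_bin / spectrum.total
    idx = rng.choice(p.size, size=n, p=p)
    lo = spectrum.energy_bin_edges[idx]
    hi = spectrum.energy_bin_edges[idx + 1]
    energy = lo + (hi - lo) * rng.random(n)

    dy = divergence_model.horizontal_half_angle * (2.0 * rng.random(n) - 1.0)

    sigma = divergence_model.vertical_sigma(energy)
    acceptance = 1.0
    if np.all(sigma == 0):
        dz = np.zeros(n)
    elif divergence_model.vertical_window is None:
        dz = sigma * rng.standard_normal(n)
    else:
        # truncated-normal importance sampling inside the aperture window
        b = divergence_model.vertical_window / sigma
        cdf_hi = ndtr(b)
        cdf_lo = 1.0 - cdf_hi
        u = cdf_lo + (cdf_hi - cdf_lo) * rng.random(n)
        dz = sigma * ndtri(u)
        acceptance = float(np.mean(cdf_hi - cdf_lo))

    return PhotonBatch(energy=energy, dy=dy, dz=dz, weight=np.ones(n), acceptance=acceptance)
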