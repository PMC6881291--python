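"""Beamline transport: filtration, apertures, collimation, phase-space files.

Photons travel along +X; Y is horizontal (the microbeam lateral direction)
and Z vertical (the scan direction).  Filtration is applied at the spectrum
level as Beer-Lambert transmission through the cumulative paddle stack
(scatter from the filters into the narrow accepted cone at 33.4 m is
negligible).  Collimation ray-traces sampled photons from the source point
through the beam-defining aperture (BDA), the conformal mask, and the
multi-slit collimator (MSC), recording survivors in a phase space at the
scoring plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .attenuation import get_material, mass_attenuation, UnknownMaterialError
from .errors import ConfigurationError, GeometryError, PSFFormatError
from .source import DivergenceModel, PhotonBatch, Spectrum

__all__ = [
    "FilterElement",
    "ApertureConfig",
    "PhaseSpace",
    "PSFRecord",
    "filtration_stack",
    "transmit",
    "vertical_acceptance",
    "spectrum_stats",
    "percent_difference",
    "collimate",
    "write_psf",
    "read_psf",
    "iter_psf",
]

#: default longitudinal positions along the beamline, metres from the source
BDA_DISTANCE_M = 32.9
MASK_DISTANCE_M = 33.4
SCORING_PLANE_M = 33.4

STANDARD_BDA_HEIGHTS_MM = (0.532, 1.053, 2.014)
STANDARD_MASK_WIDTHS_MM = (5.0, 10.0, 20.0)


@dataclass(frozen=True)
class FilterElement:
    """One filtration paddle: material, thickness and tilt.

    A paddle tilted at angle ``tilt`` (degrees, 90 = normal incidence)
    presents an effective path length nominal_thickness / sin(tilt).
    """

    material: str
    nominal_thickness: float  # mm
    tilt: float = 90.0  # degrees

    def __post_init__(self):
        if self.nominal_thickness < 0:
            raise ConfigurationError("filter thickness cannot be negative")
        if not 0 < self.tilt <= 90:
            raise ConfigurationError("filter tilt must be in (0, 90] degrees")

    @property
    def effective_thickness(self) -> float:
        """Path length through the paddle, mm."""
        return self.nominal_thickness / math.sin(math.radians(self.tilt))


def filtration_stack(field_strength_t: float) -> list[FilterElement]:
    """The standard paddle stacks for the 3 T and 2 T treatment beams."""
    common = [
        FilterElement("graphene", 0.45, 90.0),
        FilterElement("hd_graphite", 5.0, 45.0),
        FilterElement("hd_graphite", 10.0, 45.0),
        FilterElement("copper", 1.0, 45.0),
    ]
    if abs(field_strength_t - 3.0) < 1e-9:
        return common + [FilterElement("copper", 1.0, 45.0)]
    if abs(field_strength_t - 2.0) < 1e-9:
        return common + [FilterElement("aluminium", 2.0, 45.0)]
    raise ConfigurationError(f"no standard filtration stack for {field_strength_t} T")


def transmit(spectrum: Spectrum, filters: list[FilterElement]) -> Spectrum:
    """Beer-Lambert transmission of the spectrum through a paddle stack."""
    energies = spectrum.centers
    transmission = np.ones_like(energies)
    names = []
    for f in filters:
        try:
            mat = get_material(f.material)
        except UnknownMaterialError:
            raise ConfigurationError(f"unknown filter material {f.material!r}") from None
        mu = mass_attenuation(mat, energies) * mat.density  # 1/cm
        transmission = transmission * np.exp(-mu * f.effective_thickness * 0.1)
        names.append(f"{f.material} {f.effective_thickness:.2f} mm")
    label = spectrum.label + (" | filtered: " + ", ".join(names) if names else "")
    return Spectrum(spectrum.energy_bin_edges.copy(), spectrum.fluence_per_bin * transmission,
                    label=label, absolute=spectrum.absolute)


def vertical_acceptance(
    spectrum: Spectrum,
    divergence: DivergenceModel,
    bda_height_mm: float,
    distance_m: float = BDA_DISTANCE_M,
) -> Spectrum:
    """Fold the BDA's vertical angular acceptance into the spectrum.

    The vertical synchrotron opening angle shrinks with photon energy, so a
    fixed slit accepts a larger fraction of hard photons than of soft ones;
    the spectrum a downstream plane sees is correspondingly hardened.
    """
    from scipy.special import ndtr

    if bda_height_mm <= 0:
        raise ConfigurationError("BDA height must be positive")
    sigma_mm = divergence.vertical_sigma(spectrum.centers) * distance_m * 1e3
    frac = 2.0 * ndtr(0.5 * bda_height_mm / sigma_mm) - 1.0
    return Spectrum(spectrum.energy_bin_edges.copy(), spectrum.fluence_per_bin * frac,
                    label=spectrum.label + f" | BDA {bda_height_mm:g} mm vertical acceptance",
                    absolute=spectrum.absolute)


def spectrum_stats(spectrum: Spectrum) -> tuple[float, float, float]:
    """(mode_energy, mean_energy, total_fluence) of a binned spectrum.

    The mode is refined by parabolic interpolation through the peak bin and
    its neighbours; the mean is the fluence-weighted mean energy.
    """
    f = spectrum.fluence_per_bin
    if spectrum.total <= 0:
        raise ConfigurationError("spectrum statistics undefined for an all-zero spectrum")
    e = spectrum.centers
    mean = float((e * f).sum() / f.sum())
    i = int(np.argmax(f))
    mode = float(e[i])
    if 0 < i < f.size - 1:
        denom = f[i - 1] - 2.0 * f[i] + f[i + 1]
        if denom < 0:
            mode = float(e[i] + 0.5 * (f[i - 1] - f[i + 1]) / denom * (e[i + 1] - e[i]))
    return mode, mean, float(f.sum())


def percent_difference(a: float, b: float) -> float:
    """Mean-referenced percent difference, 100 |a-b| / ((a+b)/2)."""
    if a <= 0 or b <= 0:
        raise ValueError("percent difference requires positive inputs")
    return 100.0 * abs(a - b) / (0.5 * (a + b))


# ---------------------------------------------------------------------------
# Apertures and collimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ApertureConfig:
    """Beam-defining aperture, conformal mask and multi-slit collimator."""

    bda_height: float = 1.053  # mm, one of the stocked apertures
    bda_width: float = 30.0  # mm
    mask_width: float = 20.0  # mm, one of the stocked conformal masks
    msc_enabled: bool = False
    msc_slit_width: float = 50.0  # um
    msc_pitch: float = 400.0  # um
    septa_transmission: float = 0.0  # fraction carried through the septa

    def __post_init__(self):
        if not any(abs(self.bda_height - h) < 1e-6 for h in STANDARD_BDA_HEIGHTS_MM):
            raise ConfigurationError(
                f"BDA height {self.bda_height} mm is not stocked; available: {STANDARD_BDA_HEIGHTS_MM}")
        if not any(abs(self.mask_width - w) < 1e-6 for w in STANDARD_MASK_WIDTHS_MM):
            raise ConfigurationError(
                f"conformal mask width {self.mask_width} mm is not stocked; available: {STANDARD_MASK_WIDTHS_MM}")
        if self.msc_slit_width >= self.msc_pitch:
            raise ConfigurationError("MSC slit width must be smaller than the pitch")
        if min(self.bda_height, self.bda_width, self.mask_width, self.msc_slit_width, self.msc_pitch) <= 0:
            raise ConfigurationError("all aperture dimensions must be positive")
        if not 0.0 <= self.septa_transmission <= 1.0:
            raise ConfigurationError("septa transmission must be a fraction in [0, 1]")


@dataclass
class PhaseSpace:
    """Per-photon state at the scoring plane (the PSF contents).

    Positions y, z in mm (plane-local, origin on the beam axis); dy, dz are
    direction cosines with dx reconstructed as sqrt(1 - dy^2 - dz^2);
    polarisation components likewise with pol_x reconstructed from
    orthogonality.
    """

    y: np.ndarray
    z: np.ndarray
    dy: np.ndarray
    dz: np.ndarray
    energy: np.ndarray
    pol_y: np.ndarray
    pol_z: np.ndarray
    weight: np.ndarray
    distance_m: float = SCORING_PLANE_M
    acceptance: float = 1.0
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.energy.size

    @property
    def dx(self) -> np.ndarray:
        return np.sqrt(np.maximum(1.0 - self.dy**2 - self.dz**2, 0.0))

    def record(self, i: int) -> "PSFRecord":
        return PSFRecord(self.y[i], self.z[i], self.dy[i], self.dz[i],
                         self.energy[i], self.pol_y[i], self.pol_z[i], self.weight[i])

    def concatenated(self, other: "PhaseSpace") -> "PhaseSpace":
        if abs(other.distance_m - self.distance_m) > 1e-9:
            raise GeometryError("cannot merge phase spaces scored at different planes")
        return PhaseSpace(
            *(np.concatenate([getattr(self, k), getattr(other, k)])
              for k in ("y", "z", "dy", "dz", "energy", "pol_y", "pol_z", "weight")),
            distance_m=self.distance_m,
            acceptance=self.acceptance,
            provenance=self.provenance,
        )


@dataclass(frozen=True)
class PSFRecord:
    y: float
    z: float
    dy: float
    dz: float
    energy: float
    pol_y: float
    pol_z: float
    weight: float


def collimate(
    photons: PhotonBatch,
    apertures: ApertureConfig,
    scoring_plane_distance: float = SCORING_PLANE_M,
    *,
    bda_distance: float = BDA_DISTANCE_M,
    mask_distance: float = MASK_DISTANCE_M,
) -> PhaseSpace:
    """Ray-trace a photon batch through the apertures to the scoring plane.

    Photons outside the BDA or conformal-mask openings are removed; photons
    striking the MSC septa are removed (or carried with attenuated weight when
    septa_transmission > 0).  Survivors become PSF records.
    """
    if scoring_plane_distance < max(bda_distance, mask_distance) - 1e-12:
        raise GeometryError("scoring plane lies upstream of the last aperture")

    dy, dz = photons.dy, photons.dz
    energy, weight = photons.energy, photons.weight.copy()

    # BDA (height and width)
    y_bda = dy * bda_distance * 1e3
    z_bda = dz * bda_distance * 1e3
    keep = (np.abs(y_bda) <= 0.5 * apertures.bda_width) & (np.abs(z_bda) <= 0.5 * apertures.bda_height)

    # conformal mask (width only; the field height is set by the scan)
    y_mask = dy * mask_distance * 1e3
    keep &= np.abs(y_mask) <= 0.5 * apertures.mask_width

    dy, dz, energy, weight = dy[keep], dz[keep], energy[keep], weight[keep]
    y_sc = dy * scoring_plane_distance * 1e3
    z_sc = dz * scoring_plane_distance * 1e3

    if apertures.msc_enabled:
        pitch = apertures.msc_pitch * 1e-3  # mm
        half_slit = 0.5 * apertures.msc_slit_width * 1e-3
        off = np.abs((y_sc + 0.5 * pitch) % pitch - 0.5 * pitch)
        in_slit = off <= half_slit
        if apertures.septa_transmission > 0.0:
            weight = np.where(in_slit, weight, weight * apertures.septa_transmission)
        else:
            y_sc, z_sc, dy, dz = y_sc[in_slit], z_sc[in_slit], dy[in_slit], dz[in_slit]
            energy, weight = energy[in_slit], weight[in_slit]

    # direction cosines from tangents
    norm = np.sqrt(1.0 + dy**2 + dz**2)
    cy, cz = dy / norm, dz / norm
    cx = 1.0 / norm
    # polarisation in the orbital plane, orthogonal to the direction
    py = cx**2 + cz**2
    px = -cy * cx
    pz = -cy * cz
    pnorm = np.sqrt(px**2 + py**2 + pz**2)

    return PhaseSpace(
        y=y_sc, z=z_sc, dy=cy, dz=cz, energy=energy,
        pol_y=py / pnorm, pol_z=pz / pnorm, weight=weight,
        distance_m=scoring_plane_distance,
        acceptance=photons.acceptance,
        provenance={
            "bda_height_mm": apertures.bda_height,
            "mask_width_mm": apertures.mask_width,
            "msc_enabled": apertures.msc_enabled,
        },
    )


# ---------------------------------------------------------------------------
# PSF input/output: HDF5 with a CSV fallback
# ---------------------------------------------------------------------------

_PSF_FIELDS = ("y", "z", "dy", "dz", "energy", "pol_y", "pol_z", "weight")


def write_psf(path, phase_space: PhaseSpace) -> None:
    """Write a phase space losslessly (HDF5 for .h5/.hdf5, else CSV text)."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as fh:
            for name in _PSF_FIELDS:
                key = "energy_keV" if name == "energy" else name
                fh.create_dataset(key, data=getattr(phase_space, name))
            fh.attrs["distance_m"] = phase_space.distance_m
            fh.attrs["acceptance"] = phase_space.acceptance
            for k, v in phase_space.provenance.items():
                fh.attrs[k] = v
    else:
        with open(path, "w") as fh:
            fh.write(f"# distance_m: {phase_space.distance_m!r}\n")
            fh.write(f"# acceptance: {phase_space.acceptance!r}\n")
            for k, v in phase_space.provenance.items():
                fh.write(f"# {k}: {v}\n")
            fh.write("# columns: " + ",".join(_PSF_FIELDS) + "\n")
            cols = [getattr(phase_space, n) for n in _PSF_FIELDS]
            for row in zip(*cols):
                fh.write(",".join(repr(float(v)) for v in row) + "\n")


def _read_csv_psf(path):
    meta, rows = {}, []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            parts = line.split(",")
            if len(parts) != len(_PSF_FIELDS):
                raise PSFFormatError(f"malformed PSF record at line {lineno} of {path}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise PSFFormatError(f"unparseable PSF record at line {lineno} of {path}") from None
    if not rows:
        raise PSFFormatError(f"PSF file {path} contains no records")
    arr = np.asarray(rows)
    return meta, {n: arr[:, i] for i, n in enumerate(_PSF_FIELDS)}


def read_psf(path) -> PhaseSpace:
    """Read a phase space written by write_psf."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        try:
            with h5py.File(path, "r") as fh:
                data = {}
                for name in _PSF_FIELDS:
                    key = "energy_keV" if name == "energy" else name
                    data[name] = fh[key][:]
                attrs = dict(fh.attrs)
        except (OSError, KeyError) as exc:
            raise PSFFormatError(f"cannot read PSF file {path}: {exc}") from exc
        lengths = {v.size for v in data.values()}
        if len(lengths) != 1:
            raise PSFFormatError(f"inconsistent dataset lengths in {path}")
        return PhaseSpace(
            **data,
            distance_m=float(attrs.pop("distance_m", SCORING_PLANE_M)),
            acceptance=float(attrs.pop("acceptance", 1.0)),
            provenance={k: v for k, v in attrs.items()},
        )
    meta, data = _read_csv_psf(path)
    return PhaseSpace(
        **data,
        distance_m=float(meta.pop("distance_m", SCORING_PLANE_M)),
        acceptance=float(meta.pop("acceptance", 1.0)),
        provenance={k: v for k, v in meta.items() if k != "columns"},
    )


def iter_psf(path, chunk_size: int = 1_000_000):
    """Stream an HDF5 phase space in chunks of records (for very large files)."""
    import h5py

    path = str(path)
    with h5py.File(path, "r") as fh:
        n = fh["energy_keV"].shape[0]
        attrs = dict(fh.attrs)
        for start in range(0, n, chunk_size):
            sl = slice(start, min(start + chunk_size, n))
            data = {name: fh["energy_keV" if name == "energy" else name][sl] for name in _PSF_FIELDS}
            yield PhaseSpace(
                **data,
                distance_m=float(attrs.get("distance_m", SCORING_PLANE_M)),
                acceptance=float(attrs.get("acceptance", 1.0)),
                provenance={k: v for k, v in attrs.items() if k not in ("distance_m", "acceptance")},
            )
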