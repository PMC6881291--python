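"""Photon attenuation data and material definitions.

Mass attenuation coefficients (total, with coherent scattering) are embedded
on the standard tabulation grid used by the NIST XCOM / Hubbell & Seltzer
compilations and interpolated log-log, which is accurate to well under 1% for
the smooth Compton/photoelectric continuum between absorption edges.
Compounds are combined with the usual mass-weighted mixture rule.

For Monte Carlo transport the total coefficient is partitioned into
interaction channels as follows:

* incoherent (Compton): analytical Klein-Nishina cross section per electron,
  scaled by the electron density Z/A and a small tabulated binding
  (incoherent scattering function) correction for water-like media;
* coherent (Rayleigh): a tabulated per-gram coefficient for water, used for
  all low-Z phantom media (it is a few percent of the total and only changes
  the photon direction);
* photoelectric: the remainder, clamped at zero.

This keeps the exponential attenuation exactly consistent with the embedded
total coefficients while providing a physically reasonable channel split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Material",
    "MATERIALS",
    "get_material",
    "mass_attenuation",
    "klein_nishina_total",
    "UnknownMaterialError",
]


class UnknownMaterialError(KeyError):
    """Raised when a material name has no attenuation data."""


# ---------------------------------------------------------------------------
# Elemental mass attenuation coefficients mu/rho in cm^2/g (total, with
# coherent scattering), 10-300 keV.  Grid energies in keV.
# ---------------------------------------------------------------------------

_GRID = np.array([10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0, 150.0, 200.0, 300.0])

_ELEMENT_MU = {
    # symbol: (Z, A, mu/rho on _GRID)
    "H": (1, 1.008, [0.3854, 0.3764, 0.3695, 0.3570, 0.3458, 0.3355, 0.3260, 0.3091, 0.2944, 0.2651, 0.2429, 0.2112]),
    "C": (6, 12.011, [2.373, 0.8071, 0.4420, 0.2562, 0.2076, 0.1871, 0.1753, 0.1610, 0.1514, 0.1347, 0.1229, 0.1066]),
    "N": (7, 14.007, [3.879, 1.236, 0.6178, 0.3066, 0.2288, 0.1980, 0.1817, 0.1639, 0.1529, 0.1353, 0.1233, 0.1068]),
    "O": (8, 15.999, [5.952, 1.836, 0.8651, 0.3779, 0.2585, 0.2132, 0.1907, 0.1678, 0.1551, 0.1361, 0.1237, 0.1070]),
    "Al": (13, 26.982, [26.23, 7.955, 3.441, 1.128, 0.5685, 0.3681, 0.2778, 0.2018, 0.1704, 0.1378, 0.1223, 0.1042]),
    "Cl": (17, 35.453, [57.3, 17.9, 7.87, 2.498, 1.117, 0.6147, 0.3972, 0.2416, 0.1858, 0.1435, 0.1257, 0.1080]),
    "Ca": (20, 40.078, [93.41, 29.54, 13.06, 4.080, 1.830, 1.019, 0.6578, 0.3656, 0.2562, 0.1669, 0.1376, 0.1138]),
    "Cu": (29, 63.546, [215.9, 74.05, 33.79, 10.92, 4.862, 2.613, 1.593, 0.7630, 0.4584, 0.2217, 0.1559, 0.1119]),
    # W has its K edge at 69.5 keV; the grid below brackets it so the log-log
    # interpolation never crosses the edge from outside.
    "W": (74, 183.84, None),
}

_W_GRID = np.array([10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 69.52, 69.53, 80.0, 100.0, 150.0, 200.0, 300.0])
_W_MU = np.array([96.91, 139.5, 65.73, 22.73, 10.67, 5.949, 3.713, 2.552, 11.23, 7.810, 4.438, 1.581, 0.7844, 0.3238])

# Coherent (Rayleigh) mu/rho for water, cm^2/g, used per-gram for low-Z
# phantom media; a few percent of the total attenuation in this energy range.
_COHERENT_WATER = np.array([0.0980, 0.0700, 0.0550, 0.0380, 0.0262, 0.0200, 0.0153, 0.0093, 0.0054, 0.0026, 0.0016, 0.0008])

# Incoherent scattering-function correction for water-like media: ratio of
# the bound-electron incoherent cross section to the free-electron
# Klein-Nishina value.
_BINDING_GRID = np.array([10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0, 150.0, 200.0, 300.0])
_BINDING_FACTOR = np.array([0.65, 0.85, 0.92, 0.945, 0.960, 0.970, 0.985, 0.990, 0.995, 1.0, 1.0])

_RE2_CM2 = 7.9407877e-26  # classical electron radius squared, cm^2
_MEC2_KEV = 510.99895
_N_AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class Material:
    """A transport medium: mass composition and density.

    composition maps element symbols to mass fractions (summing to 1).
    """

    name: str
    density: float  # g/cm^3
    composition: dict[str, float] = field(default_factory=dict)

    @property
    def z_over_a(self) -> float:
        """Mean Z/A (electrons per atomic mass unit)."""
        return sum(w * _ELEMENT_MU[el][0] / _ELEMENT_MU[el][1] for el, w in self.composition.items())

    @property
    def electron_density(self) -> float:
        """Electrons per gram."""
        return _N_AVOGADRO * self.z_over_a


MATERIALS: dict[str, Material] = {
    "water": Material("water", 1.000, {"H": 0.111894, "O": 0.888106}),
    # Gammex RMI457 solid water, published elemental composition.
    "solid_water": Material(
        "solid_water", 1.046,
        {"H": 0.0809, "C": 0.6722, "N": 0.0240, "O": 0.1984, "Cl": 0.0013, "Ca": 0.0232},
    ),
    # Argon (1.3% by mass) approximated by its Z-neighbour chlorine.
    "air": Material("air", 1.205e-3, {"N": 0.755, "O": 0.2319, "Cl": 0.0129, "C": 0.000124}),
    "graphite": Material("graphite", 2.26, {"C": 1.0}),
    # Graphene filter paddle treated as carbon at graphite density.
    "graphene": Material("graphene", 2.26, {"C": 1.0}),
    "hd_graphite": Material("hd_graphite", 2.10, {"C": 1.0}),
    "carbon": Material("carbon", 2.26, {"C": 1.0}),
    "aluminium": Material("aluminium", 2.699, {"Al": 1.0}),
    "aluminum": Material("aluminum", 2.699, {"Al": 1.0}),
    "copper": Material("copper", 8.960, {"Cu": 1.0}),
    "tungsten": Material("tungsten", 19.30, {"W": 1.0}),
    "tungsten_carbide": Material("tungsten_carbide", 15.63, {"W": 0.9387, "C": 0.0613}),
    "vacuum": Material("vacuum", 0.0, {}),
}
# Common shorthand
MATERIALS["cu"] = MATERIALS["copper"]
MATERIALS["al"] = MATERIALS["aluminium"]
MATERIALS["w"] = MATERIALS["tungsten"]
MATERIALS["wc"] = MATERIALS["tungsten_carbide"]


def get_material(name: str | Material) -> Material:
    if isinstance(name, Material):
        return name
    try:
        return MATERIALS[name.lower()]
    except KeyError:
        raise UnknownMaterialError(f"no attenuation data for material {name!r}") from None


def _loglog_interp(energy_kev, grid, values):
    e = np.asarray(energy_kev, dtype=float)
    out = np.exp(np.interp(np.log(e), np.log(grid), np.log(values)))
    return out


def _element_mu(symbol: str, energy_kev):
    if symbol == "W":
        return _loglog_interp(energy_kev, _W_GRID, _W_MU)
    _, _, mu = _ELEMENT_MU[symbol]
    return _loglog_interp(energy_kev, _GRID, np.asarray(mu))


def mass_attenuation(material: str | Material, energy_kev) -> np.ndarray:
    """Total mass attenuation coefficient mu/rho in cm^2/g.

    Valid for 10-300 keV; values outside the tabulated grid are extrapolated
    log-log (queries below ~5 keV should not be trusted and the transport
    code absorbs such photons locally instead).
    """
    mat = get_material(material)
    e = np.atleast_1d(np.asarray(energy_kev, dtype=float))
    if np.any(e <= 0):
        raise ValueError("photon energy must be positive")
    total = np.zeros_like(e)
    for el, w in mat.composition.items():
        if w:
            total += w * _element_mu(el, e)
    if np.isscalar(energy_kev) or np.ndim(energy_kev) == 0:
        return float(total[0])
    return total


def linear_attenuation(material: str | Material, energy_kev) -> np.ndarray:
    """Linear attenuation coefficient mu in 1/cm."""
    mat = get_material(material)
    return mass_attenuation(mat, energy_kev) * mat.density


def klein_nishina_total(energy_kev) -> np.ndarray:
    """Total Klein-Nishina cross section per electron, cm^2."""
    k = np.asarray(energy_kev, dtype=float) / _MEC2_KEV
    t1 = (1 + k) / k**2 * (2 * (1 + k) / (1 + 2 * k) - np.log1p(2 * k) / k)
    t2 = np.log1p(2 * k) / (2 * k)
    t3 = (1 + 3 * k) / (1 + 2 * k) ** 2
    return 2 * np.pi * _RE2_CM2 * (t1 + t2 - t3)


def partial_mass_attenuation(material: str | Material, energy_kev):
    """Channel split of the total coefficient.

    Returns (photoelectric, incoherent, coherent) mass attenuation
    coefficients in cm^2/g.  The incoherent channel is Klein-Nishina with a
    binding correction, the coherent channel uses the water per-gram table,
    and the photoelectric channel is the (clamped) remainder so the three
    always sum to the embedded total.
    """
    mat = get_material(material)
    e = np.atleast_1d(np.asarray(energy_kev, dtype=float))
    total = np.atleast_1d(mass_attenuation(mat, e))
    binding = np.interp(e, _BINDING_GRID, _BINDING_FACTOR)
    incoh = klein_nishina_total(e) * mat.electron_density * binding
    coh = _loglog_interp(e, _GRID, _COHERENT_WATER)
    incoh = np.minimum(incoh, total)
    coh = np.minimum(coh, np.maximum(total - incoh, 0.0))
    photo = np.maximum(total - incoh - coh, 0.0)
    return photo, incoh, coh
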