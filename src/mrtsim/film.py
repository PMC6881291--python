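"""Radiochromic film dosimetry protocol.

Implements the single-channel microscope-scan workflow: pre/post-irradiation
pixel correction with an optional white-field (flat-field) division, a
fourth-order pixel-to-dose calibration polynomial with a bounded validity
range, circular/rectangular region-of-interest statistics, a GUM-style
uncertainty budget (root-sum-square of type A/B components with a coverage
factor), and a synthetic film-image generator so the whole pipeline is
testable without scanner hardware.

Films are scanned at roughly one pixel per seven micrometres on an 8-bit
camera; the green channel carries the analysis (largest dynamic range at
comparable noise), red is supported, and the blue channel is refused as
unsuitable in this dose range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, ConfigurationError

__all__ = [
    "FilmImage",
    "CalibrationCurve",
    "UncertaintyBudget",
    "pixel_correct",
    "dose_from_pixel",
    "fit_calibration",
    "combine_uncertainty",
    "roi_mean",
    "synth_film",
    "read_tiff",
    "write_tiff",
]

_CHANNELS = ("red", "green", "blue")


def _quantise_8bit(x: np.ndarray) -> np.ndarray:
    """Round half away from zero and clip to the 8-bit range."""
    return np.clip(np.floor(np.abs(x) + 0.5) * np.sign(x), 0, 255).astype(np.uint8)


@dataclass
class FilmImage:
    """A single-channel 8-bit film scan."""

    pixels: np.ndarray
    pixel_pitch_um: float = 7.0
    channel: str = "green"
    role: str = "post"  # "pre" or "post" irradiation

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ConfigurationError("film pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.pixel_pitch_um <= 0:
            raise ConfigurationError("pixel pitch must be positive")
        if self.channel not in _CHANNELS:
            raise ConfigurationError(f"unknown channel {self.channel!r}")
        if self.channel == "blue":
            raise ConfigurationError(
                "the blue channel is unsuitable for dosimetry (poor sensitivity and reproducibility)")
        if self.role not in ("pre", "post"):
            raise ConfigurationError("film role must be 'pre' or 'post'")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class CalibrationCurve:
    """Dose(P) = a P^4 + b P^3 + c P^2 + d P + e over a bounded dose range.

    The polynomial is only meaningful on the pixel-value interval it was
    fitted over; `pixel_domain` is the monotone-increasing branch that maps
    onto `dose_range`, used for numerical inversion.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    dose_range: tuple[float, float] = (0.25, 64.0)
    channel: str = "green"

    @classmethod
    def default(cls) -> "CalibrationCurve":
        """The production green-channel curve for this scanning protocol."""
        return cls(a=1.15e-6, b=-3.21e-4, c=3.33e-2, d=-1.40, e=20.5)

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.e])

    def __call__(self, p):
        return np.polyval(self.coefficients, p)

    def _branch(self, n: int = 4096):
        """Monotone-increasing branch of the curve over pixel values 0-255."""
        p = np.linspace(0.0, 255.0, n)
        dose = self(p)
        i0 = int(np.argmin(dose))
        return p[i0:], dose[i0:]

    @property
    def pixel_domain(self) -> tuple[float, float]:
        p, dose = self._branch()
        lo = float(np.interp(self.dose_range[0], dose, p))
        hi = float(np.interp(self.dose_range[1], dose, p))
        return lo, hi

    def inverse(self, dose):
        """Pixel value on the monotone branch producing the given dose.

        Tabulated inversion polished by a few Newton steps (the result
        round-trips through the polynomial to ~1e-9 Gy away from the branch
        minimum, where the derivative vanishes).
        """
        dose = np.asarray(dose, dtype=float)
        p, d = self._branch()
        if np.any(dose < d[0] - 1e-9) or np.any(dose > d[-1] + 1e-9):
            raise AnalysisError("dose outside the invertible range of the calibration curve")
        out = np.interp(dose, d, p)
        deriv = np.polyder(self.coefficients)
        for _ in range(4):
            slope = np.polyval(deriv, out)
            step = np.where(np.abs(slope) > 1e-6, (np.polyval(self.coefficients, out) - dose)
                            / np.where(np.abs(slope) > 1e-6, slope, 1.0), 0.0)
            out = np.clip(out - step, p[0], p[-1])
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"a": self.a, "b": self.b, "c": self.c, "d": self.d, "e": self.e,
                       "dose_range": list(self.dose_range), "channel": self.channel}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        with open(path) as fh:
            data = json.load(fh)
        data["dose_range"] = tuple(data["dose_range"])
        return cls(**data)


@dataclass
class UncertaintyBudget:
    """GUM-style budget: named (value %, type) components and coverage factor."""

    components: list[tuple[str, float, str]]
    coverage_factor: float = 2.0

    @classmethod
    def film_protocol(cls) -> "UncertaintyBudget":
        """The single-channel film protocol budget (percent of pixel value)."""
        return cls(components=[
            ("film scan uniformity", 3.6, "A"),
            ("microscope light influence", 1.3, "A"),
            ("positioning reproducibility", 0.4, "A"),
            ("signal growth (24 +/- 2 h development)", 2.1, "B"),
            ("sheet uniformity", 0.6, "B"),
            ("reproducibility", 2.7, "B"),
        ])


def combine_uncertainty(budget: UncertaintyBudget) -> tuple[float, float]:
    """(combined, expanded) standard uncertainty in percent.

    Root-sum-square of the components; the expanded value multiplies by the
    coverage factor (k = 2 for ~95% coverage).
    """
    values = np.array([v for _, v, _ in budget.components], dtype=float)
    if np.any(values < 0):
        raise ValueError("uncertainty components cannot be negative")
    combined = float(np.sqrt((values**2).sum()))
    return combined, budget.coverage_factor * combined


def pixel_correct(post: FilmImage, pre: FilmImage, white_field: np.ndarray | None = None) -> np.ndarray:
    """Corrected pixel grid |P_post - P_pre| (float array).

    When a white-field map is supplied, both scans are first divided by the
    mean-normalised illumination field (flat-field correction for the radial
    non-uniformity of the microscope light).
    """
    if post.shape != pre.shape:
        raise ValueError(f"image dimensions differ: {post.shape} vs {pre.shape}")
    if post.channel != pre.channel:
        raise ValueError("pre and post scans must use the same colour channel")
    if abs(post.pixel_pitch_um - pre.pixel_pitch_um) > 1e-9:
        raise ValueError("pre and post scans must share the pixel pitch")
    a = post.pixels.astype(float)
    b = pre.pixels.astype(float)
    if white_field is not None:
        wf = np.asarray(white_field, dtype=float)
        if wf.shape != post.shape:
            raise ValueError("white-field map does not match the image dimensions")
        if np.any(wf <= 0):
            raise ValueError("white-field map must be strictly positive")
        wf = wf / wf.mean()
        a = a / wf
        b = b / wf
    return np.abs(a - b)


def dose_from_pixel(p, curve: CalibrationCurve):
    """Evaluate the calibration polynomial: (dose, reliable) arrays.

    `reliable` is False where the resulting dose falls outside the fitted
    dose range (e.g. valley doses below the calibration floor).
    """
    p_arr = np.asarray(p, dtype=float)
    dose = curve(p_arr)
    lo, hi = curve.dose_range
    reliable = (dose >= lo) & (dose <= hi)
    if np.ndim(p) == 0:
        return float(dose), bool(reliable)
    return dose, reliable


def fit_calibration(doses, corrected_pixels, dose_range=None, channel: str = "green",
                    weights=None):
    """Least-squares 4th-order fit of dose on corrected pixel value.

    Returns (CalibrationCurve, residuals).  Requires at least six calibration
    points spanning the range.  weights="relative" weights points by 1/dose,
    i.e. minimises relative residuals — advisable when the calibrated range
    spans more than two decades of dose, so the high-dose points do not
    dominate the absolute residual.
    """
    doses = np.asarray(doses, dtype=float)
    pix = np.asarray(corrected_pixels, dtype=float)
    if doses.size != pix.size:
        raise ValueError("doses and pixel values must have equal length")
    if doses.size < 6:
        raise AnalysisError(f"calibration fit needs at least 6 points, got {doses.size}")
    if isinstance(weights, str):
        if weights != "relative":
            raise ValueError(f"unknown weighting scheme {weights!r}")
        weights = 1.0 / np.maximum(doses, 1e-12)
    coeff = np.polyfit(pix, doses, 4, w=weights)
    curve = CalibrationCurve(*coeff,
                             dose_range=dose_range or (float(doses.min()), float(doses.max())),
                             channel=channel)
    residuals = doses - curve(pix)
    return curve, residuals


def roi_mean(image: FilmImage | np.ndarray, shape: str = "circle",
             size_mm: float = 10.0, centre: tuple[float, float] | None = None,
             pixel_pitch_um: float | None = None) -> float:
    """Mean pixel value inside a centred region of interest.

    shape "circle" uses a disc of diameter size_mm, "rectangle" a square of
    side size_mm; pixels count when their centres fall inside.  centre is
    (row, col) in pixels, defaulting to the image centre.
    """
    if isinstance(image, FilmImage):
        arr = image.pixels.astype(float)
        pitch = image.pixel_pitch_um
    else:
        arr = np.asarray(image, dtype=float)
        if pixel_pitch_um is None:
            raise ValueError("pixel_pitch_um required for bare arrays")
        pitch = pixel_pitch_um
    nr, nc = arr.shape
    cr, cc = centre if centre is not None else ((nr - 1) / 2.0, (nc - 1) / 2.0)
    half_px = 0.5 * size_mm * 1e3 / pitch
    if cr - half_px < -0.5 or cr + half_px > nr - 0.5 or cc - half_px < -0.5 or cc + half_px > nc - 0.5:
        raise ValueError("region of interest extends outside the image")
    rows = np.arange(nr)[:, None] - cr
    cols = np.arange(nc)[None, :] - cc
    if shape == "circle":
        mask = rows**2 + cols**2 <= half_px**2
    elif shape == "rectangle":
        mask = (np.abs(rows) <= half_px) & (np.abs(cols) <= half_px)
    else:
        raise ValueError(f"unknown ROI shape {shape!r}")
    return float(arr[mask].mean())


def synth_film(
    dose_map: np.ndarray,
    curve: CalibrationCurve,
    granularity_noise_pct: float = 0.0,
    illumination: np.ndarray | None = None,
    seed: int = 0,
    *,
    pre_level: int = 60,
    pixel_pitch_um: float = 7.0,
    channel: str = "green",
) -> tuple[FilmImage, FilmImage]:
    """Generate a (pre, post) synthetic scan pair for a dose map.

    The post image carries the numerically inverted calibration response on
    top of a uniform base level, modulated by the illumination field and a
    multiplicative Gaussian granularity noise (the 'grain' of the film at
    micrometre scan resolution).  Same seed, same images.
    """
    dose_map = np.asarray(dose_map, dtype=float)
    rng = np.random.default_rng(seed)
    signal = curve.inverse(dose_map)
    if granularity_noise_pct:
        signal = signal * (1.0 + granularity_noise_pct / 100.0 * rng.standard_normal(dose_map.shape))
    pre_float = np.full(dose_map.shape, float(pre_level))
    post_float = pre_float + signal
    if illumination is not None:
        illum = np.asarray(illumination, dtype=float)
        if illum.shape != dose_map.shape:
            raise ValueError("illumination field does not match the dose map")
        norm = illum / illum.mean()
        pre_float = pre_float * norm
        post_float = post_float * norm
    pre = FilmImage(_quantise_8bit(pre_float), pixel_pitch_um, channel, role="pre")
    post = FilmImage(_quantise_8bit(post_float), pixel_pitch_um, channel, role="post")
    return pre, post


# ---------------------------------------------------------------------------
# TIFF input/output
# ---------------------------------------------------------------------------


def write_tiff(image: FilmImage, path) -> None:
    import tifffile

    tifffile.imwrite(str(path), image.pixels)


def read_tiff(path, channel: str = "green", pixel_pitch_um: float = 7.0,
              role: str = "post") -> FilmImage:
    """Read an 8-bit scan; RGB images are reduced to the requested channel."""
    import tifffile

    data = tifffile.imread(str(path))
    if data.ndim == 3:
        try:
            data = data[..., _CHANNELS.index(channel)]
        except ValueError:
            raise ConfigurationError(f"unknown channel {channel!r}") from None
    return FilmImage(data, pixel_pitch_um, channel, role)
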