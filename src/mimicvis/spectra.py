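"""Wavelength-grid spectra, illuminants, and visual-pigment templates.

Everything downstream (quantum catches, camera simulation, the synthetic
generator) works on :class:`Spectrum` objects sampled on a shared
:class:`WavelengthGrid`. The default working grid is 300-700 nm at 1 nm,
which covers both the ultraviolet (320-380 nm) and visible (400-680 nm)
passbands of a UV-capable photography setup with margin on either side.

Receptor spectral sensitivities are reconstructed from their peak
wavelength with the Govardovskii A1 visual-pigment nomogram (alpha plus
beta band), the standard template when only a lambda-max is known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from .errors import ConfigurationError, RangeError

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "PigmentTemplateParams",
    "resample_spectrum",
    "pigment_template",
    "standard_illuminant",
    "trapezoid",
]

SPECTRUM_KINDS = ("reflectance", "illuminant", "sensitivity")


@dataclass(frozen=True)
class WavelengthGrid:
    """A closed, uniformly spaced wavelength interval in nanometres."""

    start_nm: float = 300.0
    stop_nm: float = 700.0
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.start_nm) and np.isfinite(self.stop_nm)
                and np.isfinite(self.step_nm)):
            raise RangeError("grid bounds and step must be finite")
        if self.start_nm >= self.stop_nm:
            raise RangeError(
                f"start_nm ({self.start_nm}) must be < stop_nm ({self.stop_nm})")
        if self.step_nm <= 0:
            raise RangeError("step_nm must be positive")
        n_steps = (self.stop_nm - self.start_nm) / self.step_nm
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise RangeError("step_nm must divide (stop_nm - start_nm) evenly")

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1
        return self.start_nm + self.step_nm * np.arange(n)

    def __len__(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    def contains(self, other: "WavelengthGrid") -> bool:
        return self.start_nm <= other.start_nm and self.stop_nm >= other.stop_nm


DEFAULT_GRID = WavelengthGrid()


@dataclass(frozen=True)
class Spectrum:
    """Values on a wavelength grid: reflectance, illuminant or sensitivity."""

    grid: WavelengthGrid
    values: np.ndarray
    kind: str = "reflectance"
    name: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.kind not in SPECTRUM_KINDS:
            raise ConfigurationError(
                f"unknown spectrum kind {self.kind!r}; valid: {SPECTRUM_KINDS}")
        if vals.shape != (len(self.grid),):
            raise RangeError(
                f"values length {vals.shape} does not match grid length {len(self.grid)}")
        if not np.all(np.isfinite(vals)):
            raise RangeError("spectrum values must be finite")
        if np.any(vals < 0):
            raise RangeError("spectrum values must be nonnegative")
        if self.kind == "reflectance" and np.any(vals > 1.5):
            raise RangeError("reflectance above 1.5 is outside the supported range")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def scaled(self, factor: float) -> "Spectrum":
        return replace(self, values=self.values * factor)


@dataclass(frozen=True)
class PigmentTemplateParams:
    """Constants of the A1 visual-pigment nomogram.

    Defaults are the published Govardovskii values; they are stored here so
    alternative templates (A2, species-specific refits) can be injected
    without touching any calling code. ``lambda_max`` is the only parameter
    a typical caller sets.
    """

    lambda_max: float
    # alpha band: 1 / (exp[A(a-x)] + exp[B(b-x)] + exp[C(c-x)] + D), x = lmax/lambda
    A: float = 69.7
    B: float = 28.0
    C: float = -14.9
    D: float = 0.674
    b: float = 0.922
    c: float = 1.104
    # a depends weakly on lambda_max: a = a0 + a1 * exp(-(lmax-300)^2 / a2)
    a0: float = 0.8795
    a1: float = 0.0459
    a2: float = 11940.0
    # beta band: A_beta * exp(-[(lambda - lm_beta)/b_beta]^2)
    beta_amplitude: float = 0.26
    beta_peak_intercept: float = 189.0
    beta_peak_slope: float = 0.315
    beta_width_intercept: float = -40.5
    beta_width_slope: float = 0.195

    def __post_init__(self) -> None:
        if not 300.0 <= self.lambda_max <= 700.0:
            raise RangeError(
                f"lambda_max {self.lambda_max} nm outside the supported 300-700 nm range")


def trapezoid(values: np.ndarray, grid: WavelengthGrid) -> float:
    """Trapezoidal integral of sampled values over the grid (exact for
    piecewise-linear integrands on a uniform grid)."""
    return float(np.trapezoid(np.asarray(values, float), dx=grid.step_nm))


def resample_spectrum(s: Spectrum, g: WavelengthGrid,
                      extrapolation: str | None = None) -> Spectrum:
    """Linearly interpolate a spectrum onto a new grid.

    Parameters
    ----------
    extrapolation
        ``None`` (default) requires ``g`` to lie inside the support of
        ``s`` and raises :class:`RangeError` otherwise; ``"zero"`` fills
        out-of-support wavelengths with 0; ``"hold"`` extends the edge
        values.
    """
    if s.grid == g:
        return s
    lam_in = s.wavelengths
    lam_out = g.wavelengths
    outside = (lam_out < lam_in[0] - 1e-9) | (lam_out > lam_in[-1] + 1e-9)
    if outside.any() and extrapolation is None:
        raise RangeError(
            f"target grid [{g.start_nm}, {g.stop_nm}] nm extends beyond the "
            f"spectrum's support [{lam_in[0]}, {lam_in[-1]}] nm; pass an "
            "extrapolation policy ('zero' or 'hold')")
    if extrapolation not in (None, "zero", "hold"):
        raise ConfigurationError(
            f"unknown extrapolation policy {extrapolation!r}; valid: 'zero', 'hold'")
    vals = np.interp(lam_out, lam_in, s.values)
    if extrapolation == "zero":
        vals = np.where(outside, 0.0, vals)
    vals = np.clip(vals, 0.0, None)
    return Spectrum(grid=g, values=vals, kind=s.kind, name=s.name)


def pigment_template(p: PigmentTemplateParams,
                     g: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """Absorbance template (alpha + beta band) for a pigment with the given
    peak wavelength, peak-normalized so that max(S) = 1."""
    if not (g.start_nm <= p.lambda_max <= g.stop_nm):
        raise RangeError(
            f"lambda_max {p.lambda_max} nm lies outside the grid "
            f"[{g.start_nm}, {g.stop_nm}] nm")
    lam = g.wavelengths
    x = p.lambda_max / lam
    a = p.a0 + p.a1 * np.exp(-((p.lambda_max - 300.0) ** 2) / p.a2)
    alpha = 1.0 / (np.exp(p.A * (a - x)) + np.exp(p.B * (p.b - x))
                   + np.exp(p.C * (p.c - x)) + p.D)
    lm_beta = p.beta_peak_intercept + p.beta_peak_slope * p.lambda_max
    b_beta = p.beta_width_intercept + p.beta_width_slope * p.lambda_max
    beta = p.beta_amplitude * np.exp(-(((lam - lm_beta) / b_beta) ** 2))
    s = alpha + beta
    s = s / s.max()
    return Spectrum(grid=g, values=s, kind="sensitivity",
                    name=f"template_{p.lambda_max:g}nm")


def _load_d65() -> Spectrum:
    text = resources.files("mimicvis.data").joinpath("cie_d65.csv").read_text()
    rows = [line.split(",") for line in text.splitlines()
            if line.strip() and not line.startswith("#")][1:]
    lam = np.array([float(r[0]) for r in rows])
    val = np.array([float(r[1]) for r in rows])
    step = lam[1] - lam[0]
    grid = WavelengthGrid(lam[0], lam[-1], step)
    return Spectrum(grid=grid, values=val, kind="illuminant", name="D65")


def standard_illuminant(name: str, g: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """Return a named illuminant resampled onto the grid.

    ``"D65"`` is the CIE daylight tabulation (relative spectral power,
    100 at 560 nm); ``"flat"`` is an equal-energy spectrum of ones.
    """
    if name == "flat":
        return Spectrum(grid=g, values=np.ones(len(g)), kind="illuminant",
                        name="flat")
    if name == "D65":
        return resample_spectrum(_load_d65(), g)
    raise ConfigurationError(
        f"unknown illuminant {name!r}; valid names: 'D65', 'flat'")
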