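"""Calibrated UV photography: simulation, linearization, cone-catch mapping.

A UV-capable camera records each color patch through four channels (one
ultraviolet, three visible) alongside a 40% gray standard. Raw sensor
readings follow a power-law (gamma) response; calibration inverts the
gamma and rescales by the gray standard so a patch's normalized channel
value equals its effective reflectance in that channel's band.

The camera-to-animal step fits a least-squares mapping from normalized
camera responses to gray-normalized receptor catches over a training
library of reflectance spectra, optionally with pairwise product terms,
and applies it to new patches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, FittingError, NormalizationError
from .spectra import DEFAULT_GRID, Spectrum, WavelengthGrid, trapezoid
from .systems import (GRAY_REFLECTANCE, CatchVector, VisualSystem, catch_vector,
                      flat_gray, quantum_catch)

__all__ = [
    "CameraChannel",
    "PatchResponse",
    "ConeMapping",
    "default_camera",
    "simulate_camera_response",
    "linearize_normalize",
    "fit_cone_mapping",
    "apply_mapping",
]

_Q_EPSILON = 1e-6


@dataclass(frozen=True)
class CameraChannel:
    """One sensor channel: a peak-normalized sensitivity confined to a
    passband (the filter's transmission window)."""

    name: str
    sensitivity: Spectrum
    passband: tuple[float, float]

    def __post_init__(self) -> None:
        lam = self.sensitivity.wavelengths
        vals = self.sensitivity.values
        lo, hi = self.passband
        outside = (lam < lo) | (lam > hi)
        if np.any(vals[outside] > 1e-12):
            raise ConfigurationError(
                f"channel {self.name}: sensitivity nonzero outside passband")


def _gaussian_channel(name: str, center: float, sd: float,
                      passband: tuple[float, float],
                      grid: WavelengthGrid) -> CameraChannel:
    lam = grid.wavelengths
    vals = np.exp(-0.5 * ((lam - center) / sd) ** 2)
    lo, hi = passband
    vals = np.where((lam >= lo) & (lam <= hi), vals, 0.0)
    vals = vals / vals.max()
    return CameraChannel(
        name=name,
        sensitivity=Spectrum(grid=grid, values=vals, kind="sensitivity",
                             name=f"cam_{name}"),
        passband=passband)


def default_camera(grid: WavelengthGrid = DEFAULT_GRID) -> list[CameraChannel]:
    """Four synthetic channels: a UV channel confined to the 320-380 nm
    UV-pass filter and blue/green/red channels confined to the 400-680 nm
    UV/IR-cut filter."""
    return [
        _gaussian_channel("uv", 350.0, 18.0, (320.0, 380.0), grid),
        _gaussian_channel("visB", 460.0, 40.0, (400.0, 680.0), grid),
        _gaussian_channel("visG", 540.0, 45.0, (400.0, 680.0), grid),
        _gaussian_channel("visR", 600.0, 45.0, (400.0, 680.0), grid),
    ]


@dataclass(frozen=True)
class PatchResponse:
    """Per-channel sensor readings for one patch plus the gray standard."""

    channel_names: tuple[str, ...]
    raw: np.ndarray
    gray_raw: np.ndarray
    gamma: float
    normalized: np.ndarray | None = None
    label: str = ""


def _linear_response(r: Spectrum, i: Spectrum, cams: list[CameraChannel],
                     gray: Spectrum) -> np.ndarray:
    """Gray-normalized linear channel responses (effective reflectances)."""
    out = np.empty(len(cams))
    for k, cam in enumerate(cams):
        ch = cam.sensitivity
        num = trapezoid(r.values * i.values * ch.values, r.grid)
        den = trapezoid(gray.values * i.values * ch.values, r.grid)
        if den <= 0:
            warnings.warn(f"channel {cam.name}: empty overlap with the scene",
                          stacklevel=3)
            out[k] = 0.0
        else:
            out[k] = num / den * GRAY_REFLECTANCE
    return out


def simulate_camera_response(r: Spectrum, i: Spectrum,
                             cams: list[CameraChannel],
                             gamma: float = 1.0,
                             noise_sd: float = 0.0,
                             rng: np.random.Generator | None = None,
                             gray: Spectrum | None = None,
                             label: str = "") -> PatchResponse:
    """Forward camera model: linear response through a gamma curve, with
    optional additive Gaussian read noise (deterministic given ``rng``)."""
    if gamma <= 0:
        raise ConfigurationError("gamma must be positive")
    if gray is None:
        gray = flat_gray(r.grid)
    linear = _linear_response(r, i, cams, gray)
    gray_linear = np.full(len(cams), GRAY_REFLECTANCE)
    raw = linear ** (1.0 / gamma)
    gray_raw = gray_linear ** (1.0 / gamma)
    if noise_sd > 0:
        if rng is None:
            raise ConfigurationError("noise_sd > 0 requires an rng")
        raw = np.clip(raw + rng.normal(0.0, noise_sd, raw.shape), 0.0, None)
    return PatchResponse(channel_names=tuple(c.name for c in cams),
                         raw=raw, gray_raw=gray_raw, gamma=gamma, label=label)


def linearize_normalize(p: PatchResponse,
                        gray_reflectance: float = GRAY_REFLECTANCE) -> PatchResponse:
    """Undo the gamma curve and normalize to the gray standard:
    normalized_c = (raw_c / gray_raw_c)^gamma * gray_reflectance."""
    if np.any(p.gray_raw <= 0):
        raise NormalizationError("zero gray-standard reading; cannot calibrate")
    normalized = (p.raw ** p.gamma) / (p.gray_raw ** p.gamma) * gray_reflectance
    return replace(p, normalized=normalized)


@dataclass(frozen=True)
class ConeMapping:
    """Least-squares map from normalized camera responses to normalized
    receptor catches of a target visual system."""

    system: VisualSystem
    camera_names: tuple[str, ...]
    term_names: tuple[str, ...]
    coefficients: np.ndarray  # (n_terms, n_receptors)
    training_rms: np.ndarray  # per receptor
    model_order: str


def _design_row(x: np.ndarray, names: tuple[str, ...],
                model_order: str) -> tuple[np.ndarray, tuple[str, ...]]:
    terms = [1.0]
    term_names = ["intercept"]
    terms.extend(x)
    term_names.extend(names)
    if model_order == "linear+products":
        n = len(x)
        for i in range(n):
            for j in range(i + 1, n):
                terms.append(x[i] * x[j])
                term_names.append(f"{names[i]}*{names[j]}")
    return np.asarray(terms), tuple(term_names)


def fit_cone_mapping(library: list[Spectrum], i: Spectrum,
                     cams: list[CameraChannel], sys: VisualSystem,
                     model_order: str = "linear",
                     gray: Spectrum | None = None) -> ConeMapping:
    """Fit the camera-to-cone mapping over a library of reflectance spectra.

    Each training spectrum contributes its normalized camera responses
    (predictors) and its gray-normalized receptor catches (targets); the
    fit is ordinary least squares per receptor, with an intercept and,
    for ``model_order="linear+products"``, all pairwise channel products.
    """
    if model_order not in ("linear", "linear+products"):
        raise ConfigurationError(
            f"unknown model order {model_order!r}")
    cam_names = tuple(c.name for c in cams)
    n_terms = len(_design_row(np.zeros(len(cams)), cam_names, model_order)[0])
    if len(library) < 3 * n_terms:
        raise FittingError(
            f"training library of {len(library)} spectra is too small for "
            f"{n_terms} predictor terms (need at least {3 * n_terms})")
    if gray is None:
        gray = flat_gray(library[0].grid)
    X_rows, Y_rows = [], []
    term_names: tuple[str, ...] = ()
    for r in library:
        resp = _linear_response(r, i, cams, gray)
        row, term_names = _design_row(resp, cam_names, model_order)
        X_rows.append(row)
        Y_rows.append(catch_vector(r, i, sys, gray=gray).q)
    X = np.asarray(X_rows)
    Y = np.asarray(Y_rows)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns not adding rank, in order
        collinear = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            cand = kept + [j]
            if np.linalg.matrix_rank(X[:, cand]) > len(kept):
                kept.append(j)
            else:
                collinear.append(term_names[j])
        raise FittingError(
            f"rank-deficient design: collinear terms {collinear}")
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    rms = np.sqrt(np.mean(resid**2, axis=0))
    return ConeMapping(system=sys, camera_names=cam_names,
                       term_names=term_names, coefficients=coef,
                       training_rms=rms, model_order=model_order)


def apply_mapping(m: ConeMapping, p: PatchResponse) -> CatchVector:
    """Predict normalized receptor catches for a calibrated patch response."""
    if p.normalized is None:
        raise ConfigurationError(
            "patch response must be linearized/normalized before mapping")
    if p.channel_names != m.camera_names:
        raise ConfigurationError(
            f"camera channels {p.channel_names} do not match the mapping's "
            f"training layout {m.camera_names}")
    row, _ = _design_row(p.normalized, m.camera_names, m.model_order)
    q = row @ m.coefficients
    if np.any(q <= 0):
        warnings.warn(
            f"predicted nonpositive catch clamped to {_Q_EPSILON} for patch "
            f"{p.label or '<unnamed>'}", stacklevel=2)
        q = np.clip(q, _Q_EPSILON, None)
    return CatchVector(system=m.system, Q=q.copy(), q=q, f=np.log(q),
                       label=p.label)
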