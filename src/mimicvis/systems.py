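"""Receptor-channel sets and quantum-catch computation.

A :class:`VisualSystem` bundles ordered receptor channels (each a
peak-normalized spectral sensitivity with a relative abundance) with the
Weber fraction of its most abundant channel. Six presets cover the two
avian observers (blue tit as the ultraviolet-sensitive archetype, peafowl
as the violet-sensitive one, both with a double-cone achromatic channel)
and the sexually dimorphic *Heliconius erato* eye with either the green
(555 nm) or red-shifted (600 nm) long-wavelength receptor.

Quantum catches are gray-standard normalized (von Kries): each channel's
catch is divided by its catch for a flat 40% reflectance reference under
the same illuminant, so absolute illuminant intensity cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .errors import (ConfigurationError, GridMismatchError,
                     NormalizationError)
from .spectra import (DEFAULT_GRID, PigmentTemplateParams, Spectrum,
                      WavelengthGrid, pigment_template, trapezoid)

__all__ = [
    "ReceptorChannel",
    "VisualSystem",
    "CatchVector",
    "build_preset",
    "preset_names",
    "preset_table",
    "quantum_catch",
    "catch_vector",
    "flat_gray",
    "GRAY_REFLECTANCE",
]

GRAY_REFLECTANCE = 0.40


@dataclass(frozen=True)
class ReceptorChannel:
    name: str
    sensitivity: Spectrum
    eta: float
    lambda_max: float

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ConfigurationError(f"channel {self.name}: eta must be > 0")
        if abs(self.sensitivity.values.max() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"channel {self.name}: sensitivity must be peak-normalized to 1")


@dataclass(frozen=True)
class VisualSystem:
    name: str
    channels: tuple[ReceptorChannel, ...]
    weber: float = 0.05
    achromatic_channel: ReceptorChannel | None = None
    achromatic_weber: float = 0.05

    def __post_init__(self) -> None:
        if len(self.channels) < 2:
            raise ConfigurationError("a visual system needs at least 2 channels")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate channel names: {names}")
        if not 0 < self.weber < 1:
            raise ConfigurationError("weber fraction must lie in (0, 1)")
        lmaxes = [c.lambda_max for c in self.channels]
        if lmaxes != sorted(lmaxes):
            raise ConfigurationError(
                "channels must be ordered by increasing lambda_max")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.channels)

    @property
    def etas(self) -> np.ndarray:
        return np.array([c.eta for c in self.channels])


@dataclass(frozen=True)
class CatchVector:
    """Per-channel quantum catches for one color patch.

    ``Q`` are raw catches, ``q`` gray-normalized catches, ``f = ln q`` the
    log (Weber-Fechner) receptor signals. ``q_achro`` holds the normalized
    double-cone catch where the system has one.
    """

    system: VisualSystem
    Q: np.ndarray
    q: np.ndarray
    f: np.ndarray
    Q_achro: float | None = None
    q_achro: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        for arr in (self.Q, self.q, self.f):
            if np.asarray(arr).shape != (self.system.n_channels,):
                raise GridMismatchError(
                    "catch vector length does not match system channel count")


def _load_preset_table() -> dict:
    text = resources.files("mimicvis.data").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def preset_table() -> dict:
    """The raw preset configuration (names, channels, lambda-max, eta)."""
    return _load_preset_table()


def preset_names() -> tuple[str, ...]:
    return tuple(_load_preset_table().keys())


def build_preset(name: str, grid: WavelengthGrid = DEFAULT_GRID) -> VisualSystem:
    """Construct a named visual system on the given wavelength grid.

    Channel sensitivities are built with the A1 pigment template at each
    channel's lambda-max; abundances and Weber fractions come from the
    packaged preset table.
    """
    table = _load_preset_table()
    if name not in table:
        raise ConfigurationError(
            f"unknown preset {name!r}; valid presets: {sorted(table)}")
    cfg = table[name]
    channels = tuple(
        ReceptorChannel(
            name=ch["name"],
            sensitivity=pigment_template(
                PigmentTemplateParams(lambda_max=float(ch["lambda_max"])), grid),
            eta=float(ch["eta"]),
            lambda_max=float(ch["lambda_max"]),
        )
        for ch in cfg["channels"]
    )
    achro = None
    achro_weber = float(cfg.get("weber", 0.05))
    if "achromatic" in cfg:
        ac = cfg["achromatic"]
        achro = ReceptorChannel(
            name=ac["name"],
            sensitivity=pigment_template(
                PigmentTemplateParams(lambda_max=float(ac["lambda_max"])), grid),
            eta=1.0,
            lambda_max=float(ac["lambda_max"]),
        )
        achro_weber = float(ac.get("weber", 0.05))
    return VisualSystem(
        name=name,
        channels=channels,
        weber=float(cfg.get("weber", 0.05)),
        achromatic_channel=achro,
        achromatic_weber=achro_weber,
    )


def flat_gray(grid: WavelengthGrid = DEFAULT_GRID,
              reflectance: float = GRAY_REFLECTANCE) -> Spectrum:
    """Flat gray-standard reflectance (default 40%)."""
    return Spectrum(grid=grid, values=np.full(len(grid), reflectance),
                    kind="reflectance", name=f"gray{reflectance:g}")


def quantum_catch(r: Spectrum, i: Spectrum, ch: ReceptorChannel) -> float:
    """Quantum catch Q = integral of R(l) I(l) S(l) dl on the common grid."""
    if r.grid != i.grid or r.grid != ch.sensitivity.grid:
        raise GridMismatchError(
            "reflectance, illuminant and sensitivity must share one grid; "
            "resample first")
    integrand = r.values * i.values * ch.sensitivity.values
    q = trapezoid(integrand, r.grid)
    if q == 0.0:
        warnings.warn(
            f"degenerate stimulus: zero overlap between reflectance and "
            f"channel {ch.name}", stacklevel=2)
    return q


def catch_vector(r: Spectrum, i: Spectrum, sys: VisualSystem,
                 gray: Spectrum | None = None, label: str = "") -> CatchVector:
    """Quantum catches for all channels, von Kries normalized to the gray
    standard (default: flat 40% reflectance under the same illuminant)."""
    if gray is None:
        gray = flat_gray(r.grid)
    Q = np.array([quantum_catch(r, i, ch) for ch in sys.channels])
    Qg = np.array([quantum_catch(gray, i, ch) for ch in sys.channels])
    if np.any(Qg <= 0):
        raise NormalizationError(
            "gray-standard catch is zero for at least one channel")
    q = Q / Qg
    with np.errstate(divide="ignore"):
        f = np.log(q)
    Q_achro = q_achro = None
    if sys.achromatic_channel is not None:
        Q_achro = quantum_catch(r, i, sys.achromatic_channel)
        Qg_a = quantum_catch(gray, i, sys.achromatic_channel)
        if Qg_a <= 0:
            raise NormalizationError("gray-standard double-cone catch is zero")
        q_achro = Q_achro / Qg_a
    return CatchVector(system=sys, Q=Q, q=q, f=f,
                       Q_achro=Q_achro, q_achro=q_achro, label=label)
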