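"""Receptor-noise-limited (RNL) color discrimination.

The discriminability of two stimuli is the distance between their log
receptor signals after removing the achromatic (equal-shift) direction,
weighted by per-channel noise. With noise :math:`e_i` and log-signal
differences :math:`\\Delta f_i`, the chromatic distance is

.. math::

    \\Delta S^2 = \\sum_i w_i (\\Delta f_i - \\bar{f}_w)^2, \\qquad
    w_i = 1/e_i^2, \\quad
    \\bar{f}_w = \\sum_i w_i \\Delta f_i / \\sum_i w_i,

which is algebraically identical, for any number of receptors, to the
familiar dichromat / trichromat / tetrachromat closed forms of the
receptor-noise model. Channel noise scales with the inverse square root
of relative receptor abundance, anchored at the Weber fraction of the
most abundant channel: :math:`e_i = \\omega \\sqrt{\\eta_{max}/\\eta_i}`.

Distances are in just-noticeable-difference (JND) units; under bright,
natural light a difference below about 3 JND is treated as hard to
discriminate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (ConfigurationError, DomainError, GridMismatchError,
                     UnsupportedSystemError)
from .systems import CatchVector, VisualSystem

__all__ = [
    "NoiseVector",
    "ContrastResult",
    "channel_noise",
    "chromatic_jnd",
    "chromatic_distance",
    "achromatic_jnd",
    "discriminable",
    "JND_THRESHOLD",
]

JND_THRESHOLD = 3.00


@dataclass(frozen=True)
class NoiseVector:
    """Per-channel noise e_i aligned with a system's channels."""

    system: VisualSystem
    e: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.e, float)
        object.__setattr__(self, "e", e)
        if e.shape != (self.system.n_channels,):
            raise GridMismatchError("noise length does not match channel count")
        if np.any(e <= 0):
            raise ConfigurationError("noise values must be positive")


@dataclass(frozen=True)
class ContrastResult:
    delta_f: np.ndarray
    delta_S: float
    kind: str  # "chromatic" | "achromatic"


def channel_noise(sys: VisualSystem) -> NoiseVector:
    """Abundance-scaled Weber noise: e_i = omega * sqrt(eta_max / eta_i).

    The most abundant channel receives exactly the Weber fraction omega.
    """
    eta = sys.etas
    if np.any(eta <= 0):
        raise ConfigurationError("all channel abundances must be positive")
    e = sys.weber * np.sqrt(eta.max() / eta)
    return NoiseVector(system=sys, e=e)


def chromatic_distance(delta_f: np.ndarray, e: np.ndarray) -> float:
    """RNL chromatic distance from log-signal differences and noise.

    The general n-receptor form: project out the achromatic direction
    under the inverse-noise-variance metric and take the residual norm.
    """
    delta_f = np.asarray(delta_f, float)
    e = np.asarray(e, float)
    w = 1.0 / e**2
    fbar = np.sum(w * delta_f) / np.sum(w)
    return float(np.sqrt(np.sum(w * (delta_f - fbar) ** 2)))


def chromatic_jnd(a: CatchVector, b: CatchVector,
                  noise: NoiseVector) -> ContrastResult:
    """Chromatic contrast between two patches in JND units."""
    if a.system is not b.system and a.system != b.system:
        raise GridMismatchError("catch vectors come from different visual systems")
    if noise.system != a.system:
        raise GridMismatchError("noise vector belongs to a different system")
    if np.any(a.q <= 0) or np.any(b.q <= 0):
        raise DomainError(
            "nonpositive normalized catch: log receptor signals undefined")
    delta_f = a.f - b.f
    return ContrastResult(delta_f=delta_f,
                          delta_S=chromatic_distance(delta_f, noise.e),
                          kind="chromatic")


def achromatic_jnd(a: CatchVector, b: CatchVector,
                   sys: VisualSystem) -> ContrastResult:
    """Achromatic (double-cone) contrast: |ln q_D(a) - ln q_D(b)| / e_D."""
    if sys.achromatic_channel is None:
        raise UnsupportedSystemError(
            f"system {sys.name!r} has no achromatic (double-cone) channel; "
            "achromatic contrast is undefined for it")
    if a.q_achro is None or b.q_achro is None:
        raise DomainError("catch vectors carry no achromatic catch")
    if a.q_achro <= 0 or b.q_achro <= 0:
        raise DomainError("nonpositive achromatic catch")
    df = np.log(a.q_achro) - np.log(b.q_achro)
    return ContrastResult(delta_f=np.array([df]),
                          delta_S=abs(df) / sys.achromatic_weber,
                          kind="achromatic")


def discriminable(result: ContrastResult | float,
                  threshold: float = JND_THRESHOLD) -> bool:
    """True iff the contrast strictly exceeds the JND threshold.

    A contrast exactly at the threshold counts as not discriminable.
    """
    if threshold < 0:
        raise ConfigurationError("JND threshold must be nonnegative")
    ds = result.delta_S if isinstance(result, ContrastResult) else float(result)
    return ds > threshold
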