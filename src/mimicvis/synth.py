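"""Synthetic wing-patch spectra, comimic populations, and choice trials.

Real *Heliconius* wing colors are long-pass pigment reflectances: near
zero at short wavelengths, rising through a sigmoidal inflection to a
plateau, with the yellow (3-OHK) pigment adding an ultraviolet
reflectance lobe. The generator builds patch reflectances from that
shape: a logistic long-pass base plus an optional UV Gaussian lobe.

Individual-level variation has two components: a multiplicative
(brightness) lognormal factor, which is chromatically invisible after
gray normalization and log signals, and a spectral component - a normal
jitter of the inflection wavelength - which is what makes conspecific
pairs differ chromatically. Species-level divergence within a mimicry
ring is a controllable shift of the inflection (and, optionally, the UV
lobe amplitude) between the two comimic species; red patches carry extra
inflection jitter, emulating the age-related fading of red pigment.

Every generator is a pure function of its random generator state, and
each returns the ground-truth parameters alongside the data so that
recovery tests can close the loop.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, ScenarioError
from .matechoice import TREATMENTS, TrialRecord
from .mimicry import PatchMeasurement, individual_mean_jnd, pairwise_jnd_table
from .spectra import DEFAULT_GRID, Spectrum, WavelengthGrid, standard_illuminant
from .systems import VisualSystem, catch_vector, flat_gray

__all__ = [
    "PatchSpectrumModel",
    "RingScenario",
    "default_patch_model",
    "generate_patch_spectrum",
    "generate_ring",
    "calibrate_ring_scenario",
    "generate_mate_choice_trials",
    "reference_scale_trials",
]

# Long-pass parameters per pigment class: inflection (nm), logistic slope
# (1/nm), plateau reflectance, UV lobe (center nm, width nm, amplitude) or
# None, and the individual-level spectral jitter (nm). Red gets extra
# jitter for age-related fading.
_COLOR_DEFAULTS = {
    "yellow": dict(longpass_inflection=500.0, longpass_slope=0.10,
                   plateau=0.70, uv_lobe=(350.0, 25.0, 0.25),
                   inflection_sd_nm=1.5),
    "white": dict(longpass_inflection=400.0, longpass_slope=0.06,
                  plateau=0.85, uv_lobe=(345.0, 30.0, 0.15),
                  inflection_sd_nm=1.5),
    "orange": dict(longpass_inflection=560.0, longpass_slope=0.09,
                   plateau=0.65, uv_lobe=None, inflection_sd_nm=2.0),
    "red": dict(longpass_inflection=600.0, longpass_slope=0.09,
                plateau=0.60, uv_lobe=None, inflection_sd_nm=4.0),
}


@dataclass(frozen=True)
class PatchSpectrumModel:
    """Generative model of one wing-patch reflectance class."""

    color_class: str
    longpass_inflection: float
    longpass_slope: float
    plateau: float
    uv_lobe: tuple[float, float, float] | None = None
    individual_cv: float = 0.05
    inflection_sd_nm: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.plateau <= 1:
            raise ConfigurationError("plateau must lie in (0, 1]")
        if self.uv_lobe is not None and self.uv_lobe[2] < 0:
            raise ConfigurationError("UV lobe amplitude must be nonnegative")
        if self.individual_cv < 0 or self.inflection_sd_nm < 0:
            raise ConfigurationError("variation parameters must be nonnegative")


def default_patch_model(color_class: str, **overrides) -> PatchSpectrumModel:
    """The packaged generative model for a named color class."""
    if color_class not in _COLOR_DEFAULTS:
        raise ConfigurationError(
            f"unknown color class {color_class!r}; "
            f"valid: {sorted(_COLOR_DEFAULTS)}")
    params = dict(_COLOR_DEFAULTS[color_class])
    params.update(overrides)
    return PatchSpectrumModel(color_class=color_class, **params)


def generate_patch_spectrum(m: PatchSpectrumModel,
                            rng: np.random.Generator,
                            grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """Draw one individual's patch reflectance from the model."""
    lam = grid.wavelengths
    inflection = m.longpass_inflection + rng.normal(0.0, m.inflection_sd_nm) \
        if m.inflection_sd_nm > 0 else m.longpass_inflection
    base = m.plateau / (1.0 + np.exp(-m.longpass_slope * (lam - inflection)))
    if m.uv_lobe is not None:
        center, width, amp = m.uv_lobe
        base = base + amp * np.exp(-(((lam - center) / width) ** 2))
    factor = math.exp(rng.normal(0.0, m.individual_cv)) if m.individual_cv > 0 else 1.0
    vals = base * factor
    if vals.max() > 1.5:
        warnings.warn("generated reflectance exceeded 1.5; clipped", stacklevel=2)
        vals = np.clip(vals, 0.0, 1.5)
    return Spectrum(grid=grid, values=vals, kind="reflectance",
                    name=f"synthetic_{m.color_class}")


def generate_training_library(n: int, rng: np.random.Generator,
                              grid: WavelengthGrid = DEFAULT_GRID
                              ) -> list[Spectrum]:
    """Generic smooth reflectances for camera-mapping calibration.

    Each spectrum is a random baseline plus a few broad Gaussian bumps
    and an optional long-pass edge, clipped to [0.02, 1.2]. The positive
    floor keeps every receptor catch bounded away from zero, as in the
    natural-spectra libraries used to train camera-to-receptor mappings;
    it is not a model of any particular wing patch.
    """
    lam = grid.wavelengths
    out = []
    for _ in range(n):
        vals = np.full(lam.shape, rng.uniform(0.05, 0.3))
        for _ in range(int(rng.integers(2, 5))):
            c = rng.uniform(300.0, 700.0)
            w = rng.uniform(40.0, 150.0)
            a = rng.uniform(-0.3, 0.6)
            vals = vals + a * np.exp(-(((lam - c) / w) ** 2))
        if rng.random() < 0.5:
            l0 = rng.uniform(380.0, 620.0)
            k = rng.uniform(0.02, 0.1)
            vals = vals + rng.uniform(0.0, 0.6) / (1.0 + np.exp(-k * (lam - l0)))
        vals = np.clip(vals, 0.02, 1.2)
        out.append(Spectrum(grid=grid, values=vals, kind="reflectance",
                            name="library"))
    return out


@dataclass(frozen=True)
class RingScenario:
    """A two-species mimicry-ring population with controllable divergence."""

    species_a: str = "erato"
    species_b: str = "melpomene"
    n_a: int = 10
    n_b: int = 10
    colors: tuple[str, ...] = ("yellow",)
    sides: tuple[str, ...] = ("dorsal",)
    divergence_nm: float = 0.0
    uv_amp_divergence: float = 0.0
    ring: str = "synthetic-ring"
    model_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_a < 2 or self.n_b < 2:
            raise ScenarioError("each species needs at least 2 individuals")
        if not self.colors or not self.sides:
            raise ScenarioError("scenario needs at least one color and one side")
        if self.divergence_nm < 0 or self.uv_amp_divergence < 0:
            raise ScenarioError("divergence must be nonnegative")

    def model_for(self, color: str, species: str) -> PatchSpectrumModel:
        m = default_patch_model(color, **self.model_overrides.get(color, {}))
        if species == self.species_b:
            m = replace(m, longpass_inflection=m.longpass_inflection
                        + self.divergence_nm)
            if self.uv_amp_divergence and m.uv_lobe is not None:
                c, w, a = m.uv_lobe
                m = replace(m, uv_lobe=(c, w, a + self.uv_amp_divergence))
        return m


def generate_ring(scenario: RingScenario, system: VisualSystem,
                  rng: np.random.Generator,
                  illuminant: Spectrum | None = None,
                  grid: WavelengthGrid = DEFAULT_GRID,
                  ) -> tuple[list[PatchMeasurement], dict]:
    """Generate spectra for every individual x stratum and convert them to
    catch vectors under the given visual system.

    Returns the measurement list and a ground-truth dictionary (the
    per-species generative models and divergence actually used).
    """
    if illuminant is None:
        illuminant = standard_illuminant("D65", grid)
    gray = flat_gray(grid)
    measurements: list[PatchMeasurement] = []
    truth: dict = {"divergence_nm": scenario.divergence_nm,
                   "uv_amp_divergence": scenario.uv_amp_divergence,
                   "models": {}}
    for color in scenario.colors:
        for species, n in ((scenario.species_a, scenario.n_a),
                           (scenario.species_b, scenario.n_b)):
            model = scenario.model_for(color, species)
            truth["models"][(color, species)] = model
            for k in range(n):
                ind = f"{species}_{k:02d}"
                for side in scenario.sides:
                    spec = generate_patch_spectrum(model, rng, grid)
                    cv = catch_vector(spec, illuminant, system, gray=gray,
                                      label=f"{ind}_{color}_{side}")
                    measurements.append(PatchMeasurement(
                        individual_id=ind, species=species,
                        ring=scenario.ring, patch_color=color,
                        wing_side=side, catch=cv))
    return measurements, truth


def _mean_jnds(scenario: RingScenario, system: VisualSystem,
               seed: int) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    meas, _ = generate_ring(scenario, system, rng)
    means = individual_mean_jnd(pairwise_jnd_table(meas))
    return (float(means["mean_comimic_jnd"].mean()),
            float(means["mean_conspecific_jnd"].mean()))


def calibrate_ring_scenario(system: VisualSystem,
                            target_comimic_jnd: float = 6.0,
                            target_conspecific_jnd: float = 1.0,
                            color: str = "yellow",
                            n_each: int = 10,
                            seed: int = 12345) -> RingScenario:
    """Find, by bisection against the generative model itself, the
    individual spectral jitter and species divergence whose simulated
    mean conspecific and comimic JNDs hit the requested targets.

    The conspecific jitter is calibrated first (it is the conspecific
    JND's only source), then the divergence on top of it.
    """
    def conspecific_mean(sd: float) -> float:
        sc = RingScenario(n_a=n_each, n_b=n_each, colors=(color,),
                          model_overrides={color: {"inflection_sd_nm": sd}})
        return _mean_jnds(sc, system, seed)[1]

    sd = _bisect_monotone(conspecific_mean, target_conspecific_jnd,
                          lo=1e-3, hi=20.0)

    def comimic_mean(div: float) -> float:
        sc = RingScenario(n_a=n_each, n_b=n_each, colors=(color,),
                          divergence_nm=div,
                          model_overrides={color: {"inflection_sd_nm": sd}})
        return _mean_jnds(sc, system, seed)[0]

    div = _bisect_monotone(comimic_mean, target_comimic_jnd,
                           lo=0.0, hi=80.0)
    return RingScenario(n_a=n_each, n_b=n_each, colors=(color,),
                        divergence_nm=div,
                        model_overrides={color: {"inflection_sd_nm": sd}})


def _bisect_monotone(fn, target: float, lo: float, hi: float,
                     n_iter: int = 24) -> float:
    f_lo, f_hi = fn(lo), fn(hi)
    if not (f_lo <= target <= f_hi):
        raise ScenarioError(
            f"target {target} outside achievable range [{f_lo:.3g}, {f_hi:.3g}]")
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if fn(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_mate_choice_trials(n_males: int,
                                events_per_male: float,
                                p_comimic: dict[str, float] | float,
                                rng: np.random.Generator,
                                courtship_events_per_male: float = 0.0,
                                p_comimic_courtship: dict[str, float] | float | None = None,
                                ) -> tuple[list[TrialRecord], dict]:
    """Binomial choice trials for ``n_males`` males under both treatments.

    ``p_comimic`` is the probability that one event is directed at the
    comimic model, either a single value or ``{treatment: p}``. Integer
    ``events_per_male`` gives every male that many events per treatment;
    a non-integer value is used as a Poisson mean, so per-male totals
    vary the way free-behaving trials do. Ground truth (the per-treatment
    log odds) is returned with the records.
    """
    def p_of(p, tr):
        val = p[tr] if isinstance(p, dict) else float(p)
        if not 0 < val < 1:
            raise ConfigurationError(f"probability {val} outside (0, 1)")
        return val

    if p_comimic_courtship is None:
        p_comimic_courtship = p_comimic
    trials: list[TrialRecord] = []
    for k in range(n_males):
        male = f"male_{k:02d}"
        for tr in TREATMENTS:
            n_app = int(events_per_male) if float(events_per_male).is_integer() \
                else int(rng.poisson(events_per_male))
            n_crt = int(courtship_events_per_male) \
                if float(courtship_events_per_male).is_integer() \
                else int(rng.poisson(courtship_events_per_male))
            app_com = int(rng.binomial(n_app, p_of(p_comimic, tr))) if n_app else 0
            crt_com = int(rng.binomial(n_crt, p_of(p_comimic_courtship, tr))) if n_crt else 0
            trials.append(TrialRecord(male_id=male, treatment=tr,
                                      target_species="melpomene_model",
                                      approaches=app_com, courtships=crt_com))
            trials.append(TrialRecord(male_id=male, treatment=tr,
                                      target_species="erato_model",
                                      approaches=n_app - app_com,
                                      courtships=n_crt - crt_com))
    truth = {
        "log_odds_approach": {tr: math.log(p_of(p_comimic, tr)
                                           / (1 - p_of(p_comimic, tr)))
                              for tr in TREATMENTS},
        "log_odds_courtship": {tr: math.log(p_of(p_comimic_courtship, tr)
                                            / (1 - p_of(p_comimic_courtship, tr)))
                               for tr in TREATMENTS},
    }
    return trials, truth


def reference_scale_trials(rng: np.random.Generator
                           ) -> tuple[list[TrialRecord], dict]:
    """A preset scenario at the scale of a published UV-manipulation
    experiment of this design: 41 males, roughly 709 approaches and 62
    courtships in total, with the comimic preferred under the UV-blocked
    treatment. For smoke tests of the full pipeline, not a reproduction
    of any behavioral dataset."""
    return generate_mate_choice_trials(
        n_males=41,
        events_per_male=709 / 82,  # Poisson mean per male x treatment
        p_comimic={"UVplus": 0.50, "UVminus": 0.65},
        rng=rng,
        courtship_events_per_male=62 / 82,
        p_comimic_courtship={"UVplus": 0.50, "UVminus": 0.55},
    )
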