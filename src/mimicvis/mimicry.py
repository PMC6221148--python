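"""Comimic-vs-conspecific discriminability statistics.

The pipeline: compute the chromatic JND for every cross-species (comimic)
and within-species (conspecific) pair of individuals inside each
stratum (mimicry ring x patch color x wing side x visual system),
average each individual's pairwise JNDs by pair type, square-root
transform the means, and test comimic vs conspecific with a
repeated-measures one-way ANOVA in which individual is the random
factor. With exactly one comimic and one conspecific mean per
individual this F statistic is the square of the paired t statistic,
on (1, n-1) degrees of freedom.

No multiplicity correction is applied across strata; each stratum is
tested independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError
from .rnl import NoiseVector, channel_noise, chromatic_distance
from .systems import CatchVector

__all__ = [
    "PatchMeasurement",
    "JNDRecord",
    "AnovaResult",
    "pairwise_jnd_table",
    "records_to_frame",
    "individual_mean_jnd",
    "comimic_vs_conspecific_anova",
    "permutation_pvalue",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PatchMeasurement:
    individual_id: str
    species: str
    ring: str
    patch_color: str
    wing_side: str
    catch: CatchVector


@dataclass(frozen=True)
class JNDRecord:
    ring: str
    patch_color: str
    wing_side: str
    system: str
    individual_a: str
    individual_b: str
    species_a: str
    species_b: str
    pair_type: str  # "comimic" | "conspecific"
    jnd: float


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_num: int
    df_den: int
    p: float
    transform: str
    n_individuals: int
    degenerate: bool = False


def pairwise_jnd_table(measurements: list[PatchMeasurement],
                       conspecific_restriction: set[str] | None = None,
                       noise: NoiseVector | None = None) -> list[JNDRecord]:
    """All pairwise chromatic JNDs within comimics and within conspecifics.

    Within each (ring, color, side) stratum, every cross-species pair is a
    comimic record and every within-species pair a conspecific record;
    when ``conspecific_restriction`` is given, conspecific pairs are only
    formed within the listed species (the butterfly-vision case, where
    visual data exist for one clade only). Strata present in fewer than
    two species are skipped with a log entry.
    """
    records: list[JNDRecord] = []
    strata: dict[tuple, list[PatchMeasurement]] = {}
    for m in measurements:
        strata.setdefault((m.ring, m.patch_color, m.wing_side), []).append(m)
    for (ring, color, side), group in strata.items():
        system = group[0].catch.system
        e = (noise or channel_noise(system)).e
        species = sorted({m.species for m in group})
        if len(species) < 2:
            logger.info("stratum (%s, %s, %s): only one species present; "
                        "skipped", ring, color, side)
            continue
        by_species = {sp: [m for m in group if m.species == sp]
                      for sp in species}
        for sp_a, sp_b in combinations(species, 2):
            for ma in by_species[sp_a]:
                for mb in by_species[sp_b]:
                    records.append(_record(ring, color, side, ma, mb,
                                           "comimic", e))
        for sp in species:
            if conspecific_restriction is not None and sp not in conspecific_restriction:
                continue
            for ma, mb in combinations(by_species[sp], 2):
                records.append(_record(ring, color, side, ma, mb,
                                       "conspecific", e))
    return records


def _record(ring: str, color: str, side: str, ma: PatchMeasurement,
            mb: PatchMeasurement, pair_type: str, e: np.ndarray) -> JNDRecord:
    jnd = chromatic_distance(ma.catch.f - mb.catch.f, e)
    return JNDRecord(ring=ring, patch_color=color, wing_side=side,
                     system=ma.catch.system.name,
                     individual_a=ma.individual_id, individual_b=mb.individual_id,
                     species_a=ma.species, species_b=mb.species,
                     pair_type=pair_type, jnd=jnd)


def records_to_frame(records: list[JNDRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def individual_mean_jnd(records: list[JNDRecord]) -> pd.DataFrame:
    """Average each individual's pairwise JNDs by pair type and stratum.

    Returns one row per (individual, ring, color, side, system) with
    ``mean_comimic_jnd`` and ``mean_conspecific_jnd`` columns; an
    individual with no pairs of one type gets a missing value there and
    is excluded by downstream tests (with a log entry).
    """
    if not records:
        return pd.DataFrame(columns=["individual", "ring", "patch_color",
                                     "wing_side", "system",
                                     "mean_comimic_jnd", "mean_conspecific_jnd"])
    rows = []
    for r in records:
        for ind, sp in ((r.individual_a, r.species_a),
                        (r.individual_b, r.species_b)):
            rows.append((ind, sp, r.ring, r.patch_color, r.wing_side,
                         r.system, r.pair_type, r.jnd))
    df = pd.DataFrame(rows, columns=["individual", "species", "ring",
                                     "patch_color", "wing_side", "system",
                                     "pair_type", "jnd"])
    keys = ["individual", "ring", "patch_color", "wing_side", "system"]
    wide = (df.groupby(keys + ["pair_type"])["jnd"].mean()
              .unstack("pair_type"))
    wide = wide.rename(columns={"comimic": "mean_comimic_jnd",
                                "conspecific": "mean_conspecific_jnd"})
    for col in ("mean_comimic_jnd", "mean_conspecific_jnd"):
        if col not in wide:
            wide[col] = np.nan
    out = wide.reset_index()[keys + ["mean_comimic_jnd", "mean_conspecific_jnd"]]
    n_missing = out[["mean_comimic_jnd", "mean_conspecific_jnd"]].isna().any(axis=1).sum()
    if n_missing:
        logger.info("%d individual rows lack one pair type and will be "
                    "excluded from the ANOVA", n_missing)
    return out


def comimic_vs_conspecific_anova(means: pd.DataFrame,
                                 transform: str = "sqrt") -> AnovaResult:
    """Repeated-measures one-way ANOVA of comimic vs conspecific mean JNDs.

    Individuals are the random factor; with one value per individual per
    pair type, F = MS(pair type) / MS(pair type x individual) on
    (1, n-1) degrees of freedom, equal to the squared paired t statistic.
    The square-root transform (the default) is applied to the means
    before testing, i.e. after per-individual averaging.
    """
    cols = ["mean_comimic_jnd", "mean_conspecific_jnd"]
    data = means.dropna(subset=cols)
    n = len(data)
    if n < 3:
        raise InsufficientDataError(
            f"ANOVA needs at least 3 individuals with both means; got {n}")
    x = data[cols].to_numpy(float)
    if transform == "sqrt":
        x = np.sqrt(x)
    elif transform != "none":
        raise InsufficientDataError(f"unknown transform {transform!r}")
    grand = x.mean()
    ss_type = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_ind = 2 * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_resid = ss_tot - ss_type - ss_ind
    df_num, df_den = 1, n - 1
    ms_type = ss_type / df_num
    ms_resid = max(ss_resid, 0.0) / df_den
    if ms_resid == 0.0:
        if ms_type == 0.0:
            return AnovaResult(F=0.0, df_num=df_num, df_den=df_den, p=1.0,
                               transform=transform, n_individuals=n)
        logger.warning("zero residual mean square: perfectly consistent "
                       "differences; p undefined")
        return AnovaResult(F=np.inf, df_num=df_num, df_den=df_den, p=np.nan,
                           transform=transform, n_individuals=n,
                           degenerate=True)
    F = ms_type / ms_resid
    p = float(sps.f.sf(F, df_num, df_den))
    return AnovaResult(F=float(F), df_num=df_num, df_den=df_den, p=p,
                       transform=transform, n_individuals=n)


def permutation_pvalue(means: pd.DataFrame, n_permutations: int = 2000,
                       rng: np.random.Generator | None = None,
                       transform: str = "sqrt") -> float:
    """Within-individual label-flip permutation test of the same contrast.

    A robustness companion to the F test: the pair-type labels are
    flipped independently within each individual and the absolute mean
    difference is compared with its permutation distribution.
    """
    rng = rng or np.random.default_rng(0)
    cols = ["mean_comimic_jnd", "mean_conspecific_jnd"]
    x = means.dropna(subset=cols)[cols].to_numpy(float)
    if transform == "sqrt":
        x = np.sqrt(x)
    d = x[:, 0] - x[:, 1]
    observed = abs(d.mean())
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, len(d)))
    perm = np.abs((signs * d).mean(axis=1))
    return float((np.sum(perm >= observed - 1e-15) + 1) / (n_permutations + 1))
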