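"""Weighted binomial GLM for two-choice mate-preference trials.

Each male is offered a conspecific and a comimic female model under two
treatments (UV reflectance intact vs blocked) and his approaches and
courtship attempts toward each model are counted. The response is the
proportion of events directed at the comimic; the per-male event total
is the binomial weight. The model is a logit-link binomial GLM fitted by
iteratively reweighted least squares (IRLS), with Wald z tests on the
coefficients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, FittingError, InsufficientDataError

__all__ = [
    "TrialRecord",
    "GLMFit",
    "build_choice_table",
    "fit_weighted_binomial",
    "wald_test",
    "TREATMENTS",
]

logger = logging.getLogger(__name__)

TREATMENTS = ("UVplus", "UVminus")
TARGETS = ("erato_model", "melpomene_model")
COMIMIC_TARGET = "melpomene_model"
BEHAVIORS = ("approach", "courtship")


@dataclass(frozen=True)
class TrialRecord:
    """One male's counts toward one female model under one treatment."""

    male_id: str
    treatment: str
    target_species: str
    approaches: int
    courtships: int
    trials_observed: int = 1

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ConfigurationError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")
        if self.target_species not in TARGETS:
            raise ConfigurationError(
                f"target_species must be one of {TARGETS}, "
                f"got {self.target_species!r}")
        if min(self.approaches, self.courtships, self.trials_observed) < 0:
            raise ConfigurationError("counts must be nonnegative")


def build_choice_table(trials: list[TrialRecord],
                       behavior: str = "approach") -> pd.DataFrame:
    """Aggregate trials into one row per male x treatment.

    ``successes`` are events toward the comimic model, ``failures`` events
    toward the conspecific, ``weight`` their sum. Replicate records for
    the same male/treatment/target are summed first. Males missing either
    treatment are excluded with a log entry; zero-event rows are kept
    with weight 0 (they contribute nothing to the likelihood).
    """
    if behavior not in BEHAVIORS:
        raise ConfigurationError(
            f"behavior must be one of {BEHAVIORS}, got {behavior!r}")
    count_of = {"approach": lambda t: t.approaches,
                "courtship": lambda t: t.courtships}[behavior]
    counts: dict[tuple[str, str, str], int] = {}
    for t in trials:
        key = (t.male_id, t.treatment, t.target_species)
        counts[key] = counts.get(key, 0) + count_of(t)
    males = sorted({k[0] for k in counts})
    rows = []
    for male in males:
        present = {tr for (m, tr, _tg) in counts if m == male}
        if present != set(TREATMENTS):
            logger.info("male %s missing treatment(s) %s; excluded",
                        male, set(TREATMENTS) - present)
            continue
        for tr in TREATMENTS:
            s = counts.get((male, tr, COMIMIC_TARGET), 0)
            f = sum(counts.get((male, tr, tg), 0)
                    for tg in TARGETS if tg != COMIMIC_TARGET)
            rows.append({"male_id": male, "treatment": tr, "behavior": behavior,
                         "successes": s, "failures": f, "weight": s + f})
    df = pd.DataFrame(rows, columns=["male_id", "treatment", "behavior",
                                     "successes", "failures", "weight"])
    df["proportion"] = np.where(df["weight"] > 0,
                                df["successes"] / df["weight"].where(df["weight"] > 0),
                                np.nan)
    return df


@dataclass(frozen=True)
class GLMFit:
    terms: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    z: np.ndarray
    p: np.ndarray
    deviance: float
    iterations: int
    converged: bool
    design: str

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.terms,
                             "estimate": self.coefficients,
                             "se": self.standard_errors,
                             "z": self.z, "p": self.p})


def _design_matrix(table: pd.DataFrame, design: str) -> tuple[np.ndarray, tuple[str, ...]]:
    n = len(table)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    if design == "intercept_only":
        pass
    elif design == "treatment":
        cols.append((table["treatment"] == "UVminus").to_numpy(float))
        names.append("treatment[UVminus]")
    elif design == "treatment_x_behavior":
        if "behavior" not in table or table["behavior"].nunique() < 2:
            raise FittingError(
                "treatment_x_behavior needs a table stacking both behaviors "
                "(concatenate build_choice_table outputs)")
        t = (table["treatment"] == "UVminus").to_numpy(float)
        b = (table["behavior"] == "courtship").to_numpy(float)
        cols += [t, b, t * b]
        names += ["treatment[UVminus]", "behavior[courtship]",
                  "treatment[UVminus]:behavior[courtship]"]
    else:
        raise ConfigurationError(
            f"unknown design {design!r}; valid: intercept_only, treatment, "
            "treatment_x_behavior")
    return np.column_stack(cols), tuple(names)


def fit_weighted_binomial(table: pd.DataFrame,
                          design: str = "treatment",
                          tol: float = 1e-10,
                          max_iter: int = 50) -> GLMFit:
    """Fit the logit-link binomial GLM by IRLS.

    ``table`` needs ``successes``, ``failures`` (or ``weight``) columns
    plus whatever factors the design references. Rows with zero weight
    drop out of the likelihood. Convergence is declared when the largest
    coefficient change falls below ``tol``; complete separation leaves
    ``converged`` False with a warning, and estimates are still reported.
    """
    work = table.copy()
    if "weight" not in work:
        work["weight"] = work["successes"] + work["failures"]
    work = work[work["weight"] > 0]
    if work.empty:
        raise InsufficientDataError("no rows with positive weight")
    X, names = _design_matrix(work, design)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FittingError("design matrix is rank deficient after aggregation")
    n = work["weight"].to_numpy(float)
    y = work["successes"].to_numpy(float) / n

    mu = (y * n + 0.5) / (n + 1.0)
    beta = np.zeros(X.shape[1])
    eta = np.log(mu / (1 - mu))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        var = mu * (1 - mu)
        W = n * var
        z = eta + (y - mu) / var
        WX = X * W[:, None]
        XtWX = X.T @ WX
        beta_new = np.linalg.solve(XtWX, WX.T @ z)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        if step < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            "IRLS did not converge (possible separation: a cell with all "
            "successes or all failures); estimates reported with caution",
            stacklevel=2)
    var = mu * (1 - mu)
    W = n * var
    cov = np.linalg.inv(X.T @ (X * W[:, None]))
    se = np.sqrt(np.diag(cov))
    zstat = beta / se
    pvals = 2 * sps.norm.sf(np.abs(zstat))
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_terms = np.where(y > 0, y * np.log(y / mu), 0.0) + \
            np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
    deviance = float(2 * np.sum(n * dev_terms))
    return GLMFit(terms=names, coefficients=beta, standard_errors=se,
                  z=zstat, p=pvals, deviance=deviance, iterations=it,
                  converged=converged, design=design)


def wald_test(fit: GLMFit, term: str) -> tuple[float, float]:
    """Wald z statistic and two-sided p value for a named coefficient."""
    if term not in fit.terms:
        raise ConfigurationError(
            f"unknown term {term!r}; fitted terms: {fit.terms}")
    k = fit.terms.index(term)
    return float(fit.z[k]), float(fit.p[k])
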