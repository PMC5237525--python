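"""Logistic risk models for AKI and 30-day mortality after hip fracture.

Ships the published coefficient sets (``model1``, ``model2``,
``mortality30d`` and the simplified integer score ``nhrisk``) and the
development procedure used to build them: a univariate screen at p < 0.2
followed by backward elimination on AIC.

Model 1 (banded age) covariates: male sex, CKD stage 3B–5, age band
(65–85 or >85, reference <65) and two-or-more comorbidities.  The NH-RISK
score assigns each covariate ``round(4 × coefficient)`` points and converts
a total of ``s`` points to ``risk = 1/(1 + exp(2.264 − s/4))``.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import PatientEpisode
from .frailty import comorbidity_count
from .renal import CKD_3B_5, CKDStage

log = logging.getLogger(__name__)


class CovariateError(KeyError):
    """A model covariate cannot be extracted for an episode."""


class SeparationError(RuntimeError):
    """Logistic fit failed because a covariate perfectly separates the outcome."""


@dataclass
class RiskModelSpec:
    """Named logistic model: intercept plus log-odds increments per covariate."""

    name: str
    intercept: float
    coefficients: dict[str, float]
    age_handling: str = "banded"  # banded | continuous
    # populated only on fitted models
    se: dict[str, float] | None = None
    conf_int: dict[str, tuple[float, float]] | None = None
    aic: float | None = None

    def to_json(self, path) -> None:
        data = {
            "name": self.name,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "age_handling": self.age_handling,
        }
        if self.aic is not None:
            data["aic"] = self.aic
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RiskModelSpec":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            name=data["name"],
            intercept=data["intercept"],
            coefficients=dict(data["coefficients"]),
            age_handling=data.get("age_handling", "banded"),
        )


@dataclass
class NHRiskScore:
    """Integer NH-RISK points (0–8) and the corresponding predicted risk."""

    points: int
    predicted_risk: float
    components: dict[str, int] = field(default_factory=dict)


def _load_builtin(name: str) -> dict:
    text = resources.files("hipaki").joinpath(f"model_specs/{name}.json").read_text()
    return json.loads(text)


def builtin_model(name: str) -> RiskModelSpec:
    """One of the shipped specs: ``model1``, ``model2`` or ``mortality30d``."""
    data = _load_builtin(name)
    return RiskModelSpec(
        name=data["name"],
        intercept=data["intercept"],
        coefficients=dict(data["coefficients"]),
        age_handling=data.get("age_handling", "banded"),
    )


def builtin_nhrisk() -> dict:
    """The shipped NH-RISK point table (points, divisor, intercept)."""
    return _load_builtin("nhrisk")


# ---------------------------------------------------------------------------
# Covariate extraction and prediction
# ---------------------------------------------------------------------------

def extract_covariates(
    episode: PatientEpisode,
    ckd: CKDStage | None = None,
    aki: bool | None = None,
) -> dict[str, float]:
    """Model covariates from an episode plus its pre-admission CKD stage.

    ``ckd=None`` means the stage was imputed to G2 (the convention for
    patients without a measured pre-admission creatinine), so the CKD 3B–5
    indicator is 0.  Age bands follow the risk models (<65 reference,
    65–85, >85), not the NHFS bands.
    """
    _, two_plus = comorbidity_count(episode)
    cov: dict[str, float] = {
        "male": float(episode.sex.upper() == "M"),
        "ckd_3b_5": float(ckd is not None and ckd.stage in CKD_3B_5),
        "age_65_85": float(65 <= episode.age_years <= 85),
        "age_gt_85": float(episode.age_years > 85),
        "age_per_year": float(episode.age_years),
        "two_plus_comorbidities": float(two_plus),
        "amts_lt_7": float(episode.amts is not None and episode.amts < 7),
    }
    if aki is not None:
        cov["aki"] = float(aki)
    return cov


def model_predict(spec: RiskModelSpec, covariates: Mapping[str, float]) -> float:
    """Probability from the logistic transform of intercept + Σ coefficients."""
    logit = spec.intercept
    for name, coef in spec.coefficients.items():
        if name not in covariates:
            raise CovariateError(f"model {spec.name!r} needs covariate {name!r}")
        logit += coef * covariates[name]
    return 1.0 / (1.0 + math.exp(-logit))


def nh_risk_predicted_risk(points: int, intercept: float = -2.264, divisor: int = 4) -> float:
    """Predicted AKI risk for an integer score: logistic(points/divisor + intercept)."""
    return 1.0 / (1.0 + math.exp(-(intercept + points / divisor)))


def nh_risk(covariates: Mapping[str, float]) -> NHRiskScore:
    """NH-RISK integer points and predicted risk for one episode."""
    table = builtin_nhrisk()
    components = {}
    total = 0
    for name, pts in table["points"].items():
        if name not in covariates:
            raise CovariateError(f"NH-RISK needs covariate {name!r}")
        got = int(round(covariates[name])) * pts
        components[name] = got
        total += got
    risk = nh_risk_predicted_risk(total, table["intercept"], table["divisor"])
    return NHRiskScore(points=total, predicted_risk=risk, components=components)


# ---------------------------------------------------------------------------
# Model development: univariate screen + backward elimination on AIC
# ---------------------------------------------------------------------------

def univariate_screen(
    data: pd.DataFrame,
    predictors: Sequence[str],
    outcome: str,
    alpha: float = 0.2,
) -> list[str]:
    """Retain predictors with univariate p < ``alpha`` against a binary outcome.

    Binary predictors use a Pearson chi-squared 2×2 test; continuous ones the
    Mann–Whitney rank test.  Zero-variance predictors are excluded with a
    warning.
    """
    y = data[outcome].to_numpy()
    retained = []
    for name in predictors:
        x = data[name].to_numpy()
        if np.all(x == x[0]):
            log.warning("predictor %s has zero variance; excluded", name)
            continue
        if set(np.unique(x)) <= {0, 1, 0.0, 1.0}:
            table = pd.crosstab(x, y).to_numpy()
            _, p, _, _ = stats.chi2_contingency(table, correction=False)
        else:
            _, p = stats.mannwhitneyu(x[y == 1], x[y == 0], alternative="two-sided")
        if p < alpha:
            retained.append(name)
    return retained


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=100)
        except Exception as exc:  # PerfectSeparationError and friends
            raise SeparationError(_describe_separation(y, X)) from exc
    if not res.mle_retvals.get("converged", True):
        raise SeparationError(_describe_separation(y, X))
    return res


def _describe_separation(y: np.ndarray, X: pd.DataFrame) -> str:
    for col in X.columns:
        x = X[col].to_numpy()
        if set(np.unique(x)) <= {0.0, 1.0}:
            for level in (0.0, 1.0):
                sub = y[x == level]
                if len(sub) > 0 and (sub.min() == sub.max()):
                    return f"perfect separation involving covariate {col!r}"
    return "logistic fit failed to converge (possible separation)"


def fit_backward_aic(
    data: pd.DataFrame,
    predictors: Sequence[str],
    outcome: str,
    name: str = "fitted",
) -> RiskModelSpec:
    """Maximum-likelihood logistic fit with backward elimination on AIC.

    Starting from the full model, repeatedly drops the predictor whose
    removal lowers AIC the most, until no removal lowers it.  Ties are broken
    by dropping the predictor with the larger Wald p-value.  Returns the
    fitted spec with standard errors, 95% CIs and the final AIC attached.
    """
    if len(data) <= len(predictors):
        raise ValueError("need more observations than predictors")
    y = data[outcome].to_numpy(dtype=float)
    current = list(predictors)
    res = _fit_logit(y, data[current])
    while len(current) > 1:
        candidates = []
        for drop in current:
            reduced = [p for p in current if p != drop]
            res_red = _fit_logit(y, data[reduced])
            candidates.append((res_red.aic, res.pvalues.get(drop, 0.0), drop, res_red, reduced))
        # best removal: lowest AIC; ties broken on the larger p-value
        candidates.sort(key=lambda c: (c[0], -c[1]))
        best_aic, _, drop, best_res, reduced = candidates[0]
        if best_aic < res.aic:
            log.info("backward elimination drops %s (AIC %.2f -> %.2f)", drop, res.aic, best_aic)
            current, res = reduced, best_res
        else:
            break
    params = res.params
    ci = res.conf_int()
    return RiskModelSpec(
        name=name,
        intercept=float(params["const"]),
        coefficients={p: float(params[p]) for p in current},
        se={k: float(res.bse[k]) for k in params.index},
        conf_int={k: (float(ci.loc[k, 0]), float(ci.loc[k, 1])) for k in params.index},
        aic=float(res.aic),
    )


def fit_full_logit(
    data: pd.DataFrame,
    predictors: Sequence[str],
    outcome: str,
    name: str = "fitted",
) -> RiskModelSpec:
    """Plain maximum-likelihood logistic fit of a fixed predictor set."""
    y = data[outcome].to_numpy(dtype=float)
    res = _fit_logit(y, data[list(predictors)])
    params = res.params
    ci = res.conf_int()
    return RiskModelSpec(
        name=name,
        intercept=float(params["const"]),
        coefficients={p: float(params[p]) for p in predictors},
        se={k: float(res.bse[k]) for k in params.index},
        conf_int={k: (float(ci.loc[k, 0]), float(ci.loc[k, 1])) for k in params.index},
        aic=float(res.aic),
    )


def simplify_to_points(spec: RiskModelSpec, divisor: int = 4) -> dict:
    """Integer point table: each coefficient becomes ``round(coefficient × divisor)``.

    Predicted risk for a total of ``s`` points is
    ``logistic(intercept + s/divisor)``, so each point approximates its
    coefficient to within 1/(2·divisor) on the log-odds scale.
    """
    points = {
        name: int(math.floor(coef * divisor + 0.5)) if coef >= 0 else -int(
            math.floor(-coef * divisor + 0.5)
        )
        for name, coef in spec.coefficients.items()
    }
    return {
        "name": f"{spec.name}_points",
        "intercept": spec.intercept,
        "divisor": divisor,
        "points": points,
    }
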