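"""Kidney-function engine: eGFR, baseline creatinine, AKI and CKD staging.

All creatinine values are in µmol/l (88.4 µmol/l = 1 mg/dl); eGFR is in
ml/min/1.73 m².  AKI is staged from serum creatinine (SCr) relative to a
pre-admission baseline using the KDIGO creatinine criteria:

* stage 1 — SCr 1.5–1.99 × baseline, or an absolute rise ≥ 26.5 µmol/l;
* stage 2 — SCr 2–2.99 × baseline;
* stage 3 — SCr ≥ 3 × baseline, or SCr ≥ 353.6 µmol/l once stage 1 has
  already been met, or initiation of renal replacement therapy (RRT).

The baseline is the mean of all SCr values drawn 7–365 days before
admission; when none exists it is back-calculated from the MDRD equation
assuming an eGFR of 75 ml/min/1.73 m².  Staging is revised after every
in-admission result and the episode keeps the worst stage reached.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Sequence

log = logging.getLogger(__name__)

#: µmol/l per mg/dl
UMOL_PER_MGDL = 88.4
#: absolute-rise criterion for stage 1 (0.3 mg/dl)
ABS_RISE_UMOL = 26.5
#: absolute-concentration criterion for stage 3 (4.0 mg/dl)
SCR_STAGE3_UMOL = 353.6
#: eGFR assumed when back-calculating an estimated baseline SCr
DEFAULT_ASSUMED_EGFR = 75.0


class TriggerRule(str, enum.Enum):
    """Which KDIGO creatinine rule produced a stage."""

    NONE = "none"
    RATIO = "ratio"
    ABSOLUTE_RISE = "absolute_rise"
    SCR_GE_353_6 = "scr_ge_353_6"
    RRT = "rrt"


class CKDStageLabel(str, enum.Enum):
    G1 = "G1_normal"
    G2 = "G2"
    G3A = "G3A"
    G3B = "G3B"
    G4 = "G4"
    G5 = "G5"


class BaselineProvenance(str, enum.Enum):
    MEASURED_MEAN = "measured_mean"
    ESTIMATED = "estimated"


@dataclass
class CreatinineSeries:
    """Timestamped serum creatinine values for one hospital episode.

    Measurements are stored sorted by time; values are µmol/l and must be
    positive.  ``admission_ts``/``discharge_ts`` anchor the pre-admission,
    in-admission and post-discharge windows.
    """

    times: list[datetime]
    values: list[float]
    admission_ts: datetime | None = None
    discharge_ts: datetime | None = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if any(v <= 0 for v in self.values):
            raise ValueError("serum creatinine must be positive")
        order = sorted(range(len(self.times)), key=lambda i: self.times[i])
        self.times = [self.times[i] for i in order]
        self.values = [self.values[i] for i in order]

    def __len__(self) -> int:
        return len(self.values)

    # -- window helpers (whole days elapsed) --------------------------------
    def pre_admission(self, window: tuple[int, int] = (7, 365)) -> list[float]:
        """Values measured ``window[0]``–``window[1]`` whole days before admission."""
        if self.admission_ts is None:
            return []
        lo, hi = window
        out = []
        for t, v in zip(self.times, self.values):
            days_before = _whole_days(t, self.admission_ts)
            if lo <= days_before <= hi:
                out.append(v)
        return out

    def in_admission(self) -> list[tuple[datetime, float]]:
        """Measurements taken between admission and discharge (inclusive)."""
        if self.admission_ts is None:
            return []
        out = []
        for t, v in zip(self.times, self.values):
            if t >= self.admission_ts and (self.discharge_ts is None or t <= self.discharge_ts):
                out.append((t, v))
        return out

    def post_discharge(self, window: tuple[int, int] = (90, 365)) -> list[float]:
        """Values measured ``window[0]``–``window[1]`` whole days after discharge."""
        if self.discharge_ts is None:
            return []
        lo, hi = window
        out = []
        for t, v in zip(self.times, self.values):
            days_after = _whole_days(self.discharge_ts, t)
            if lo <= days_after <= hi:
                out.append(v)
        return out


def _whole_days(earlier: datetime, later: datetime) -> int:
    """Whole days elapsed from ``earlier`` to ``later`` (negative if reversed)."""
    seconds = (later - earlier).total_seconds()
    return math.floor(seconds / 86400.0)


@dataclass
class BaselineResult:
    value: float
    provenance: BaselineProvenance
    n_values_used: int
    window: tuple[int, int]

    def __post_init__(self) -> None:
        if self.provenance is BaselineProvenance.MEASURED_MEAN and self.n_values_used < 1:
            raise ValueError("measured_mean baseline requires >= 1 value")
        if self.provenance is BaselineProvenance.ESTIMATED and self.n_values_used != 0:
            raise ValueError("estimated baseline uses no measured values")


@dataclass
class AKIAssessment:
    per_measurement: list[tuple[datetime, int, TriggerRule]]
    worst_stage: int
    admission_stage: int
    baseline: BaselineResult
    rrt: bool = False


@dataclass
class CKDStage:
    stage: CKDStageLabel
    egfr: float | None
    basis: str  # pre_admission | post_discharge | imputed_stage2


@dataclass
class RecoveryResult:
    evaluable: bool
    percent_change: float | None = None
    dialysis_dependent: bool = False


class NotAssessableError(ValueError):
    """Raised when an episode lacks the measurements a computation needs."""


# ---------------------------------------------------------------------------
# eGFR and baseline estimation
# ---------------------------------------------------------------------------

def compute_egfr_mdrd(
    scr_umol: float,
    age_years: float,
    sex: str,
    ethnicity: str = "non_black",
    coefficient: float = 175.0,
) -> float:
    """4-variable MDRD eGFR (ml/min/1.73 m²), IDMS-traceable 175 coefficient.

    ``eGFR = 175 × (SCr/88.4)^−1.154 × age^−0.203 [× 0.742 female] [× 1.212 black]``

    Unknown ethnicity is treated as non-black (no 1.212 factor).
    """
    if scr_umol <= 0:
        raise ValueError(f"serum creatinine must be positive, got {scr_umol}")
    if age_years < 18:
        raise ValueError("MDRD eGFR is defined for adults (age >= 18)")
    egfr = coefficient * (scr_umol / UMOL_PER_MGDL) ** -1.154 * age_years ** -0.203
    if sex.upper() == "F":
        egfr *= 0.742
    if ethnicity == "black":
        egfr *= 1.212
    elif ethnicity == "unknown":
        log.debug("unknown ethnicity treated as non-black for MDRD")
    return egfr


def estimate_baseline_scr(
    age_years: float,
    sex: str,
    ethnicity: str = "non_black",
    assumed_egfr: float = DEFAULT_ASSUMED_EGFR,
    coefficient: float = 175.0,
) -> float:
    """Estimated baseline SCr (µmol/l) by analytic inversion of MDRD.

    Solves ``compute_egfr_mdrd(scr, ...) == assumed_egfr`` for scr; the
    default assumed eGFR of 75 ml/min/1.73 m² follows KDIGO guidance for
    patients with no measured pre-admission creatinine.
    """
    if age_years < 18:
        raise ValueError("baseline estimation is defined for adults (age >= 18)")
    factor = coefficient * age_years ** -0.203
    if sex.upper() == "F":
        factor *= 0.742
    if ethnicity == "black":
        factor *= 1.212
    return UMOL_PER_MGDL * (assumed_egfr / factor) ** (-1.0 / 1.154)


def establish_baseline(
    series: CreatinineSeries,
    age_years: float,
    sex: str,
    ethnicity: str = "non_black",
    window: tuple[int, int] = (7, 365),
    assumed_egfr: float = DEFAULT_ASSUMED_EGFR,
) -> BaselineResult:
    """Baseline SCr: mean of pre-admission values in ``window``, else estimated."""
    pre = series.pre_admission(window)
    if pre:
        return BaselineResult(
            value=sum(pre) / len(pre),
            provenance=BaselineProvenance.MEASURED_MEAN,
            n_values_used=len(pre),
            window=window,
        )
    est = estimate_baseline_scr(age_years, sex, ethnicity, assumed_egfr)
    return BaselineResult(
        value=est, provenance=BaselineProvenance.ESTIMATED, n_values_used=0, window=window
    )


# ---------------------------------------------------------------------------
# AKI staging
# ---------------------------------------------------------------------------

def stage_single(
    scr_umol: float, baseline_umol: float, prior_stage1_met: bool = False
) -> tuple[int, TriggerRule]:
    """Stage one SCr value against a baseline; returns (stage, triggering rule).

    Ratio bands are half-open ([1.5, 2), [2, 3), [3, ∞)).  The ≥353.6 µmol/l
    rule promotes to stage 3 when stage 1 was met earlier in the episode or by
    this same measurement through the ratio/absolute-rise rules.  When both
    stage-1 rules fire, the ratio rule is reported.
    """
    if baseline_umol <= 0:
        raise ValueError(f"baseline must be positive, got {baseline_umol}")
    ratio = scr_umol / baseline_umol
    rise = scr_umol - baseline_umol
    meets_stage1 = ratio >= 1.5 or rise >= ABS_RISE_UMOL
    if ratio >= 3.0:
        return 3, TriggerRule.RATIO
    if scr_umol >= SCR_STAGE3_UMOL and (prior_stage1_met or meets_stage1):
        return 3, TriggerRule.SCR_GE_353_6
    if ratio >= 2.0:
        return 2, TriggerRule.RATIO
    if ratio >= 1.5:
        return 1, TriggerRule.RATIO
    if rise >= ABS_RISE_UMOL:
        return 1, TriggerRule.ABSOLUTE_RISE
    return 0, TriggerRule.NONE


def assess_episode(
    series: CreatinineSeries,
    baseline: BaselineResult,
    rrt_flag: bool = False,
) -> AKIAssessment:
    """Stage every in-admission SCr in time order and record the worst stage.

    Mirrors a rolling e-alert: staging is revised after each new result, with
    the stage-1-met flag carried forward so a later SCr ≥ 353.6 µmol/l can be
    promoted to stage 3.  RRT initiation forces stage 3 retrospectively.
    The admission stage is the stage of the first in-admission measurement.
    """
    inpatient = series.in_admission()
    if not inpatient:
        raise NotAssessableError("no in-admission creatinine measurements")
    per: list[tuple[datetime, int, TriggerRule]] = []
    prior_stage1 = False
    for t, v in inpatient:
        stage, rule = stage_single(v, baseline.value, prior_stage1)
        per.append((t, stage, rule))
        if stage >= 1:
            prior_stage1 = True
    worst = max(s for _, s, _ in per)
    if rrt_flag:
        worst = 3
    return AKIAssessment(
        per_measurement=per,
        worst_stage=worst,
        admission_stage=per[0][1],
        baseline=baseline,
        rrt=rrt_flag,
    )


# ---------------------------------------------------------------------------
# CKD staging and renal recovery
# ---------------------------------------------------------------------------

#: (lower eGFR bound inclusive, stage); scanned top-down, <15 falls to G5
_CKD_BANDS: Sequence[tuple[float, CKDStageLabel]] = (
    (90.0, CKDStageLabel.G1),
    (60.0, CKDStageLabel.G2),
    (45.0, CKDStageLabel.G3A),
    (30.0, CKDStageLabel.G3B),
    (15.0, CKDStageLabel.G4),
)


def ckd_stage_from_egfr(egfr: float) -> CKDStageLabel:
    """Map a positive finite eGFR to its CKD G-stage band (a partition)."""
    if not (egfr > 0 and math.isfinite(egfr)):
        raise ValueError(f"eGFR must be positive and finite, got {egfr}")
    for lower, label in _CKD_BANDS:
        if egfr >= lower:
            return label
    return CKDStageLabel.G5


#: CKD stages counted as "stage 3B-5" in the risk models (eGFR < 45)
CKD_3B_5 = {CKDStageLabel.G3B, CKDStageLabel.G4, CKDStageLabel.G5}


def ckd_stage(
    series: CreatinineSeries,
    age_years: float,
    sex: str,
    ethnicity: str = "non_black",
    basis: str = "pre_admission",
    window: tuple[int, int] | None = None,
    impute_stage2: bool = False,
) -> CKDStage:
    """CKD stage from the mean SCr in the pre-admission or post-discharge window.

    With no value in the window: returns G2 (``basis='imputed_stage2'``) when
    imputation is requested — the convention used for patients without a
    measured pre-admission SCr — otherwise raises :class:`NotAssessableError`.
    """
    if basis == "pre_admission":
        values = series.pre_admission(window or (7, 365))
    elif basis == "post_discharge":
        values = series.post_discharge(window or (90, 365))
    else:
        raise ValueError(f"unknown CKD basis {basis!r}")
    if not values:
        if impute_stage2:
            return CKDStage(stage=CKDStageLabel.G2, egfr=None, basis="imputed_stage2")
        raise NotAssessableError(f"no creatinine values in {basis} window")
    mean_scr = sum(values) / len(values)
    egfr = compute_egfr_mdrd(mean_scr, age_years, sex, ethnicity)
    return CKDStage(stage=ckd_stage_from_egfr(egfr), egfr=egfr, basis=basis)


def classify_recovery(
    series: CreatinineSeries,
    baseline: BaselineResult,
    dialysis_flag: bool = False,
    window: tuple[int, int] = (90, 365),
) -> RecoveryResult:
    """Post-discharge renal recovery vs the measured pre-admission baseline.

    Percent change = 100 × (mean post-discharge SCr − baseline)/baseline over
    the 90–365 day window (shorter-term changes may still be resolving AKI).
    An estimated baseline or an empty window makes the result non-evaluable
    rather than an error.
    """
    if baseline.provenance is not BaselineProvenance.MEASURED_MEAN:
        return RecoveryResult(evaluable=False, dialysis_dependent=dialysis_flag)
    post = series.post_discharge(window)
    if not post:
        return RecoveryResult(evaluable=False, dialysis_dependent=dialysis_flag)
    mean_post = sum(post) / len(post)
    pct = 100.0 * (mean_post - baseline.value) / baseline.value
    return RecoveryResult(evaluable=True, percent_change=pct, dialysis_dependent=dialysis_flag)
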