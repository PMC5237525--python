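"""High-level pipeline: stage a cohort, build covariate/score tables.

Chains the kidney-function engine over every episode of a cohort and
assembles the flat tables the risk models, frailty score and validation
statistics consume.  Episodes already on long-term dialysis for end-stage
renal disease are excluded before staging, with a logged reason code.
"""

from __future__ import annotations

import logging

import pandas as pd

from .cohort import CohortDataset, RunConfig
from .frailty import nhfs_for_episode
from .models import extract_covariates, nh_risk
from .renal import (
    AKIAssessment,
    NotAssessableError,
    TriggerRule,
    assess_episode,
    ckd_stage,
    establish_baseline,
)

log = logging.getLogger(__name__)


def stage_cohort(
    dataset: CohortDataset, config: RunConfig | None = None
) -> tuple[dict[str, AKIAssessment], pd.DataFrame]:
    """Run baseline establishment and KDIGO staging over every episode.

    Returns per-episode assessments plus a staging table (one row per staged
    episode: baseline value/provenance, admission and worst stage, trigger
    rule, number of in-admission values).  Excluded episodes (ESRD on
    dialysis, no creatinine series, no in-admission measurement) are logged
    with a reason code and omitted from the table.
    """
    config = config or RunConfig()
    assessments: dict[str, AKIAssessment] = {}
    rows = []
    for ep in dataset.episodes:
        if ep.esrd_on_dialysis:
            log.info("excluded %s: esrd_on_dialysis", ep.episode_id)
            continue
        series = dataset.creatinine.get(ep.episode_id)
        if series is None or len(series) == 0:
            log.info("excluded %s: no_creatinine_series", ep.episode_id)
            continue
        baseline = establish_baseline(
            series,
            ep.age_years,
            ep.sex,
            ep.ethnicity,
            window=config.baseline_window_days,
            assumed_egfr=config.assumed_egfr_for_imputation,
        )
        try:
            assessment = assess_episode(
                series, baseline, rrt_flag=bool(ep.received_rrt_in_admission)
            )
        except NotAssessableError:
            log.info("excluded %s: no_inpatient_scr", ep.episode_id)
            continue
        assessments[ep.episode_id] = assessment
        worst_rules = [r for _, s, r in assessment.per_measurement if s == assessment.worst_stage]
        trigger = TriggerRule.RRT if assessment.rrt else (
            worst_rules[0] if worst_rules else TriggerRule.NONE
        )
        rows.append(
            {
                "episode_id": ep.episode_id,
                "baseline_value": baseline.value,
                "baseline_provenance": baseline.provenance.value,
                "admission_stage": assessment.admission_stage,
                "worst_stage": assessment.worst_stage,
                "trigger_rule": trigger.value,
                "n_inpatient_scr": len(assessment.per_measurement),
            }
        )
    return assessments, pd.DataFrame(rows)


def covariate_table(dataset: CohortDataset, config: RunConfig | None = None) -> pd.DataFrame:
    """Model-ready table: covariates, NHFS, NH-RISK and the staged AKI outcome.

    The CKD 3B–5 indicator comes from the measured pre-admission baseline
    when one exists and is imputed to stage 2 (indicator 0) otherwise,
    matching the convention of the published models.
    """
    config = config or RunConfig()
    assessments, staging = stage_cohort(dataset, config)
    staged = staging.set_index("episode_id")
    rows = []
    for ep in dataset.episodes:
        if ep.episode_id not in assessments:
            continue
        series = dataset.creatinine[ep.episode_id]
        try:
            ckd = ckd_stage(
                series,
                ep.age_years,
                ep.sex,
                ep.ethnicity,
                basis="pre_admission",
                window=config.baseline_window_days,
                impute_stage2=False,
            )
        except NotAssessableError:
            ckd = None  # imputed stage 2 => indicator 0
        worst = int(staged.loc[ep.episode_id, "worst_stage"])
        cov = extract_covariates(ep, ckd, aki=worst >= 1)
        score = nh_risk(cov)
        rows.append(
            {
                "episode_id": ep.episode_id,
                **cov,
                "worst_stage": worst,
                "aki": int(worst >= 1),
                "nhfs": nhfs_for_episode(ep),
                "nhrisk_points": score.points,
                "nhrisk_predicted": score.predicted_risk,
            }
        )
    return pd.DataFrame(rows)
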