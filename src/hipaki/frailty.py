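"""Nottingham Hip Fracture Score (NHFS).

A weighted seven-factor frailty score (range 0–10) predicting 30-day
mortality after hip fracture.  Components: age band, cognitive impairment
on admission (AMTS < 7), not living at home, male sex, anaemia
(haemoglobin < 100 g/l), previous malignancy, and more than one of four
defined comorbidities (stroke/TIA, cardiovascular disease, diabetes,
previously diagnosed renal disease).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .cohort import PatientEpisode

log = logging.getLogger(__name__)

#: NHFS weights.  Age 66–85 scores 3 and ≥86 scores 4; every boolean
#: component scores 1.  Kept as a table so the weighting can be adjusted in
#: one place; the maximum attainable score is 10.
NHFS_WEIGHTS: dict[str, int] = {
    "age_66_85": 3,
    "age_ge_86": 4,
    "amts_lt_7": 1,
    "not_admitted_from_home": 1,
    "male": 1,
    "hb_lt_100": 1,
    "malignancy": 1,
    "two_plus_comorbidities": 1,
}

#: the four comorbidities counted for the ">1 comorbidity" component
COMORBIDITY_FLAGS = ("stroke_tia", "cardiovascular", "diabetes", "renal_disease")

#: NHFS age-band cut points.  Distinct from the risk models' 65/85 bands —
#: the two conventions must not be conflated.
NHFS_AGE_BANDS = {"band1": (66, 85), "band2_min": 86}

MIN_ADULT_AGE = 18


@dataclass
class NHFSComponents:
    age_66_85: bool
    age_ge_86: bool
    amts_lt_7: bool
    not_admitted_from_home: bool
    male: bool
    hb_lt_100: bool
    malignancy: bool
    two_plus_comorbidities: bool


def comorbidity_count(episode: PatientEpisode) -> tuple[int, bool]:
    """Count of the four defined comorbidity flags and the >1 indicator."""
    count = sum(int(getattr(episode, flag, 0) or 0) for flag in COMORBIDITY_FLAGS)
    return count, count >= 2


def nhfs_components(episode: PatientEpisode) -> NHFSComponents:
    """Resolve the seven NHFS components from an episode.

    A missing AMTS or haemoglobin scores 0 for that component (the deficit
    cannot be asserted); the missingness is logged.
    """
    if episode.age_years < MIN_ADULT_AGE:
        raise ValueError(f"NHFS is defined for adults, got age {episode.age_years}")
    lo, hi = NHFS_AGE_BANDS["band1"]
    if episode.amts is None:
        log.debug("episode %s: missing AMTS scores 0", episode.episode_id)
    if episode.admission_hb_g_per_l is None:
        log.debug("episode %s: missing haemoglobin scores 0", episode.episode_id)
    _, two_plus = comorbidity_count(episode)
    return NHFSComponents(
        age_66_85=lo <= episode.age_years <= hi,
        age_ge_86=episode.age_years >= NHFS_AGE_BANDS["band2_min"],
        amts_lt_7=episode.amts is not None and episode.amts < 7,
        not_admitted_from_home=not bool(episode.admitted_from_home),
        male=episode.sex.upper() == "M",
        hb_lt_100=(
            episode.admission_hb_g_per_l is not None and episode.admission_hb_g_per_l < 100
        ),
        malignancy=bool(episode.malignancy),
        two_plus_comorbidities=two_plus,
    )


def nhfs(components: NHFSComponents) -> int:
    """Weighted NHFS total, an integer in [0, 10]."""
    if components.age_66_85 and components.age_ge_86:
        raise ValueError("age bands are mutually exclusive")
    score = 0
    for name, weight in NHFS_WEIGHTS.items():
        if getattr(components, name):
            score += weight
    return score


def nhfs_for_episode(episode: PatientEpisode) -> int:
    return nhfs(nhfs_components(episode))
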