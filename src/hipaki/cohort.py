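"""Cohort I/O: CSV schemas, run configuration and row-level validation.

Two tables describe a cohort.  ``episodes.csv`` has one row per hip-fracture
admission (demographics, comorbidity flags, admission covariates, outcome
flags); ``creatinine.csv`` holds the timestamped serum creatinine values for
those episodes.  Creatinine is stored internally in µmol/l; rows may declare
``mg_dl`` and are converted (× 88.4) at read time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from datetime import datetime
from pathlib import Path

import pandas as pd
import yaml

from .renal import UMOL_PER_MGDL, CreatinineSeries

log = logging.getLogger(__name__)

EPISODE_COLUMNS = [
    "episode_id",
    "age_years",
    "sex",
    "ethnicity",
    "admit_ts",
    "discharge_ts",
    "death_ts",
    "admitted_from_home",
    "amts",
    "admission_hb_g_per_l",
    "diabetes",
    "stroke_tia",
    "cardiovascular",
    "renal_disease",
    "malignancy",
    "esrd_on_dialysis",
    "received_rrt_in_admission",
    "critical_care",
]
#: columns that may be blank
_OPTIONAL = {"discharge_ts", "death_ts", "amts", "admission_hb_g_per_l"}

CREATININE_COLUMNS = ["episode_id", "measured_ts", "scr_value", "unit"]


class SchemaError(ValueError):
    """A required column is missing or a table is structurally invalid."""


class IntegrityError(ValueError):
    """Cross-row constraint violated (e.g. duplicate episode ids)."""


@dataclass
class PatientEpisode:
    """One hip-fracture admission."""

    episode_id: str
    age_years: float
    sex: str  # M | F
    ethnicity: str = "non_black"  # black | non_black | unknown
    admit_ts: datetime | None = None
    discharge_ts: datetime | None = None
    death_ts: datetime | None = None
    admitted_from_home: int = 1
    amts: float | None = None
    admission_hb_g_per_l: float | None = None
    diabetes: int = 0
    stroke_tia: int = 0
    cardiovascular: int = 0
    renal_disease: int = 0
    malignancy: int = 0
    esrd_on_dialysis: int = 0
    received_rrt_in_admission: int = 0
    critical_care: int = 0


@dataclass
class CohortDataset:
    """Validated cohort: episodes plus their creatinine series."""

    episodes: list[PatientEpisode]
    creatinine: dict[str, CreatinineSeries]
    provenance: str = "user-supplied"

    def __post_init__(self) -> None:
        ids = [e.episode_id for e in self.episodes]
        if len(ids) != len(set(ids)):
            raise IntegrityError("duplicate episode ids")
        orphans = set(self.creatinine) - set(ids)
        if orphans:
            raise IntegrityError(f"creatinine series without episode: {sorted(orphans)[:5]}")
        for ep in self.episodes:
            if ep.admit_ts and ep.discharge_ts and not ep.admit_ts < ep.discharge_ts:
                raise IntegrityError(f"episode {ep.episode_id}: admission not before discharge")

    def __len__(self) -> int:
        return len(self.episodes)

    def episode(self, episode_id: str) -> PatientEpisode:
        for ep in self.episodes:
            if ep.episode_id == episode_id:
                return ep
        raise KeyError(episode_id)


@dataclass
class RunConfig:
    """Pipeline configuration; all randomness flows from ``seed``."""

    seed: int = 0
    split_ratio: float = 0.66
    baseline_window_days: tuple[int, int] = (7, 365)
    recovery_window_days: tuple[int, int] = (90, 365)
    assumed_egfr_for_imputation: float = 75.0
    hl_groups: int = 10
    output_dir: str = "."

    def __post_init__(self) -> None:
        for name in ("baseline_window_days", "recovery_window_days"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lower bound must be < upper bound")
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must be in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        for name in ("baseline_window_days", "recovery_window_days"):
            if name in data:
                data[name] = tuple(data[name])
        return cls(**data)


@dataclass
class RejectionReport:
    """Per-row exclusions recorded while reading a cohort."""

    accepted: int = 0
    rejected: list[tuple[str, int, str]] = field(default_factory=list)  # (table, row, reason)

    def add(self, table: str, row: int, reason: str) -> None:
        self.rejected.append((table, row, reason))
        log.warning("excluded %s row %d: %s", table, row, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def _require_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")


def _parse_ts(value) -> datetime | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    ts = pd.Timestamp(value)
    if pd.isna(ts):
        return None
    return ts.to_pydatetime()


def read_cohort(
    episodes_path: str | Path,
    creatinine_path: str | Path,
    provenance: str = "user-supplied",
) -> tuple[CohortDataset, RejectionReport]:
    """Read and validate the two cohort CSVs.

    Rows with unparseable dates, non-positive creatinine or unknown episode
    ids are rejected individually and tallied in the returned
    :class:`RejectionReport`; structural problems (missing columns, duplicate
    episode ids) raise instead.
    """
    report = RejectionReport()
    edf = pd.read_csv(episodes_path, dtype={"episode_id": str})
    _require_columns(edf, EPISODE_COLUMNS, "episodes")
    if edf["episode_id"].duplicated().any():
        dups = edf.loc[edf["episode_id"].duplicated(), "episode_id"].tolist()
        raise IntegrityError(f"duplicate episode id(s): {dups[:5]}")

    episodes: list[PatientEpisode] = []
    for i, row in edf.iterrows():
        try:
            admit = _parse_ts(row["admit_ts"])
            discharge = _parse_ts(row["discharge_ts"])
            death = _parse_ts(row["death_ts"])
            if admit is None:
                raise ValueError("unparseable admit_ts")
        except (ValueError, TypeError) as exc:
            report.add("episodes", int(i), f"bad_timestamp: {exc}")
            continue
        sex = str(row["sex"]).upper()
        if sex not in ("M", "F"):
            report.add("episodes", int(i), f"bad_sex: {row['sex']!r}")
            continue
        episodes.append(
            PatientEpisode(
                episode_id=str(row["episode_id"]),
                age_years=float(row["age_years"]),
                sex=sex,
                ethnicity=str(row["ethnicity"]) if pd.notna(row["ethnicity"]) else "unknown",
                admit_ts=admit,
                discharge_ts=discharge,
                death_ts=death,
                admitted_from_home=int(row["admitted_from_home"]),
                amts=float(row["amts"]) if pd.notna(row["amts"]) else None,
                admission_hb_g_per_l=(
                    float(row["admission_hb_g_per_l"])
                    if pd.notna(row["admission_hb_g_per_l"])
                    else None
                ),
                diabetes=int(row["diabetes"]),
                stroke_tia=int(row["stroke_tia"]),
                cardiovascular=int(row["cardiovascular"]),
                renal_disease=int(row["renal_disease"]),
                malignancy=int(row["malignancy"]),
                esrd_on_dialysis=int(row["esrd_on_dialysis"]),
                received_rrt_in_admission=int(row["received_rrt_in_admission"]),
                critical_care=int(row["critical_care"]),
            )
        )
        report.accepted += 1

    by_id = {e.episode_id: e for e in episodes}
    cdf = pd.read_csv(creatinine_path, dtype={"episode_id": str})
    _require_columns(cdf, CREATININE_COLUMNS, "creatinine")
    times: dict[str, list[datetime]] = {}
    values: dict[str, list[float]] = {}
    for i, row in cdf.iterrows():
        eid = str(row["episode_id"])
        if eid not in by_id:
            report.add("creatinine", int(i), f"orphan_row: unknown episode {eid}")
            continue
        try:
            ts = _parse_ts(row["measured_ts"])
            if ts is None:
                raise ValueError("unparseable measured_ts")
        except (ValueError, TypeError) as exc:
            report.add("creatinine", int(i), f"bad_timestamp: {exc}")
            continue
        value = float(row["scr_value"])
        unit = str(row["unit"])
        if unit == "mg_dl":
            value *= UMOL_PER_MGDL
        elif unit != "umol_l":
            report.add("creatinine", int(i), f"bad_unit: {unit!r}")
            continue
        if value <= 0:
            report.add("creatinine", int(i), f"non_positive_scr: {row['scr_value']}")
            continue
        times.setdefault(eid, []).append(ts)
        values.setdefault(eid, []).append(value)
        report.accepted += 1

    series = {
        eid: CreatinineSeries(
            times=times[eid],
            values=values[eid],
            admission_ts=by_id[eid].admit_ts,
            discharge_ts=by_id[eid].discharge_ts,
        )
        for eid in times
    }
    dataset = CohortDataset(episodes=episodes, creatinine=series, provenance=provenance)
    return dataset, report


def write_cohort(dataset: CohortDataset, episodes_path: str | Path, creatinine_path: str | Path) -> None:
    """Write a cohort back to the two CSV schemas (µmol/l, ISO timestamps)."""
    rows = []
    for ep in dataset.episodes:
        rows.append(
            {
                "episode_id": ep.episode_id,
                "age_years": ep.age_years,
                "sex": ep.sex,
                "ethnicity": ep.ethnicity,
                "admit_ts": ep.admit_ts.isoformat() if ep.admit_ts else "",
                "discharge_ts": ep.discharge_ts.isoformat() if ep.discharge_ts else "",
                "death_ts": ep.death_ts.isoformat() if ep.death_ts else "",
                "admitted_from_home": ep.admitted_from_home,
                "amts": "" if ep.amts is None else ep.amts,
                "admission_hb_g_per_l": (
                    "" if ep.admission_hb_g_per_l is None else ep.admission_hb_g_per_l
                ),
                "diabetes": ep.diabetes,
                "stroke_tia": ep.stroke_tia,
                "cardiovascular": ep.cardiovascular,
                "renal_disease": ep.renal_disease,
                "malignancy": ep.malignancy,
                "esrd_on_dialysis": ep.esrd_on_dialysis,
                "received_rrt_in_admission": ep.received_rrt_in_admission,
                "critical_care": ep.critical_care,
            }
        )
    pd.DataFrame(rows, columns=EPISODE_COLUMNS).to_csv(episodes_path, index=False)

    crows = []
    for eid, series in dataset.creatinine.items():
        for t, v in zip(series.times, series.values):
            crows.append(
                {
                    "episode_id": eid,
                    "measured_ts": t.isoformat(),
                    "scr_value": repr(float(v)),
                    "unit": "umol_l",
                }
            )
    pd.DataFrame(crows, columns=CREATININE_COLUMNS).to_csv(creatinine_path, index=False)


def write_report(report, path: str | Path) -> None:
    """Serialise a validation report (JSON) or calibration table (CSV).

    ``report`` may be a :class:`hipaki.validation.ValidationReport` (written
    as JSON) or a calibration-table ``DataFrame`` (written as CSV with one
    row per score: predicted risk and observed rate per dataset).
    Refuses to write an empty report.
    """
    path = Path(path)
    if isinstance(report, pd.DataFrame):
        if report.empty:
            raise ValueError("refusing to write an empty calibration table")
        report.to_csv(path, index=False)
        return
    data = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    if not data:
        raise ValueError("refusing to write an empty report")
    path.write_text(json.dumps(data, indent=2))
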