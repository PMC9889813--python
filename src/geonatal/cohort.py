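"""Birth-record ingestion, exclusions, outcome classification and aggregation.

Each live birth is classified on two axes: low birth weight (LBW,
birthweight < 2500 g) and preterm birth (PTB, gestational age < 37
completed weeks).  Their cross gives four mutually exclusive groups —
LBW_pre, LBW_term, NBW_pre, NBW_term — so that by construction
LBW = LBW_term + LBW_pre and PTB = LBW_pre + NBW_pre.

Maternal age is binned twice: a fine 9-class partition
(≤15, (15,20], ..., (45,50], >50) used for age standardization, and a
coarse 3-class reporting partition (≤20, (20,35], >35) used for
stratified analyses and summary tables.  All intervals are
left-open/right-closed apart from the open-ended extremes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

LBW_THRESHOLD_G = 2500
PTB_THRESHOLD_WK = 37

#: plausibility bounds for gestational age of a live birth, completed weeks
GESTATION_RANGE_WK = (20, 45)

#: fine maternal-age partition (upper edges of the right-closed bins)
AGE_CLASS_EDGES = (15, 20, 25, 30, 35, 40, 45, 50)
N_AGE_CLASSES = 9

#: coarse reporting partition used by the stratified scans
REPORTING_STRATA = ("<=20", "(20,35]", ">35")

#: canonical birth-record CSV columns
RECORD_COLUMNS = (
    "municipality_id",
    "year",
    "birthweight_g",
    "gestational_weeks",
    "maternal_age",
    "plurality",
    "sex",
)

OUTCOMES = ("lbw", "ptb", "lbwterm", "lbwpre")


class OutcomeGroup(str, Enum):
    """The four-way cross of birthweight and term status."""

    LBW_PRE = "LBW_pre"
    LBW_TERM = "LBW_term"
    NBW_PRE = "NBW_pre"
    NBW_TERM = "NBW_term"


@dataclass(frozen=True)
class OutcomeFlags:
    is_lbw: bool
    is_preterm: bool

    @property
    def group(self) -> OutcomeGroup:
        if self.is_lbw:
            return OutcomeGroup.LBW_PRE if self.is_preterm else OutcomeGroup.LBW_TERM
        return OutcomeGroup.NBW_PRE if self.is_preterm else OutcomeGroup.NBW_TERM


@dataclass
class ExclusionReport:
    """Tally of records dropped before analysis, by reason."""

    multiple: int = 0
    missing: int = 0

    @property
    def total(self) -> int:
        return self.multiple + self.missing


def classify_birth(birthweight_g: float, gestational_weeks: float) -> OutcomeFlags:
    """Classify one birth by weight and term status.

    Raises ``ValueError`` for missing or non-positive inputs: upstream
    filtering (:func:`apply_exclusions`) must have removed those, and a
    silent default classification would corrupt counts.
    """
    if birthweight_g is None or gestational_weeks is None:
        raise ValueError("birthweight and gestational age must be present")
    if not (birthweight_g > 0 and gestational_weeks > 0):
        raise ValueError(
            f"non-positive birth measurements: weight={birthweight_g}, "
            f"weeks={gestational_weeks}"
        )
    return OutcomeFlags(
        is_lbw=birthweight_g < LBW_THRESHOLD_G,
        is_preterm=gestational_weeks < PTB_THRESHOLD_WK,
    )


def assign_age_class(maternal_age: float) -> int:
    """Map maternal age in completed years to the fine class index 1..9."""
    if maternal_age < 0:
        raise ValueError(f"negative maternal age: {maternal_age}")
    # right-closed bins: age <= 15 -> 1, 15 < age <= 20 -> 2, ..., age > 50 -> 9
    return int(np.searchsorted(AGE_CLASS_EDGES, maternal_age, side="left")) + 1


def assign_reporting_stratum(maternal_age: float) -> str:
    """Map maternal age to the coarse stratum {<=20, (20,35], >35}."""
    if maternal_age <= 20:
        return REPORTING_STRATA[0]
    if maternal_age <= 35:
        return REPORTING_STRATA[1]
    return REPORTING_STRATA[2]


def read_birth_records(path) -> pd.DataFrame:
    """Read the birth-record CSV (empty fields are missing values)."""
    df = pd.read_csv(path, dtype={"municipality_id": str, "sex": str})
    missing_cols = set(RECORD_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"birth-record CSV lacks columns: {sorted(missing_cols)}")
    return df


def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop multiple births and records with missing analysis fields.

    A record is kept iff plurality == 1 and all of municipality_id,
    birthweight_g, gestational_weeks, maternal_age are present, with
    gestational age inside the live-birth plausibility window
    ``GESTATION_RANGE_WK`` (implausible values are treated as missing).
    Multiple-birth exclusion is tallied first, so a plural record with a
    missing field counts once, as "multiple".  Idempotent.
    """
    report = ExclusionReport()
    if len(records) == 0:
        return records.copy(), report

    df = records.copy()
    lo, hi = GESTATION_RANGE_WK
    gest = pd.to_numeric(df["gestational_weeks"], errors="coerce")
    gest = gest.where((gest >= lo) & (gest <= hi))
    weight = pd.to_numeric(df["birthweight_g"], errors="coerce")
    weight = weight.where(weight > 0)
    age = pd.to_numeric(df["maternal_age"], errors="coerce")
    age = age.where(age >= 0)

    is_multiple = pd.to_numeric(df["plurality"], errors="coerce").fillna(1) > 1
    has_missing = (
        gest.isna() | weight.isna() | age.isna() | df["municipality_id"].isna()
    )

    report.multiple = int(is_multiple.sum())
    report.missing = int((has_missing & ~is_multiple).sum())

    kept = df.loc[~is_multiple & ~has_missing].copy()
    kept["gestational_weeks"] = gest.loc[kept.index]
    kept["birthweight_g"] = weight.loc[kept.index]
    kept["maternal_age"] = age.loc[kept.index]
    if report.total:
        log.info(
            "exclusions: %d multiple, %d missing, %d kept",
            report.multiple, report.missing, len(kept),
        )
    return kept, report


def classify_records(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorized classification: append flag/group/age-class columns."""
    df = records.copy()
    df["is_lbw"] = df["birthweight_g"] < LBW_THRESHOLD_G
    df["is_preterm"] = df["gestational_weeks"] < PTB_THRESHOLD_WK
    df["group"] = np.select(
        [
            df["is_lbw"] & df["is_preterm"],
            df["is_lbw"] & ~df["is_preterm"],
            ~df["is_lbw"] & df["is_preterm"],
        ],
        [OutcomeGroup.LBW_PRE.value, OutcomeGroup.LBW_TERM.value,
         OutcomeGroup.NBW_PRE.value],
        default=OutcomeGroup.NBW_TERM.value,
    )
    df["age_class"] = (
        np.searchsorted(AGE_CLASS_EDGES, df["maternal_age"].to_numpy(), side="left") + 1
    )
    df["reporting_stratum"] = np.select(
        [df["maternal_age"] <= 20, df["maternal_age"] <= 35],
        [REPORTING_STRATA[0], REPORTING_STRATA[1]],
        default=REPORTING_STRATA[2],
    )
    return df


def _selector_mask(df: pd.DataFrame, outcome: str) -> pd.Series:
    outcome = outcome.lower()
    if outcome == "lbw":
        return df["is_lbw"]
    if outcome == "ptb":
        return df["is_preterm"]
    if outcome in ("lbwterm", "lbw_term"):
        return df["group"] == OutcomeGroup.LBW_TERM.value
    if outcome in ("lbwpre", "lbw_pre"):
        return df["group"] == OutcomeGroup.LBW_PRE.value
    raise ValueError(f"unknown outcome selector: {outcome!r}")


def aggregate_counts(
    records: pd.DataFrame,
    municipality_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Aggregate classified records to municipality × age-class count rows.

    Returns a frame with one row per (municipality_id, age_class 1..9)
    carrying the birth denominator and case counts for all four outcomes
    (columns ``n_cases_lbw``, ``n_cases_ptb``, ``n_cases_lbwterm``,
    ``n_cases_lbwpre``).  If ``municipality_ids`` (the geometry universe)
    is given, municipalities without births get zero rows and any record
    outside the universe raises ``KeyError`` naming the offending ids.
    """
    df = records if "group" in records.columns else classify_records(records)

    if municipality_ids is not None:
        universe = pd.Index(municipality_ids, dtype=str).unique()
        unknown = set(df["municipality_id"].astype(str)) - set(universe)
        if unknown:
            raise KeyError(
                f"records reference municipalities absent from geometry: "
                f"{sorted(unknown)[:10]}"
            )
    else:
        universe = pd.Index(sorted(df["municipality_id"].astype(str).unique()))

    grouped = df.groupby(
        [df["municipality_id"].astype(str), "age_class"], observed=True
    )
    out = grouped.agg(
        n_births=("municipality_id", "size"),
        n_cases_lbw=("is_lbw", "sum"),
        n_cases_ptb=("is_preterm", "sum"),
        n_cases_lbwterm=("group", lambda g: int((g == "LBW_term").sum())),
        n_cases_lbwpre=("group", lambda g: int((g == "LBW_pre").sum())),
    )
    full_index = pd.MultiIndex.from_product(
        [universe, range(1, N_AGE_CLASSES + 1)], names=["municipality_id", "age_class"]
    )
    out = out.reindex(full_index, fill_value=0).reset_index()
    for col in out.columns[2:]:
        out[col] = out[col].astype(int)
    return out


def write_count_table(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, index=False)


def partition_identity_holds(counts: pd.DataFrame) -> bool:
    """LBW cases must equal LBW_term + LBW_pre in every stratum row."""
    return bool(
        (counts["n_cases_lbw"] == counts["n_cases_lbwterm"] + counts["n_cases_lbwpre"])
        .all()
    )
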