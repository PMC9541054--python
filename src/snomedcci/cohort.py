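"""Study-cohort construction from claims-shaped tables.

Index event: the earliest inpatient visit (``visit_type == "IP"``) in the
requested calendar year, same-day ties broken by lowest visit id.
Eligibility: age >= 18 at index (age = calendar year - year of birth, since
claims carry year of birth only) and a single observation period spanning
the full 365-day lookback through index — gaps disqualify. The one-year
mortality outcome is a death date within 365 days after index, both ends
included; a death recorded before index is a data anomaly and excludes the
person (counted, not silently dropped).

Exclusions are applied in a fixed order and tallied into an attrition table
whose counts sum back to the number of persons considered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ContractError, SchemaError

logger = logging.getLogger(__name__)

ONE_YEAR_DAYS = 365
INPATIENT = "IP"

_REQUIRED_COLUMNS = {
    "persons": ["person_id", "year_of_birth", "sex"],
    "observation_periods": ["person_id", "start_date", "end_date"],
    "visits": ["person_id", "visit_id", "visit_start", "visit_type"],
    "condition_occurrences": ["person_id", "code", "vocabulary", "date"],
    "deaths": ["person_id", "death_date"],
}

#: attrition stages, in application order
ATTRITION_STAGES = (
    "no_inpatient_visit_in_year",
    "age_under_18",
    "insufficient_prior_observation",
    "death_before_index",
    "eligible",
)


@dataclass
class ClaimsBundle:
    """Claims-shaped tables (delimited-text friendly).

    Date columns are parsed to day precision; malformed dates are rejected
    row-wise by :meth:`validate` with a per-table count.
    """

    persons: pd.DataFrame
    observation_periods: pd.DataFrame
    visits: pd.DataFrame
    condition_occurrences: pd.DataFrame
    deaths: pd.DataFrame
    rejected_rows: dict[str, int] = field(default_factory=dict)

    def validate(self) -> "ClaimsBundle":
        """Check schemas, parse dates, drop malformed rows with a report."""
        for table, cols in _REQUIRED_COLUMNS.items():
            df = getattr(self, table)
            missing = set(cols) - set(df.columns)
            if missing:
                raise SchemaError(table, missing)
        for table, date_cols in (
            ("observation_periods", ["start_date", "end_date"]),
            ("visits", ["visit_start"]),
            ("condition_occurrences", ["date"]),
            ("deaths", ["death_date"]),
        ):
            df = getattr(self, table).copy()
            bad = pd.Series(False, index=df.index)
            for c in date_cols:
                parsed = pd.to_datetime(df[c], errors="coerce", format="mixed")
                bad |= parsed.isna()
                df[c] = parsed
            n_bad = int(bad.sum())
            if n_bad:
                logger.warning("%s: rejected %d row(s) with malformed dates", table, n_bad)
            self.rejected_rows[table] = n_bad
            setattr(self, table, df[~bad].reset_index(drop=True))

        # observation periods must not overlap within a person
        op = self.observation_periods.sort_values(["person_id", "start_date"])
        prev_end = op.groupby("person_id")["end_date"].shift()
        if (op["start_date"] <= prev_end).any():
            offenders = op.loc[op["start_date"] <= prev_end, "person_id"].unique()
            raise ContractError(
                "overlapping observation periods for person(s): "
                + ", ".join(str(p) for p in offenders[:10])
            )
        return self

    @classmethod
    def read_dir(cls, path: str | Path) -> "ClaimsBundle":
        """Load the five tables from ``<path>/<table>.csv`` and validate."""
        path = Path(path)
        frames = {
            t: pd.read_csv(path / f"{t}.csv")
            for t in _REQUIRED_COLUMNS
        }
        return cls(**frames).validate()

    def write_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for t in _REQUIRED_COLUMNS:
            df = getattr(self, t).copy()
            for c in df.columns:
                if pd.api.types.is_datetime64_any_dtype(df[c]):
                    df[c] = df[c].dt.strftime("%Y-%m-%d")
            df.to_csv(path / f"{t}.csv", index=False)


@dataclass
class CohortResult:
    """Eligible rows plus the attrition accounting."""

    rows: pd.DataFrame  # person_id, index_date, age_at_index, sex, (died_within_365)
    attrition: dict[str, int]

    def attrition_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": list(self.attrition), "n": list(self.attrition.values())}
        )


def build_cohort(bundle: ClaimsBundle, calendar_year: int) -> CohortResult:
    """Select the eligible cohort for one calendar year.

    Returns one row per eligible person (person_id, index_date, age_at_index,
    sex) and per-stage exclusion counts; input persons = eligible + excluded.
    """
    persons = bundle.persons
    attrition = dict.fromkeys(ATTRITION_STAGES, 0)

    visits = bundle.visits
    ip = visits[
        (visits["visit_type"] == INPATIENT)
        & (pd.to_datetime(visits["visit_start"]).dt.year == calendar_year)
    ].copy()
    ip["visit_start"] = pd.to_datetime(ip["visit_start"])
    # earliest visit wins; same-day ties broken by lowest visit id
    ip = ip.sort_values(["person_id", "visit_start", "visit_id"])
    index_rows = ip.groupby("person_id", as_index=False).first()[
        ["person_id", "visit_start"]
    ].rename(columns={"visit_start": "index_date"})

    df = persons.merge(index_rows, on="person_id", how="left")
    no_ip = df["index_date"].isna()
    attrition["no_inpatient_visit_in_year"] = int(no_ip.sum())
    df = df[~no_ip].copy()

    df["age_at_index"] = calendar_year - df["year_of_birth"].astype(int)
    underage = df["age_at_index"] < 18
    attrition["age_under_18"] = int(underage.sum())
    df = df[~underage]

    # continuous observation: one period spanning [index - 365d, index]
    op = bundle.observation_periods.copy()
    op["start_date"] = pd.to_datetime(op["start_date"])
    op["end_date"] = pd.to_datetime(op["end_date"])
    merged = df.merge(op, on="person_id", how="left")
    covers = (
        (merged["start_date"] <= merged["index_date"] - pd.Timedelta(days=ONE_YEAR_DAYS))
        & (merged["end_date"] >= merged["index_date"])
    )
    covered_persons = set(merged.loc[covers.fillna(False), "person_id"])
    uncovered = ~df["person_id"].isin(covered_persons)
    attrition["insufficient_prior_observation"] = int(uncovered.sum())
    df = df[~uncovered]

    attrition["eligible"] = len(df)
    rows = df[["person_id", "index_date", "age_at_index", "sex"]] \
        .sort_values("person_id").reset_index(drop=True)
    return CohortResult(rows=rows, attrition=attrition)


def attach_outcome(result: CohortResult, deaths: pd.DataFrame) -> CohortResult:
    """Add ``died_within_365``: death in [index, index + 365 days], inclusive.

    A death recorded before index is a data anomaly: the person is excluded
    and counted under the ``death_before_index`` attrition stage (and
    ``eligible`` is reduced accordingly).
    """
    rows = result.rows.copy()
    deaths = deaths.copy()
    deaths["death_date"] = pd.to_datetime(deaths["death_date"])
    first_death = deaths.groupby("person_id", as_index=False)["death_date"].min()
    rows = rows.merge(first_death, on="person_id", how="left")

    anomalous = (rows["death_date"] < rows["index_date"]).fillna(False)
    attrition = dict(result.attrition)
    attrition["death_before_index"] = int(anomalous.sum())
    if anomalous.any():
        logger.warning("attach_outcome: excluded %d person(s) with death before index",
                       int(anomalous.sum()))
    rows = rows[~anomalous].copy()
    attrition["eligible"] = len(rows)

    delta = (rows["death_date"] - rows["index_date"]).dt.days
    rows["died_within_365"] = ((delta >= 0) & (delta <= ONE_YEAR_DAYS)).fillna(False)
    rows = rows.drop(columns=["death_date"]).reset_index(drop=True)
    return CohortResult(rows=rows, attrition=attrition)
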