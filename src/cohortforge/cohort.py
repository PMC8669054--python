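"""Cohort definition: registry filters, earliest-exam selection, keyword exclusion.

The study population is every adult outpatient (or emergency patient) with
an abdominal/pelvic CT in a single calendar year.  A research-registry
export contains far more than that — other modalities, other years,
inpatients, other body regions — so the cohort is carved out in three
steps:

1. row-level registry filters (modality, year, description substring,
   exam group, patient type, age);
2. earliest-exam-per-patient selection, so each patient contributes one exam;
3. exclusion of exams whose description reveals a mislabeled interventional
   or musculoskeletal procedure, via a keyword blacklist.

Rows with unparseable dates or ages are quarantined into a rejects frame
with a reason rather than silently dropped, so attrition always sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Sequence, Tuple

import pandas as pd

__all__ = [
    "CohortFilterConfig",
    "FilterOutcome",
    "apply_registry_filters",
    "select_earliest_per_patient",
    "apply_keyword_exclusion",
    "DEFAULT_EXCLUSION_KEYWORDS",
]

#: Exam-description keywords marking mislabeled interventional / MSK exams.
#: Matching is case-insensitive substring matching, which makes "drainage"
#: redundant given "drain"; the list is kept verbatim for auditability.
DEFAULT_EXCLUSION_KEYWORDS: Tuple[str, ...] = (
    "ablation", "fna", "biopsy", "drainage", "guidance", "drain",
    "drg", "bx", "interventional", "interv", "perc", "bone",
)


@dataclass(frozen=True)
class CohortFilterConfig:
    """Registry filter thresholds for cohort definition.

    Defaults encode the study conditions: CT only, exams in 2012,
    description containing "Abd", body-region groups outside the excluded
    set, non-inpatients, age 18–99 inclusive at both bounds.
    """

    modalities: FrozenSet[str] = frozenset({"CT"})
    year: int = 2012
    description_substring: str = "Abd"
    excluded_groups: FrozenSet[str] = frozenset(
        {"chest", "hdnk", "unclassified", "resp", "lextr", "cspin"}
    )
    excluded_patient_types: FrozenSet[str] = frozenset({"inpatient"})
    age_min: int = 18
    age_max: int = 99
    exclusion_keywords: Tuple[str, ...] = DEFAULT_EXCLUSION_KEYWORDS

    def __post_init__(self) -> None:
        if self.age_min > self.age_max:
            raise ValueError("age_min must not exceed age_max")
        if not self.exclusion_keywords:
            raise ValueError("exclusion keyword list must be non-empty")


@dataclass
class FilterOutcome:
    """Partition of a registry export into kept / removed / rejected rows.

    ``removed`` carries a ``removed_reason`` column (first failing filter),
    ``rejects`` a ``reject_reason`` column (unparseable date or age).
    ``kept`` + ``removed`` + ``rejects`` always partitions the input.
    """

    kept: pd.DataFrame
    removed: pd.DataFrame
    rejects: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.kept) + len(self.removed) + len(self.rejects)
        self.total = n


def apply_registry_filters(
    records: pd.DataFrame, config: CohortFilterConfig = CohortFilterConfig()
) -> FilterOutcome:
    """Apply all registry filters; a row is kept iff it passes every one.

    Input order is preserved in each partition.  Dates are accepted in any
    form :func:`pandas.to_datetime` parses; failures are routed to the
    rejects frame, as are non-integer or negative ages.
    """
    df = records.copy()
    if df.empty:
        empty = df.iloc[0:0]
        return FilterOutcome(kept=empty.copy(), removed=empty.copy(), rejects=empty.copy())

    dates = pd.to_datetime(df["exam_date"], errors="coerce", format="mixed")
    ages = pd.to_numeric(df["age"], errors="coerce")
    bad = dates.isna() | ages.isna() | (ages < 0)
    reject_reason = pd.Series("", index=df.index)
    reject_reason[ages.isna() | (ages < 0)] = "unparseable or negative age"
    reject_reason[dates.isna()] = "unparseable exam_date"

    rejects = df[bad].copy()
    rejects["reject_reason"] = reject_reason[bad]

    ok = df[~bad].copy()
    ok_dates = dates[~bad]
    ok_ages = ages[~bad]

    desc = ok["exam_description"].astype(str).str.casefold()
    substring = config.description_substring.casefold()
    checks = [
        ("modality not in whitelist", ok["modality"].isin(config.modalities)),
        ("exam year outside window", ok_dates.dt.year.eq(config.year)),
        ("description lacks required substring", desc.str.contains(substring, regex=False)),
        ("excluded exam group", ~ok["exam_group"].astype(str).str.casefold().isin(config.excluded_groups)),
        ("excluded patient type", ~ok["patient_type"].astype(str).str.casefold().isin(config.excluded_patient_types)),
        ("age outside range", ok_ages.between(config.age_min, config.age_max)),
    ]
    keep_mask = pd.Series(True, index=ok.index)
    removed_reason = pd.Series("", index=ok.index)
    for reason, passed in reversed(checks):  # reversed so the FIRST failure wins
        removed_reason[~passed] = reason
        keep_mask &= passed

    removed = ok[~keep_mask].copy()
    removed["removed_reason"] = removed_reason[~keep_mask]
    kept = ok[keep_mask].copy()
    return FilterOutcome(kept=kept, removed=removed, rejects=rejects)


def _selection_key(df: pd.DataFrame) -> pd.DataFrame:
    """Deterministic earliest-exam sort key: (date, time, accession).

    A missing exam time sorts after any present time, so a record with a
    known earlier time wins a same-day tie; the unique accession breaks any
    remaining tie, making selection independent of input order.
    """
    key = pd.DataFrame(index=df.index)
    key["date"] = pd.to_datetime(df["exam_date"], format="mixed")
    time = df.get("exam_time")
    if time is None:
        key["time"] = "99:99:99"
    else:
        t = time.astype(str).str.strip()
        key["time"] = t.where(t.ne("") & t.notna() & t.ne("nan"), "99:99:99")
    key["accession"] = df["accession"].astype(str)
    return key


def select_earliest_per_patient(records: pd.DataFrame) -> pd.DataFrame:
    """Keep one exam per patient: the earliest under (date, time, accession).

    Output has exactly one row per distinct ``patient_id`` and is sorted by
    patient; the choice is invariant to input row order.
    """
    if records.empty:
        return records.copy()
    key = _selection_key(records)
    order = key.assign(patient=records["patient_id"].astype(str)).sort_values(
        ["patient", "date", "time", "accession"], kind="mergesort"
    )
    first_idx = order.groupby("patient", sort=True).head(1).index
    return records.loc[first_idx].copy()


def apply_keyword_exclusion(
    records: pd.DataFrame, keywords: Sequence[str] = DEFAULT_EXCLUSION_KEYWORDS
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a cohort into (kept, excluded) by description keywords.

    A record is excluded iff its lowercased description contains any
    keyword as a substring.
    """
    if records.empty:
        return records.copy(), records.copy()
    desc = records["exam_description"].astype(str).str.casefold()
    mask = pd.Series(False, index=records.index)
    for kw in keywords:
        mask |= desc.str.contains(kw.casefold(), regex=False)
    return records[~mask].copy(), records[mask].copy()
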