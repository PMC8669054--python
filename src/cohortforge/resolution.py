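"""De-novo accession resolution against a PACS study index.

Multi-part CT orders can mint several accession numbers — abdomen, pelvis,
contrast — of which only one carries the images, and which one varies with
era and site policy; some accessions exist purely for billing.  The
registry's accession is therefore untrustworthy, and the image-bearing
accession is re-identified from scratch by querying the PACS index with
(MRN, exam date) and applying a filter cascade:

1. candidates are CT studies for that MRN within the date window with
   strictly more than 20 images (excludes billing shells and partial
   outside-scan imports);
2. same-day candidates with body part abdomen / GI / GU / body win first;
3. failing that, same-day pelvis, then chest (pelvis preferred);
4. failing that, the window widens to ±4 days and the same body-part
   preference is replayed.

Within a tier, ties break by smallest date distance, then largest image
count, then lexicographic accession — deterministic and invariant to
candidate order.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "PacsStudyRecord",
    "PacsIndex",
    "ResolutionResult",
    "BodyPartVocabulary",
    "DEFAULT_VOCABULARY",
    "ABDOMEN_GROUP",
    "MIN_IMAGE_COUNT",
    "find_candidates",
    "resolve_accession",
    "resolve_cohort",
    "flag_registry_discrepancies",
    "flag_misresolutions",
]

#: Candidate studies must have strictly more than this many images.
MIN_IMAGE_COUNT = 20

#: Body parts accepted at the primary cascade tier.
ABDOMEN_GROUP = frozenset({"abdomen", "gi", "gu", "body"})


class BodyPartVocabulary:
    """Maps site-specific body-part spellings to a canonical vocabulary.

    Canonical values are ``abdomen, gi, gu, body, pelvis, chest, other``.
    Lookup is case-folded and whitespace-trimmed; unknown spellings map to
    ``other``.
    """

    def __init__(self, mapping: Optional[Mapping[str, str]] = None) -> None:
        base = {
            "abdomen": "abdomen", "abd": "abdomen",
            "gi": "gi", "gu": "gu", "body": "body",
            "pelvis": "pelvis", "pel": "pelvis",
            "chest": "chest", "ch": "chest",
        }
        if mapping:
            base.update({k.strip().casefold(): v for k, v in mapping.items()})
        self._map = base

    def canonical(self, raw: str) -> str:
        return self._map.get(str(raw).strip().casefold(), "other")


DEFAULT_VOCABULARY = BodyPartVocabulary()


@dataclass(frozen=True)
class PacsStudyRecord:
    """One study row from a hospital PACS index (canonical identifiers)."""

    mrn: str
    accession: str
    study_date: dt.date
    body_part: str
    modality: str
    image_count: int
    hospital: str = ""

    def __post_init__(self) -> None:
        if self.image_count < 0:
            raise ValueError("image_count must be >= 0")


@dataclass(frozen=True)
class ResolutionResult:
    """Outcome of the cascade for one exam."""

    exam_key: Tuple[str, str]  # (canonical MRN, canonical registry accession)
    status: str  # "resolved" | "unresolved"
    chosen_accession: Optional[str] = None
    tier: Optional[str] = None  # abdomen_same_window | pelvis_or_chest_same_window | date_expanded
    window_used: Optional[int] = None
    differs_from_registry: bool = False

    def __post_init__(self) -> None:
        if self.status == "resolved" and self.chosen_accession is None:
            raise ValueError("resolved result requires a chosen accession")


class PacsIndex:
    """In-memory PACS study index with MRN and accession lookups.

    Built from one or more per-hospital DataFrames with columns
    ``mrn, accession, study_date, body_part, modality, image_count``
    (plus optional ``hospital``).  Body parts are canonicalized on load.
    """

    def __init__(
        self,
        frames: Mapping[str, pd.DataFrame],
        vocabulary: BodyPartVocabulary = DEFAULT_VOCABULARY,
    ) -> None:
        self.vocabulary = vocabulary
        self._by_mrn: Dict[str, List[PacsStudyRecord]] = {}
        self._by_accession: Dict[str, List[PacsStudyRecord]] = {}
        for hospital, df in frames.items():
            for row in df.itertuples(index=False):
                rec = PacsStudyRecord(
                    mrn=str(row.mrn),
                    accession=str(row.accession),
                    study_date=pd.Timestamp(row.study_date).date(),
                    body_part=vocabulary.canonical(row.body_part),
                    modality=str(row.modality),
                    image_count=int(row.image_count),
                    hospital=hospital,
                )
                self._by_mrn.setdefault(rec.mrn, []).append(rec)
                self._by_accession.setdefault(rec.accession, []).append(rec)

    def studies_for_mrn(self, mrn: str) -> List[PacsStudyRecord]:
        return self._by_mrn.get(str(mrn), [])

    def studies_for_accession(self, accession: str) -> List[PacsStudyRecord]:
        return self._by_accession.get(str(accession), [])

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_mrn.values())


def find_candidates(
    index: PacsIndex, mrn: str, date: dt.date, window_days: int
) -> List[PacsStudyRecord]:
    """All CT studies for an MRN within the date window with >20 images.

    The image-count bound is strict (a 20-image study is excluded, a
    21-image study included).  An empty result is a valid outcome.
    """
    out = []
    for rec in index.studies_for_mrn(mrn):
        if rec.modality != "CT":
            continue
        if abs((rec.study_date - date).days) > window_days:
            continue
        if rec.image_count > MIN_IMAGE_COUNT:
            out.append(rec)
    return out


def _pick_best(candidates: Sequence[PacsStudyRecord], date: dt.date) -> PacsStudyRecord:
    """Within-tier tie-break: closest date, then most images, then accession."""
    return min(
        candidates,
        key=lambda r: (abs((r.study_date - date).days), -r.image_count, r.accession),
    )


def resolve_accession(
    exam_key: Tuple[str, str],
    date: dt.date,
    candidates_w0: Iterable[PacsStudyRecord],
    candidates_w4: Iterable[PacsStudyRecord],
) -> ResolutionResult:
    """Run the body-part cascade over same-day and ±4-day candidate sets.

    The date-expanded tier replays the full body-part preference (abdomen
    group, then pelvis, then chest) over the wide-window set rather than
    only the abdomen tier.  Deterministic and candidate-order-invariant.
    """
    w0 = list(candidates_w0)
    w4 = list(candidates_w4)
    registry_acc = exam_key[1]

    tiers = [
        ("abdomen_same_window", 0, [r for r in w0 if r.body_part in ABDOMEN_GROUP]),
        ("pelvis_or_chest_same_window", 0, [r for r in w0 if r.body_part == "pelvis"]),
        ("pelvis_or_chest_same_window", 0, [r for r in w0 if r.body_part == "chest"]),
        ("date_expanded", 4, [r for r in w4 if r.body_part in ABDOMEN_GROUP]),
        ("date_expanded", 4, [r for r in w4 if r.body_part == "pelvis"]),
        ("date_expanded", 4, [r for r in w4 if r.body_part == "chest"]),
    ]
    for tier_name, window, cands in tiers:
        if cands:
            best = _pick_best(cands, date)
            return ResolutionResult(
                exam_key=exam_key,
                status="resolved",
                chosen_accession=best.accession,
                tier=tier_name,
                window_used=window,
                differs_from_registry=best.accession != registry_acc,
            )
    return ResolutionResult(exam_key=exam_key, status="unresolved")


def resolve_cohort(cohort: pd.DataFrame, index: PacsIndex) -> pd.DataFrame:
    """Resolve every cohort exam; returns one result row per input row.

    Expects canonical identifier columns (``patient_id_canonical``,
    ``accession_canonical``) from :func:`~cohortforge.identifiers.normalize_cohort`.
    """
    columns = [
        "patient_id_canonical", "accession_canonical", "exam_date", "status",
        "chosen_accession", "tier", "window_used", "differs_from_registry",
    ]
    if cohort.empty:
        return pd.DataFrame(columns=columns)
    rows = []
    for row in cohort.itertuples(index=False):
        mrn = str(row.patient_id_canonical)
        acc = str(row.accession_canonical)
        date = pd.Timestamp(row.exam_date).date()
        w0 = find_candidates(index, mrn, date, 0)
        w4 = find_candidates(index, mrn, date, 4)
        res = resolve_accession((mrn, acc), date, w0, w4)
        rows.append(
            {
                "patient_id_canonical": mrn,
                "accession_canonical": acc,
                "exam_date": pd.Timestamp(row.exam_date),
                "status": res.status,
                "chosen_accession": res.chosen_accession if res.chosen_accession else "",
                "tier": res.tier or "",
                "window_used": res.window_used if res.window_used is not None else -1,
                "differs_from_registry": res.differs_from_registry,
            }
        )
    return pd.DataFrame(rows, columns=columns)


def flag_registry_discrepancies(results: pd.DataFrame) -> Tuple[int, pd.DataFrame]:
    """Resolved exams whose chosen accession differs from the registry's.

    Comparison is on canonical accessions; the flagged frame is sorted by
    exam key (MRN, registry accession).
    """
    resolved = results[results["status"] == "resolved"]
    flagged = resolved[resolved["chosen_accession"] != resolved["accession_canonical"]]
    flagged = flagged.sort_values(["patient_id_canonical", "accession_canonical"], kind="mergesort")
    return len(flagged), flagged.reset_index(drop=True)


def flag_misresolutions(
    results: pd.DataFrame, ground_truth: pd.DataFrame
) -> Tuple[int, pd.DataFrame]:
    """Resolved exams whose chosen accession is not the image-bearing one.

    Requires a fixture ground-truth table with columns
    ``patient_id, registry_accession, true_accession``.  Returns the count
    and an override table (exam key, wrong choice, correction) that can be
    replayed onto the results — the programmatic analogue of manually
    correcting mis-resolved exams.
    """
    if ground_truth is None or ground_truth.empty:
        raise ValueError("ground truth table required to score misresolutions")
    truth = ground_truth.set_index(["patient_id", "registry_accession"])["true_accession"]
    resolved = results[results["status"] == "resolved"]
    rows = []
    for row in resolved.itertuples(index=False):
        key = (row.patient_id_canonical, row.accession_canonical)
        if key not in truth.index:
            continue
        true_acc = str(truth.loc[key])
        if true_acc and row.chosen_accession != true_acc:
            rows.append(
                {
                    "patient_id_canonical": key[0],
                    "accession_canonical": key[1],
                    "chosen_accession": row.chosen_accession,
                    "corrected_accession": true_acc,
                }
            )
    overrides = pd.DataFrame(
        rows,
        columns=[
            "patient_id_canonical",
            "accession_canonical",
            "chosen_accession",
            "corrected_accession",
        ],
    ).sort_values(["patient_id_canonical", "accession_canonical"], kind="mergesort").reset_index(drop=True)
    return len(overrides), overrides


def apply_overrides(results: pd.DataFrame, overrides: pd.DataFrame) -> pd.DataFrame:
    """Replay manual corrections onto resolution results.

    For each override row the chosen accession is replaced by the corrected
    one; all other rows pass through unchanged.
    """
    if overrides.empty:
        return results.copy()
    out = results.copy()
    correction = overrides.set_index(["patient_id_canonical", "accession_canonical"])[
        "corrected_accession"
    ]
    keys = list(zip(out["patient_id_canonical"], out["accession_canonical"]))
    new_chosen = []
    for key, chosen in zip(keys, out["chosen_accession"]):
        new_chosen.append(str(correction.loc[key]) if key in correction.index else chosen)
    out["chosen_accession"] = new_chosen
    return out
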