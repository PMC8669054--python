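"""Triage of retrieved exams into non-recoverable failure categories.

Even after careful resolution, a fraction of exams cannot enter the final
dataset: the registry and PACS disagree on the (MRN, accession) pairing,
the study is absent, the files will not parse, pixel data will not
decode, the study holds only scout/localizer images, or the "patient" is
a scanner test object.  Each cohort exam receives exactly one disposition,
decided in a fixed precedence order so multi-fault studies are classified
deterministically — identifier-level faults dominate content-level faults:

    mrn_acc_discrepancy → missing → encoding → corrupted
    → topogram_only → test_patient → included

The final attrition report telescopes the cohort from its initial size
through keyword exclusion and each failure category down to the number of
valid exams, and hard-fails if the categories do not partition the cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import pydicom

from .resolution import PacsIndex

__all__ = [
    "TriageConfig",
    "DispositionRecord",
    "FAILURE_DISPOSITIONS",
    "triage_study",
    "triage_cohort",
    "AttritionReport",
    "build_attrition_report",
    "PartitionError",
]

FAILURE_DISPOSITIONS = (
    "failed_mrn_acc_discrepancy",
    "failed_topogram_only",
    "failed_missing",
    "failed_corrupted",
    "failed_test_patient",
    "failed_encoding",
)

ALL_DISPOSITIONS = ("included", "excluded_keyword") + FAILURE_DISPOSITIONS


@dataclass(frozen=True)
class TriageConfig:
    """Content-level detection knobs.

    ``localizer_flag`` is the ImageType value marking a scout image; a
    study whose every decodable instance carries it is topogram-only.
    ``test_name_patterns`` are substrings (case-insensitive) of the DICOM
    patient name that mark non-patient test exams.
    """

    localizer_flag: str = "LOCALIZER"
    test_name_patterns: Tuple[str, ...] = ("TEST", "PHANTOM", "ZZZ")


@dataclass(frozen=True)
class DispositionRecord:
    """The single final fate of one cohort exam."""

    exam_key: Tuple[str, str]
    disposition: str
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.disposition not in ALL_DISPOSITIONS:
            raise ValueError(f"unknown disposition {self.disposition!r}")


def _inspect_dicom_dir(
    dicom_dir: Path, config: TriageConfig
) -> Tuple[str, str]:
    """Content-level checks on a retrieved study directory.

    Returns (disposition, evidence); disposition "included" means the
    content passed every check.
    """
    files = sorted(p for p in Path(dicom_dir).iterdir() if p.is_file())
    if not files:
        return "failed_missing", "study directory empty"

    datasets = []
    for path in files:
        try:
            datasets.append(pydicom.dcmread(path))
        except Exception as exc:  # undecodable DICOM encoding
            return "failed_encoding", f"{path.name}: {type(exc).__name__}"
    for path, ds in zip(files, datasets):
        try:
            ds.pixel_array
        except Exception as exc:
            return "failed_corrupted", f"{path.name}: pixel decode {type(exc).__name__}"
    image_types = [[str(v).upper() for v in ds.get("ImageType", [])] for ds in datasets]
    if all(config.localizer_flag in it for it in image_types):
        return "failed_topogram_only", f"all {len(datasets)} instances are localizers"
    for ds in datasets:
        name = str(ds.get("PatientName", "")).upper()
        if any(pat in name for pat in config.test_name_patterns):
            return "failed_test_patient", f"patient name {name!r}"
    return "included", ""


def triage_study(
    resolution: pd.Series,
    registry_record: pd.Series,
    pacs_index: PacsIndex,
    dicom_dir: Optional[Path] = None,
    config: TriageConfig = TriageConfig(),
) -> DispositionRecord:
    """Assign the disposition for one exam.

    ``resolution`` is one row of :func:`~cohortforge.resolution.resolve_cohort`
    output; ``registry_record`` the matching cohort row with canonical
    identifiers.  ``dicom_dir`` is the retrieved study directory when one
    was (expected to be) retrieved; ``None`` limits triage to index-level
    checks.  An absent or empty directory while the index reports images
    is treated as a missing exam and logged distinctly.
    """
    key = (str(registry_record["patient_id_canonical"]), str(registry_record["accession_canonical"]))

    if resolution["status"] != "resolved":
        # unresolved: decide between identifier discrepancy and a truly
        # missing study by looking the registry accession up across PACS
        rows = pacs_index.studies_for_accession(key[1])
        if rows and all(r.mrn != key[0] for r in rows):
            pacs_mrns = sorted({r.mrn for r in rows})
            return DispositionRecord(
                key,
                "failed_mrn_acc_discrepancy",
                f"accession held by PACS MRN(s) {pacs_mrns}, registry MRN {key[0]}",
            )
        return DispositionRecord(key, "failed_missing", "no resolvable study in any PACS index")

    chosen = str(resolution["chosen_accession"])
    chosen_rows = pacs_index.studies_for_accession(chosen)
    if chosen_rows and all(r.mrn != key[0] for r in chosen_rows):
        return DispositionRecord(
            key, "failed_mrn_acc_discrepancy", f"chosen accession {chosen} held by a different MRN"
        )

    if dicom_dir is not None:
        dicom_dir = Path(dicom_dir)
        if not dicom_dir.is_dir():
            return DispositionRecord(
                key, "failed_missing", f"index reports images but {dicom_dir} absent"
            )
        disposition, evidence = _inspect_dicom_dir(dicom_dir, config)
        return DispositionRecord(key, disposition, evidence)

    return DispositionRecord(key, "included", "")


def triage_cohort(
    cohort: pd.DataFrame,
    resolutions: pd.DataFrame,
    pacs_index: PacsIndex,
    dicom_root: Optional[Path] = None,
    rendered: Optional[Dict[str, str]] = None,
    config: TriageConfig = TriageConfig(),
) -> pd.DataFrame:
    """Disposition every cohort exam; one output row per input row.

    ``rendered`` maps chosen accession → study directory name under
    ``dicom_root`` for the subset of studies that were actually retrieved
    as files; all other studies are triaged on index-level evidence alone.
    """
    columns = ["patient_id_canonical", "accession_canonical", "disposition", "evidence"]
    if cohort.empty:
        return pd.DataFrame(columns=columns)
    rendered = rendered or {}
    res_indexed = resolutions.set_index(["patient_id_canonical", "accession_canonical"])
    rows = []
    for _, rec in cohort.iterrows():
        key = (str(rec["patient_id_canonical"]), str(rec["accession_canonical"]))
        res = res_indexed.loc[key]
        dicom_dir = None
        chosen = str(res["chosen_accession"])
        if dicom_root is not None and chosen in rendered:
            dicom_dir = Path(dicom_root) / rendered[chosen]
        disp = triage_study(res, rec, pacs_index, dicom_dir, config)
        rows.append(
            {
                "patient_id_canonical": key[0],
                "accession_canonical": key[1],
                "disposition": disp.disposition,
                "evidence": disp.evidence,
            }
        )
    return pd.DataFrame(rows, columns=columns)


class PartitionError(RuntimeError):
    """Raised when dispositions fail to partition the cohort."""


@dataclass
class AttritionReport:
    """Stage-by-stage accounting of cohort shrinkage."""

    stages: List[Tuple[str, int]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "exams"])

    def to_text(self) -> str:
        width = max((len(s) for s, _ in self.stages), default=10) + 2
        lines = [f"{stage:<{width}}{count:>8d}" for stage, count in self.stages]
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(dict(self.stages), indent=2)

    def __getitem__(self, stage: str) -> int:
        for s, c in self.stages:
            if s == stage:
                return c
        raise KeyError(stage)


def build_attrition_report(
    dispositions: pd.DataFrame,
    stage_counts: Optional[Dict[str, int]] = None,
) -> AttritionReport:
    """Build the telescoping attrition table and verify conservation.

    ``dispositions`` must cover every cohort exam (one row each) and may
    include ``excluded_keyword`` rows for exams dropped before retrieval.
    ``stage_counts`` may supply upstream totals (registry rows, rows after
    filters, exams after earliest-per-patient selection) which are
    prepended verbatim.  Raises :class:`PartitionError`, naming the
    offending exam keys, if any exam has a duplicate or unknown disposition
    or the categories fail to telescope.
    """
    dup = dispositions.duplicated(subset=["patient_id_canonical", "accession_canonical"], keep=False)
    if dup.any():
        keys = dispositions[dup][["patient_id_canonical", "accession_canonical"]].values.tolist()
        raise PartitionError(f"duplicate dispositions for exam keys {keys[:10]}")
    unknown = ~dispositions["disposition"].isin(ALL_DISPOSITIONS)
    if unknown.any():
        keys = dispositions[unknown][["patient_id_canonical", "accession_canonical"]].values.tolist()
        raise PartitionError(f"unknown dispositions for exam keys {keys[:10]}")

    counts = dispositions["disposition"].value_counts().to_dict()
    n_total = len(dispositions)
    n_keyword = counts.get("excluded_keyword", 0)
    n_included = counts.get("included", 0)
    n_failures = sum(counts.get(d, 0) for d in FAILURE_DISPOSITIONS)
    if n_keyword + n_included + n_failures != n_total:
        raise PartitionError(
            f"dispositions do not partition the cohort: "
            f"{n_keyword} + {n_included} + {n_failures} != {n_total}"
        )

    report = AttritionReport()
    for stage, count in (stage_counts or {}).items():
        report.stages.append((stage, int(count)))
    report.stages.append(("selected cohort (one exam per patient)", n_total))
    report.stages.append(("excluded by description keywords", n_keyword))
    report.stages.append(("cohort after keyword exclusion", n_total - n_keyword))
    for disp in FAILURE_DISPOSITIONS:
        report.stages.append((disp, counts.get(disp, 0)))
    report.stages.append(("non-recoverable failures (total)", n_failures))
    report.stages.append(("final valid exams", n_included))
    return report
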