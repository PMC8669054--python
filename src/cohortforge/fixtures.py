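"""Synthetic RIS/PACS fixture generation with injected failure modes.

Real research-registry exports and hospital PACS databases cannot be
shared, so the pipeline is exercised against a deterministic synthetic
stand-in: a registry export (one row per exam, raw and possibly malformed
identifiers), per-hospital PACS study indices (canonical identifiers,
body part, image count), a rendering manifest for the subset of studies
materialized as DICOM files, and a ground-truth table recording which
failure mode — if any — was injected into each exam, enabling exact
recovery scoring.

Injected modes cover every documented way a large retrieval goes wrong:

* ``mislabeled_interventional`` — an interventional/MSK procedure hiding
  under an abdominal CT description (caught by keyword exclusion);
* ``mrn_zero_dropped`` / ``acc_prefix_added`` — site-specific identifier
  corruption (leading zeros dropped on export; a legacy "A" accession
  prefix from before an EMR migration);
* ``billing_only_acc`` / ``linkage_pelvis`` / ``linkage_chest`` — the
  registry accession is a billing shell and the images actually live
  under a sibling abdomen, pelvis, or chest accession;
* ``date_offset`` — the registry exam date is off by up to ±4 days from
  the PACS study date;
* ``adversarial_misresolution`` — a decoy abdomen study (>20 images, same
  day) that the resolution cascade provably prefers over the true
  pelvis-linked study;
* six non-recoverable modes — ``mrn_acc_discrepancy``, ``topogram_only``,
  ``missing``, ``corrupted``, ``test_patient``, ``encoding_error``.

The ``paper_replica_config`` preset encodes the documented attrition of a
33,182-exam / 23,186-patient abdominal-CT cohort; all counts in the
fixture are exact by construction, whatever the seed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .dicomgen import StudySpec, render_dicom_fixture
from .identifiers import SiteRuleSet

__all__ = [
    "HospitalSpec",
    "FixtureConfig",
    "FixtureConfigError",
    "FixtureBundle",
    "paper_replica_config",
    "generate_registry",
    "generate_pacs_index",
    "render_manifest",
    "generate_fixture",
    "write_fixture",
    "INJECTED_MODES",
    "NON_RECOVERABLE_MODES",
]

INJECTED_MODES = (
    "none",
    "mislabeled_interventional",
    "mrn_zero_dropped",
    "acc_prefix_added",
    "billing_only_acc",
    "linkage_pelvis",
    "linkage_chest",
    "date_offset",
    "adversarial_misresolution",
    "mrn_acc_discrepancy",
    "topogram_only",
    "missing",
    "corrupted",
    "test_patient",
    "encoding_error",
)

NON_RECOVERABLE_MODES = (
    "mrn_acc_discrepancy",
    "topogram_only",
    "missing",
    "corrupted",
    "test_patient",
    "encoding_error",
)

#: Modes whose image-bearing accession differs from the registry accession.
LINKAGE_MODES = ("billing_only_acc", "linkage_pelvis", "linkage_chest")

DECOY_KINDS = (
    "inpatient",
    "age_out_of_range",
    "wrong_year",
    "excluded_group",
    "non_ct",
    "no_abd_description",
)

_CLEAN_DESCRIPTIONS = (
    "CT Abd/Pelvis W Contrast",
    "CT Abd WO Contrast",
    "CT Abd/Pel W/WO Contrast",
    "CT Abdomen Pelvis Enterography",
    "CT Abd Multiphase Liver",
    "CT Abd/Pelvis Routine",
)

_KEYWORD_DESCRIPTIONS = (
    "CT Abd Biopsy Guidance",
    "CT Abd Perc Drainage",
    "CT Abd FNA Aspiration",
    "CT Abd Ablation Planning",
    "CT Abd Drg Chk",
    "CT Abd Interventional",
    "CT Abd Bone Survey",
)

_BODY_PART_SPELLINGS = {
    "upper": {"abdomen": "ABDOMEN", "pelvis": "PELVIS", "chest": "CHEST",
              "gi": "GI", "gu": "GU", "body": "BODY"},
    "abbrev": {"abdomen": "ABD", "pelvis": "PEL", "chest": "CH",
               "gi": "GI", "gu": "GU", "body": "BODY"},
    "title": {"abdomen": "Abdomen", "pelvis": "Pelvis", "chest": "Chest",
              "gi": "Gi", "gu": "Gu", "body": "Body"},
}

REGISTRY_COLUMNS = (
    "patient_id", "accession", "hospital", "exam_date", "exam_time",
    "exam_description", "exam_group", "modality", "patient_type", "age",
    "exam_code",
)

PACS_COLUMNS = ("mrn", "accession", "study_date", "body_part", "modality", "image_count")

TRUTH_COLUMNS = (
    "patient_id", "registry_accession", "injected_mode", "true_accession",
    "detail", "row_class",
)


class FixtureConfigError(ValueError):
    """Raised when a fixture configuration is internally inconsistent."""


@dataclass(frozen=True)
class HospitalSpec:
    """One hospital in the roster: sampling weight plus identifier and
    body-part-spelling conventions."""

    code: str
    weight: float
    mrn_pad_width: int = 0
    acc_legacy_prefix: str = ""
    body_part_style: str = "upper"

    def rule_set(self) -> SiteRuleSet:
        return SiteRuleSet(self.code, self.mrn_pad_width, self.acc_legacy_prefix)


DEFAULT_HOSPITALS = (
    HospitalSpec("site_a", 0.5, mrn_pad_width=8, acc_legacy_prefix="A", body_part_style="upper"),
    HospitalSpec("site_b", 0.3, body_part_style="abbrev"),
    HospitalSpec("site_c", 0.2, body_part_style="title"),
)


@dataclass(frozen=True)
class FixtureConfig:
    """Full description of one synthetic cohort fixture.

    ``n_exams`` counts registry rows that survive the upstream filters
    (one primary exam per patient plus later repeat exams); decoy rows
    that the filters must remove are counted separately in
    ``decoy_counts``.  ``mode_counts`` gives the exact number of primary
    exams carrying each injected failure mode; every remaining primary is
    clean (mode ``none``).
    """

    n_patients: int
    n_exams: int
    seed: int = 2012
    mode_counts: Mapping[str, int] = field(default_factory=dict)
    decoy_counts: Mapping[str, int] = field(default_factory=dict)
    hospitals: Tuple[HospitalSpec, ...] = DEFAULT_HOSPITALS
    date_offset_max: int = 4
    linkage_proportions: Tuple[float, float, float] = (0.6, 0.3, 0.1)
    billing_split_rate: float = 0.3
    year: int = 2012
    n_render_clean: int = 10

    def __post_init__(self) -> None:
        if self.n_patients < 0 or self.n_exams < self.n_patients:
            raise FixtureConfigError("need n_exams >= n_patients >= 0")
        for mode, count in self.mode_counts.items():
            if mode not in INJECTED_MODES or mode == "none":
                raise FixtureConfigError(f"unknown injected mode {mode!r}")
            if count < 0:
                raise FixtureConfigError(f"negative count for mode {mode!r}")
        if sum(self.mode_counts.values()) > self.n_patients:
            raise FixtureConfigError("sum of injection counts exceeds number of primary exams")
        for kind, count in self.decoy_counts.items():
            if kind not in DECOY_KINDS:
                raise FixtureConfigError(f"unknown decoy kind {kind!r}")
            if count < 0:
                raise FixtureConfigError(f"negative decoy count for {kind!r}")
        if not 1 <= self.date_offset_max <= 4:
            raise FixtureConfigError("date_offset_max must be in [1, 4]")
        props = self.linkage_proportions
        if len(props) != 3 or any(p < 0 or p > 1 for p in props) or abs(sum(props) - 1) > 1e-9:
            raise FixtureConfigError("linkage proportions must lie in [0,1] and sum to 1")
        if not 0 <= self.billing_split_rate <= 1:
            raise FixtureConfigError("billing_split_rate must lie in [0,1]")
        if not self.hospitals:
            raise FixtureConfigError("hospital roster must be non-empty")

    def site_rules(self) -> Dict[str, SiteRuleSet]:
        return {h.code: h.rule_set() for h in self.hospitals}

    def mode_count(self, mode: str) -> int:
        return int(self.mode_counts.get(mode, 0))


def split_by_proportions(total: int, proportions: Sequence[float]) -> List[int]:
    """Integer split of ``total`` by proportions (largest-remainder rule)."""
    raw = [total * p for p in proportions]
    base = [int(x) for x in raw]
    short = total - sum(base)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:short]:
        base[i] += 1
    return base


def paper_replica_config(seed: int = 2012) -> FixtureConfig:
    """The packaged replica preset.

    Encodes the documented attrition of the study cohort: 33,182
    filter-surviving exam rows over 23,186 patients; 283 mislabeled
    interventional/MSK exams; 10,089 exams needing identifier
    reformatting; 838 exams whose image-bearing accession differs from
    the registry accession (split abdomen/pelvis/chest by the linkage
    proportions); 24 adversarial records the cascade mis-resolves; and 51
    non-recoverable failures split 17/7/8/3/1/15 across the six
    categories.  All counts are independent of the seed, which only moves
    the random dressing (dates, image counts, site assignment).
    """
    linkage = split_by_proportions(838, (0.6, 0.3, 0.1))
    mode_counts = {
        "mislabeled_interventional": 283,
        "mrn_zero_dropped": 6000,
        "acc_prefix_added": 4089,
        "billing_only_acc": linkage[0],
        "linkage_pelvis": linkage[1],
        "linkage_chest": linkage[2],
        "date_offset": 500,
        "adversarial_misresolution": 24,
        "mrn_acc_discrepancy": 17,
        "topogram_only": 7,
        "missing": 8,
        "corrupted": 3,
        "test_patient": 1,
        "encoding_error": 15,
    }
    decoy_counts = {
        "inpatient": 100,
        "age_out_of_range": 80,
        "wrong_year": 80,
        "excluded_group": 80,
        "non_ct": 80,
        "no_abd_description": 80,
    }
    return FixtureConfig(
        n_patients=23_186,
        n_exams=33_182,
        seed=seed,
        mode_counts=mode_counts,
        decoy_counts=decoy_counts,
    )


# ---------------------------------------------------------------------------
# plan construction (internal)
# ---------------------------------------------------------------------------

_MODE_ASSIGNMENT_ORDER = tuple(m for m in INJECTED_MODES if m != "none")


def _assign_modes(config: FixtureConfig, rng: np.random.Generator) -> np.ndarray:
    """Assign one primary injected mode per patient, exact counts."""
    modes = np.full(config.n_patients, "none", dtype=object)
    perm = rng.permutation(config.n_patients)
    cursor = 0
    for mode in _MODE_ASSIGNMENT_ORDER:
        count = config.mode_count(mode)
        modes[perm[cursor:cursor + count]] = mode
        cursor += count
    return modes


def _assign_sites(
    config: FixtureConfig, modes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    codes = [h.code for h in config.hospitals]
    weights = np.array([h.weight for h in config.hospitals], dtype=float)
    weights = weights / weights.sum()
    sites = rng.choice(codes, size=config.n_patients, p=weights).astype(object)

    pad_sites = [h.code for h in config.hospitals if h.mrn_pad_width > 0]
    prefix_sites = [h.code for h in config.hospitals if h.acc_legacy_prefix]
    if config.mode_count("mrn_zero_dropped") and not pad_sites:
        raise FixtureConfigError("mrn_zero_dropped injections need a site with mrn_pad_width > 0")
    if config.mode_count("acc_prefix_added") and not prefix_sites:
        raise FixtureConfigError("acc_prefix_added injections need a site with a legacy prefix")
    # identifier corruption only makes sense at a site with that convention
    mask = modes == "mrn_zero_dropped"
    if mask.any():
        sites[mask] = rng.choice(pad_sites, size=int(mask.sum()))
    mask = modes == "acc_prefix_added"
    if mask.any():
        sites[mask] = rng.choice(prefix_sites, size=int(mask.sum()))
    return sites


def _build_plan(config: FixtureConfig) -> pd.DataFrame:
    """One row per registry row with every generated attribute, raw and
    canonical.  Internal: both the registry export and the PACS indices
    are projections of this frame."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    modes = _assign_modes(config, rng)
    sites = _assign_sites(config, modes, rng)

    year_start = dt.date(config.year, 1, 1)
    primary_day = rng.integers(0, 300, size=n)
    ages = rng.integers(18, 100, size=n)
    ptype = rng.choice(["outpatient", "emergency"], size=n, p=[0.8, 0.2]).astype(object)
    clean_desc = rng.integers(0, len(_CLEAN_DESCRIPTIONS), size=n)
    keyword_desc = rng.integers(0, len(_KEYWORD_DESCRIPTIONS), size=n)
    offsets = rng.integers(1, config.date_offset_max + 1, size=n) * rng.choice([-1, 1], size=n)

    acc_seq = 500_000_000
    zero_seq = 1_000_000
    rows: List[dict] = []

    for i in range(n):
        mode = modes[i]
        site = sites[i]
        if mode == "mrn_zero_dropped":
            mrn_canonical = "0" + str(zero_seq)
            zero_seq += 1
            mrn_raw = mrn_canonical.lstrip("0")
        else:
            mrn_canonical = str(10_000_000 + i)
            mrn_raw = mrn_canonical
        acc_canonical = str(acc_seq)
        acc_seq += 1
        acc_raw = acc_canonical
        if mode == "acc_prefix_added":
            prefix = next(h.acc_legacy_prefix for h in config.hospitals if h.code == site)
            acc_raw = prefix + acc_canonical
        true_acc = acc_canonical
        detail = ""
        if mode in LINKAGE_MODES or mode == "adversarial_misresolution":
            true_acc = str(acc_seq)
            acc_seq += 1
        elif mode == "missing":
            true_acc = ""
        elif mode == "date_offset":
            detail = str(int(offsets[i]))
        description = (
            _KEYWORD_DESCRIPTIONS[keyword_desc[i]]
            if mode == "mislabeled_interventional"
            else _CLEAN_DESCRIPTIONS[clean_desc[i]]
        )
        rows.append(
            {
                "row_class": "primary",
                "patient_idx": i,
                "mrn_canonical": mrn_canonical,
                "mrn_raw": mrn_raw,
                "acc_canonical": acc_canonical,
                "acc_raw": acc_raw,
                "true_acc": true_acc,
                "mode": mode,
                "detail": detail,
                "hospital": site,
                "exam_date": year_start + dt.timedelta(days=int(primary_day[i])),
                "exam_description": description,
                "exam_group": "abdomen",
                "modality": "CT",
                "patient_type": ptype[i],
                "age": int(ages[i]),
            }
        )

    # later repeat exams for randomly chosen patients (never the earliest:
    # at least ten days after the primary, outside any resolution window)
    n_extra = config.n_exams - n
    extra_patients = rng.integers(0, n, size=n_extra) if n else np.array([], dtype=int)
    extra_gap = rng.integers(10, 40, size=n_extra)
    extra_desc = rng.integers(0, len(_CLEAN_DESCRIPTIONS), size=n_extra)
    for j in range(n_extra):
        p = int(extra_patients[j])
        base = rows[p]
        acc_canonical = str(acc_seq)
        acc_seq += 1
        rows.append(
            {
                "row_class": "extra",
                "patient_idx": p,
                "mrn_canonical": base["mrn_canonical"],
                "mrn_raw": base["mrn_raw"],  # export corruption is per patient
                "acc_canonical": acc_canonical,
                "acc_raw": acc_canonical,
                "true_acc": acc_canonical,
                "mode": "none",
                "detail": "",
                "hospital": base["hospital"],
                "exam_date": base["exam_date"] + dt.timedelta(days=int(extra_gap[j])),
                "exam_description": _CLEAN_DESCRIPTIONS[extra_desc[j]],
                "exam_group": "abdomen",
                "modality": "CT",
                "patient_type": base["patient_type"],
                "age": base["age"],
            }
        )

    # decoy rows that the upstream registry filters must remove
    decoy_idx = 0
    codes = [h.code for h in config.hospitals]
    for kind in DECOY_KINDS:
        for _ in range(int(config.decoy_counts.get(kind, 0))):
            acc_canonical = str(acc_seq)
            acc_seq += 1
            row = {
                "row_class": f"decoy_{kind}",
                "patient_idx": -1,
                "mrn_canonical": str(20_000_000 + decoy_idx),
                "mrn_raw": str(20_000_000 + decoy_idx),
                "acc_canonical": acc_canonical,
                "acc_raw": acc_canonical,
                "true_acc": "",
                "mode": "none",
                "detail": "",
                "hospital": codes[int(rng.integers(0, len(codes)))],
                "exam_date": year_start + dt.timedelta(days=int(rng.integers(0, 300))),
                "exam_description": _CLEAN_DESCRIPTIONS[int(rng.integers(0, len(_CLEAN_DESCRIPTIONS)))],
                "exam_group": "abdomen",
                "modality": "CT",
                "patient_type": "outpatient",
                "age": int(rng.integers(18, 100)),
            }
            decoy_idx += 1
            if kind == "inpatient":
                row["patient_type"] = "inpatient"
            elif kind == "age_out_of_range":
                row["age"] = int(rng.choice([17, 100]))
            elif kind == "wrong_year":
                row["exam_date"] = dt.date(config.year + int(rng.choice([-1, 1])), 6, 15)
            elif kind == "excluded_group":
                row["exam_group"] = str(rng.choice(["chest", "hdnk", "unclassified", "resp", "lextr", "cspin"]))
            elif kind == "non_ct":
                row["modality"] = "MR"
            elif kind == "no_abd_description":
                row["exam_description"] = "CT Liver Mass Protocol"
            rows.append(row)

    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def generate_registry(config: FixtureConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the registry export and its ground-truth table.

    Deterministic given the config (seed included): two calls yield
    byte-identical CSV serializations.  The registry carries raw (possibly
    corrupted) identifiers; the ground truth carries canonical ones.
    """
    plan = _build_plan(config)
    registry = pd.DataFrame(
        {
            "patient_id": plan["mrn_raw"],
            "accession": plan["acc_raw"],
            "hospital": plan["hospital"],
            "exam_date": plan["exam_date"].map(lambda d: d.isoformat()),
            "exam_time": "",
            "exam_description": plan["exam_description"],
            "exam_group": plan["exam_group"],
            "modality": plan["modality"],
            "patient_type": plan["patient_type"],
            "age": plan["age"],
            "exam_code": "ABDPEL",
        }
    )
    truth = pd.DataFrame(
        {
            "patient_id": plan["mrn_canonical"],
            "registry_accession": plan["acc_canonical"],
            "injected_mode": plan["mode"],
            "true_accession": plan["true_acc"],
            "detail": plan["detail"],
            "row_class": plan["row_class"],
        }
    )
    return registry, truth


def _spelling(style: str, part: str) -> str:
    return _BODY_PART_SPELLINGS.get(style, _BODY_PART_SPELLINGS["upper"])[part]


def generate_pacs_index(
    registry: pd.DataFrame, ground_truth: pd.DataFrame, config: FixtureConfig
) -> Dict[str, pd.DataFrame]:
    """Derive per-hospital PACS study indices from a generated registry.

    For every non-missing exam the true image-bearing study appears with
    more than 20 images and the body part its linkage mode dictates;
    billing-only accessions appear with at most a handful of images; date
    offsets are applied per label; MRNs are stored canonically (padded,
    unprefixed).  Raises :class:`FixtureConfigError` on a ground-truth row
    whose exam key has no registry row.
    """
    if len(registry) != len(ground_truth):
        raise FixtureConfigError(
            "registry and ground truth must come from the same generation run"
        )
    rng = np.random.default_rng(config.seed + 1)
    styles = {h.code: h.body_part_style for h in config.hospitals}
    frames: Dict[str, List[dict]] = {h.code: [] for h in config.hospitals}

    m = len(registry)
    clean_part = rng.choice(
        ["abdomen", "gi", "gu", "body"], size=m, p=[0.85, 0.05, 0.05, 0.05]
    )
    big_counts = rng.integers(100, 600, size=m)
    small_counts = rng.integers(0, 6, size=m)
    decoy_counts = rng.integers(25, 41, size=m)
    billing_draw = rng.random(size=m)
    sibling_seq = 800_000_000
    foreign_seq = 70_000_000

    def add(site: str, mrn: str, acc: str, date: dt.date, part: str, count: int) -> None:
        if site not in frames:
            raise FixtureConfigError(f"exam assigned to unknown hospital {site!r}")
        frames[site].append(
            {
                "mrn": mrn,
                "accession": acc,
                "study_date": date.isoformat(),
                "body_part": _spelling(styles.get(site, "upper"), part),
                "modality": "CT",
                "image_count": int(count),
            }
        )

    for i, (reg, truth) in enumerate(
        zip(registry.itertuples(index=False), ground_truth.itertuples(index=False))
    ):
        row_class = truth.row_class
        if row_class.startswith("decoy"):
            continue  # decoy rows never reach resolution; keep the index lean
        mode = truth.injected_mode
        mrn = str(truth.patient_id)
        acc = str(truth.registry_accession)
        true_acc = str(truth.true_accession)
        site = str(reg.hospital)
        date = dt.date.fromisoformat(str(reg.exam_date))

        if mode == "missing":
            continue
        if mode == "none":
            add(site, mrn, acc, date, str(clean_part[i]), big_counts[i])
            if row_class == "primary" and billing_draw[i] < config.billing_split_rate:
                # billing shells for the multi-part order: no images attached
                for part in ("pelvis", "abdomen"):
                    add(site, mrn, str(sibling_seq), date, part, small_counts[i])
                    sibling_seq += 1
        elif mode in ("mislabeled_interventional", "mrn_zero_dropped", "acc_prefix_added",
                      "corrupted", "test_patient", "encoding_error"):
            add(site, mrn, acc, date, "abdomen", big_counts[i])
        elif mode == "topogram_only":
            add(site, mrn, acc, date, "abdomen", 24)
        elif mode == "date_offset":
            add(site, mrn, acc, date + dt.timedelta(days=int(truth.detail)), "abdomen", big_counts[i])
        elif mode == "billing_only_acc":
            add(site, mrn, acc, date, "pelvis", small_counts[i])
            add(site, mrn, true_acc, date, "abdomen", big_counts[i])
        elif mode == "linkage_pelvis":
            add(site, mrn, acc, date, "abdomen", small_counts[i])
            add(site, mrn, true_acc, date, "pelvis", big_counts[i])
        elif mode == "linkage_chest":
            add(site, mrn, acc, date, "abdomen", small_counts[i])
            add(site, mrn, true_acc, date, "chest", big_counts[i])
        elif mode == "adversarial_misresolution":
            # decoy abdomen study the cascade must prefer over the true study
            add(site, mrn, acc, date, "abdomen", decoy_counts[i])
            add(site, mrn, true_acc, date, "pelvis", big_counts[i])
        elif mode == "mrn_acc_discrepancy":
            add(site, str(foreign_seq), acc, date, "abdomen", big_counts[i])
            foreign_seq += 1
        else:
            raise FixtureConfigError(f"unhandled injected mode {mode!r}")

    return {
        site: pd.DataFrame(rows, columns=list(PACS_COLUMNS))
        for site, rows in frames.items()
    }


_RENDERED_MODES = ("topogram_only", "corrupted", "test_patient", "encoding_error")


def render_manifest(
    registry: pd.DataFrame, ground_truth: pd.DataFrame, config: FixtureConfig
) -> pd.DataFrame:
    """Which studies to materialize as DICOM files, and how.

    All content-level failure studies are rendered, plus the first
    ``n_render_clean`` clean primaries; everything else exists only as
    index rows, keeping the fixture at desk scale.
    """
    rows = []
    n_clean = 0
    for reg, truth in zip(registry.itertuples(index=False), ground_truth.itertuples(index=False)):
        if truth.row_class != "primary":
            continue
        mode = truth.injected_mode
        if mode in _RENDERED_MODES:
            render_mode = mode
        elif mode == "none" and n_clean < config.n_render_clean:
            render_mode = "none"
            n_clean += 1
        else:
            continue
        rows.append(
            {
                "mrn": str(truth.patient_id),
                "accession": str(truth.registry_accession),
                "study_date": str(reg.exam_date),
                "render_mode": render_mode,
                "n_instances": 24,
            }
        )
    return pd.DataFrame(rows, columns=["mrn", "accession", "study_date", "render_mode", "n_instances"])


@dataclass
class FixtureBundle:
    """A complete generated fixture, in memory."""

    config: FixtureConfig
    registry: pd.DataFrame
    ground_truth: pd.DataFrame
    pacs: Dict[str, pd.DataFrame]
    manifest: pd.DataFrame


def generate_fixture(config: FixtureConfig, verify: bool = True) -> FixtureBundle:
    """Generate registry, ground truth, PACS indices, and render manifest.

    With ``verify=True`` the adversarial records are checked by actually
    running the resolution cascade: each must resolve to the registry
    accession (the decoy) and not to the true image-bearing accession.
    """
    registry, truth = generate_registry(config)
    pacs = generate_pacs_index(registry, truth, config)
    manifest = render_manifest(registry, truth, config)
    bundle = FixtureBundle(config, registry, truth, pacs, manifest)
    if verify:
        _verify_adversarial(bundle)
    return bundle


def _verify_adversarial(bundle: FixtureBundle) -> None:
    from .resolution import PacsIndex, find_candidates, resolve_accession

    adversarial = bundle.ground_truth[
        bundle.ground_truth["injected_mode"] == "adversarial_misresolution"
    ]
    if adversarial.empty:
        return
    index = PacsIndex(bundle.pacs)
    reg = bundle.registry
    dates = {}
    for reg_row, truth_row in zip(reg.itertuples(index=False), bundle.ground_truth.itertuples(index=False)):
        dates[(truth_row.patient_id, truth_row.registry_accession)] = str(reg_row.exam_date)
    for row in adversarial.itertuples(index=False):
        key = (str(row.patient_id), str(row.registry_accession))
        date = dt.date.fromisoformat(dates[key])
        res = resolve_accession(
            key,
            date,
            find_candidates(index, key[0], date, 0),
            find_candidates(index, key[0], date, 4),
        )
        if res.status != "resolved" or res.chosen_accession != key[1] or res.chosen_accession == str(row.true_accession):
            raise FixtureConfigError(
                f"adversarial construction failed for exam {key}: cascade chose "
                f"{res.chosen_accession!r} (true {row.true_accession!r})"
            )


def write_fixture(bundle: FixtureBundle, out_dir: Path, render_dicom: bool = False) -> Path:
    """Serialize a fixture to disk (CSV throughout; DICOM optional).

    Layout: ``registry.csv``, ``ground_truth.csv``, ``render_manifest.csv``,
    ``pacs_<site>.csv`` per hospital, and — with ``render_dicom`` — one
    study directory per manifest row under ``dicom/``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.registry.to_csv(out / "registry.csv", index=False)
    bundle.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    bundle.manifest.to_csv(out / "render_manifest.csv", index=False)
    for site, df in bundle.pacs.items():
        df.to_csv(out / f"pacs_{site}.csv", index=False)
    if render_dicom:
        render_all(bundle.manifest, out / "dicom")
    return out


def render_all(manifest: pd.DataFrame, dicom_root: Path) -> Dict[str, str]:
    """Render every manifest study; returns accession → directory name."""
    dicom_root = Path(dicom_root)
    rendered: Dict[str, str] = {}
    for row in manifest.itertuples(index=False):
        spec = StudySpec(
            mrn=str(row.mrn),
            accession=str(row.accession),
            study_date=dt.date.fromisoformat(str(row.study_date)),
            n_instances=int(row.n_instances),
        )
        render_dicom_fixture(spec, str(row.render_mode), dicom_root)
        rendered[str(row.accession)] = str(row.accession)
    return rendered
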