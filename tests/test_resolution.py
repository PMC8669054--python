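"""Accession resolution: candidate filtering, cascade choice, discrepancy flags."""

import datetime as dt
import random

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohortforge.resolution import (
    ABDOMEN_GROUP,
    PacsIndex,
    PacsStudyRecord,
    apply_overrides,
    find_candidates,
    flag_misresolutions,
    flag_registry_discrepancies,
    resolve_accession,
)

DATE = dt.date(2012, 6, 15)


def _study(acc, body_part="abdomen", day_offset=0, image_count=100, mrn="01234567",
           modality="CT"):
    return PacsStudyRecord(
        mrn=mrn, accession=acc, study_date=DATE + dt.timedelta(days=day_offset),
        body_part=body_part, modality=modality, image_count=image_count,
    )


def _index(records):
    df = pd.DataFrame(
        [
            dict(mrn=r.mrn, accession=r.accession, study_date=r.study_date.isoformat(),
                 body_part=r.body_part, modality=r.modality, image_count=r.image_count)
            for r in records
        ],
        columns=["mrn", "accession", "study_date", "body_part", "modality", "image_count"],
    )
    return PacsIndex({"site": df})


def test_image_count_threshold_is_strict():
    index = _index([_study("a20", image_count=20), _study("a21", image_count=21)])
    cands = find_candidates(index, "01234567", DATE, 0)
    assert [c.accession for c in cands] == ["a21"]


def test_find_candidates_empty_index():
    assert find_candidates(_index([]), "01234567", DATE, 0) == []


def test_find_candidates_windows_match_linear_scan():
    """Seven-study hand case vs an exhaustive date-difference scan."""
    studies = [
        _study("d0", day_offset=0), _study("dm1", day_offset=-1),
        _study("dp3", day_offset=3), _study("dp4", day_offset=4),
        _study("dm5", day_offset=-5), _study("small", day_offset=0, image_count=5),
        _study("mr", day_offset=0, modality="MR"),
    ]
    index = _index(studies)
    for window in (0, 4):
        got = {c.accession for c in find_candidates(index, "01234567", DATE, window)}
        want = {
            s.accession for s in studies
            if s.modality == "CT" and s.image_count > 20
            and abs((s.study_date - DATE).days) <= window
        }
        assert got == want


def test_cascade_prefers_abdomen_over_pelvis():
    cands = [_study("pel", "pelvis"), _study("abd", "abdomen")]
    res = resolve_accession(("01234567", "abd"), DATE, cands, cands)
    assert res.status == "resolved"
    assert res.chosen_accession == "abd"
    assert res.tier == "abdomen_same_window"
    assert res.window_used == 0
    assert not res.differs_from_registry


def test_cascade_unresolved_when_no_candidates():
    res = resolve_accession(("01234567", "x"), DATE, [], [])
    assert res.status == "unresolved"
    assert res.chosen_accession is None
    assert res.tier is None


def test_cascade_pelvis_preferred_over_chest_then_date_expansion():
    w4_only = [_study("chest4", "chest", day_offset=4), _study("pel4", "pelvis", day_offset=2)]
    res = resolve_accession(("01234567", "reg"), DATE, [], w4_only)
    assert res.tier == "date_expanded"
    assert res.chosen_accession == "pel4"  # no abdomen anywhere; pelvis beats chest
    assert res.differs_from_registry


def _oracle_choice(w0, w4, date):
    """Independent brute-force statement of the documented preference order:
    enumerate (tier, date distance, -image count, accession) tuples over
    every candidate and take the lexicographic minimum."""
    scored = []
    for window, cands in ((0, w0), (4, w4)):
        for rank, predicate in enumerate(
            (lambda r: r.body_part in ABDOMEN_GROUP,
             lambda r: r.body_part == "pelvis",
             lambda r: r.body_part == "chest")
        ):
            tier = (0 if window == 0 else 1) * 3 + rank
            for r in cands:
                if predicate(r):
                    scored.append(
                        ((tier, abs((r.study_date - date).days), -r.image_count, r.accession), r)
                    )
    if not scored:
        return None
    return min(scored)[1].accession


_candidate_strategy = st.lists(
    st.builds(
        _study,
        acc=st.sampled_from([f"acc{i}" for i in range(6)]),
        body_part=st.sampled_from(["abdomen", "pelvis", "chest"]),
        day_offset=st.sampled_from([0, -1, 1, -3, 3, -4, 4]),
        image_count=st.sampled_from([21, 50]),
    ),
    max_size=6,
    unique_by=lambda s: s.accession,
)


@settings(max_examples=400, derandomize=True, deadline=None)
@given(_candidate_strategy)
def test_cascade_equals_enumeration_oracle(candidates):
    """Resolver choice equals exhaustive enumeration under the stated
    preference order, for every candidate set of size <= 6."""
    w0 = [c for c in candidates if c.study_date == DATE]
    res = resolve_accession(("01234567", "reg"), DATE, w0, candidates)
    expected = _oracle_choice(w0, candidates, DATE)
    if expected is None:
        assert res.status == "unresolved"
    else:
        assert res.chosen_accession == expected


@settings(max_examples=100, derandomize=True, deadline=None)
@given(_candidate_strategy, st.randoms(use_true_random=False))
def test_cascade_order_invariance(candidates, rnd):
    w0 = [c for c in candidates if c.study_date == DATE]
    baseline = resolve_accession(("01234567", "reg"), DATE, w0, candidates)
    shuffled_w0, shuffled_w4 = list(w0), list(candidates)
    rnd.shuffle(shuffled_w0)
    rnd.shuffle(shuffled_w4)
    again = resolve_accession(("01234567", "reg"), DATE, shuffled_w0, shuffled_w4)
    assert baseline == again


@settings(max_examples=100, derandomize=True, deadline=None)
@given(_candidate_strategy)
def test_window_expansion_never_changes_tier1_resolution(candidates):
    """Enlarging the date window must not disturb a same-day abdomen hit."""
    w0 = [c for c in candidates if c.study_date == DATE]
    narrow = resolve_accession(("01234567", "reg"), DATE, w0, w0)
    if narrow.status == "resolved" and narrow.tier == "abdomen_same_window":
        wide = resolve_accession(("01234567", "reg"), DATE, w0, candidates)
        assert wide.chosen_accession == narrow.chosen_accession
        assert wide.tier == narrow.tier


def test_flag_registry_discrepancies_hand_case():
    results = pd.DataFrame(
        {
            "patient_id_canonical": [f"p{i}" for i in range(5)],
            "accession_canonical": ["r0", "r1", "r2", "r3", "r4"],
            "status": ["resolved"] * 4 + ["unresolved"],
            "chosen_accession": ["r0", "x1", "r2", "x3", ""],
        }
    )
    n, flagged = flag_registry_discrepancies(results)
    assert n == 2
    assert flagged["accession_canonical"].tolist() == ["r1", "r3"]  # sorted by exam key


def test_flag_registry_discrepancies_identity_run():
    results = pd.DataFrame(
        {
            "patient_id_canonical": ["p0"], "accession_canonical": ["r0"],
            "status": ["resolved"], "chosen_accession": ["r0"],
        }
    )
    assert flag_registry_discrepancies(results)[0] == 0


def test_flag_misresolutions_requires_ground_truth():
    results = pd.DataFrame({"status": []})
    with pytest.raises(ValueError):
        flag_misresolutions(results, pd.DataFrame())


def test_flag_misresolutions_and_override_replay():
    results = pd.DataFrame(
        {
            "patient_id_canonical": ["p0", "p1", "p2"],
            "accession_canonical": ["r0", "r1", "r2"],
            "status": ["resolved"] * 3,
            "chosen_accession": ["r0", "wrong", "r2"],
        }
    )
    truth = pd.DataFrame(
        {
            "patient_id": ["p0", "p1", "p2"],
            "registry_accession": ["r0", "r1", "r2"],
            "true_accession": ["r0", "true1", "r2"],
        }
    )
    n, overrides = flag_misresolutions(results, truth)
    assert n == 1
    corrected = apply_overrides(results, overrides)
    assert corrected["chosen_accession"].tolist() == ["r0", "true1", "r2"]


def test_misresolution_count_matches_adversarial_injections(small_bundle, small_result):
    """Every adversarial record — and nothing else — mis-resolves, matching
    record-by-record ground-truth comparison."""
    n_adversarial = int(
        (small_bundle.ground_truth["injected_mode"] == "adversarial_misresolution").sum()
    )
    assert small_result.n_misresolved == n_adversarial == 2
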