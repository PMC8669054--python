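"""Synthetic fixture generation: determinism, label conservation, solvability."""

import pandas as pd
import pytest

from cohortforge.fixtures import (
    FixtureConfig,
    FixtureConfigError,
    NON_RECOVERABLE_MODES,
    generate_fixture,
    generate_pacs_index,
    generate_registry,
    paper_replica_config,
    split_by_proportions,
)
from cohortforge.resolution import PacsIndex, find_candidates, resolve_accession

from conftest import SMALL_MODE_COUNTS, small_config


def test_replica_preset_encodes_documented_attrition():
    config = paper_replica_config()
    assert config.n_patients == 23_186
    assert config.n_exams == 33_182
    assert config.mode_count("mislabeled_interventional") == 283
    assert config.mode_count("mrn_zero_dropped") + config.mode_count("acc_prefix_added") == 10_089
    linkage = (config.mode_count("billing_only_acc") + config.mode_count("linkage_pelvis")
               + config.mode_count("linkage_chest"))
    assert linkage == 838
    assert config.mode_count("adversarial_misresolution") == 24
    assert sum(config.mode_count(m) for m in NON_RECOVERABLE_MODES) == 51
    assert [config.mode_count(m) for m in NON_RECOVERABLE_MODES] == [17, 7, 8, 3, 1, 15]
    # preset is a constant
    assert paper_replica_config() == config


def test_split_by_proportions_sums_exactly():
    assert sum(split_by_proportions(838, (0.6, 0.3, 0.1))) == 838
    assert split_by_proportions(10, (0.5, 0.5, 0.0)) == [5, 5, 0]


def test_generation_is_byte_identical_across_calls(tmp_path):
    config = small_config(seed=3)
    reg1, truth1 = generate_registry(config)
    reg2, truth2 = generate_registry(config)
    assert reg1.to_csv(index=False) == reg2.to_csv(index=False)
    assert truth1.to_csv(index=False) == truth2.to_csv(index=False)
    pacs1 = generate_pacs_index(reg1, truth1, config)
    pacs2 = generate_pacs_index(reg2, truth2, config)
    for site in pacs1:
        assert pacs1[site].to_csv(index=False) == pacs2[site].to_csv(index=False)


def test_different_seeds_move_dressing_not_counts():
    a = generate_fixture(small_config(seed=1), verify=False)
    b = generate_fixture(small_config(seed=2), verify=False)
    assert a.registry.to_csv(index=False) != b.registry.to_csv(index=False)
    counts_a = a.ground_truth["injected_mode"].value_counts().to_dict()
    counts_b = b.ground_truth["injected_mode"].value_counts().to_dict()
    assert counts_a == counts_b


def test_label_conservation(small_bundle):
    """Each injected mode appears in the ground truth exactly as often as
    the config requested."""
    primaries = small_bundle.ground_truth.query("row_class == 'primary'")
    counts = primaries["injected_mode"].value_counts().to_dict()
    for mode, expected in SMALL_MODE_COUNTS.items():
        assert counts.get(mode, 0) == expected
    config = small_bundle.config
    assert counts.get("none", 0) == config.n_patients - sum(SMALL_MODE_COUNTS.values())
    assert len(small_bundle.registry) == (
        config.n_exams + sum(config.decoy_counts.values())
    )


def test_zero_injection_config_is_all_clean():
    config = FixtureConfig(n_patients=10, n_exams=12, seed=5)
    registry, truth = generate_registry(config)
    assert len(registry) == 12
    assert (truth["injected_mode"] == "none").all()


def test_injection_counts_exceeding_patients_rejected():
    with pytest.raises(FixtureConfigError):
        FixtureConfig(n_patients=5, n_exams=5, mode_counts={"missing": 6})
    with pytest.raises(FixtureConfigError):
        FixtureConfig(n_patients=5, n_exams=5, mode_counts={"bogus_mode": 1})
    with pytest.raises(FixtureConfigError):
        FixtureConfig(n_patients=5, n_exams=5, linkage_proportions=(0.9, 0.9, 0.2))
    with pytest.raises(FixtureConfigError):
        FixtureConfig(n_patients=5, n_exams=4)


def test_pacs_index_requires_matching_generation_run():
    config = small_config()
    registry, truth = generate_registry(config)
    with pytest.raises(FixtureConfigError):
        generate_pacs_index(registry.iloc[:-1], truth, config)


def _pacs_rows_for(bundle, accession):
    rows = []
    for site, df in bundle.pacs.items():
        rows.extend(df[df["accession"] == accession].to_dict("records"))
    return rows


def test_pacs_rows_follow_linkage_modes(small_bundle):
    truth = small_bundle.ground_truth
    vocab_pelvis = {"PELVIS", "PEL", "Pelvis"}

    for row in truth.query("injected_mode == 'linkage_pelvis'").itertuples():
        registry_rows = _pacs_rows_for(small_bundle, row.registry_accession)
        true_rows = _pacs_rows_for(small_bundle, row.true_accession)
        assert all(r["image_count"] <= 20 for r in registry_rows)  # billing shell
        assert len(true_rows) == 1
        assert true_rows[0]["body_part"] in vocab_pelvis
        assert true_rows[0]["image_count"] > 20

    for row in truth.query("injected_mode == 'missing'").itertuples():
        assert _pacs_rows_for(small_bundle, row.registry_accession) == []

    for row in truth.query("injected_mode == 'none' and row_class == 'primary'").itertuples():
        true_rows = _pacs_rows_for(small_bundle, row.registry_accession)
        assert len(true_rows) == 1
        assert true_rows[0]["image_count"] > 20

    for row in truth.query("injected_mode == 'mrn_acc_discrepancy'").itertuples():
        rows = _pacs_rows_for(small_bundle, row.registry_accession)
        assert rows and all(r["mrn"] != row.patient_id for r in rows)


def test_true_accession_exists_unless_missing(small_bundle):
    truth = small_bundle.ground_truth.query("row_class in ('primary', 'extra')")
    for row in truth.itertuples():
        if row.injected_mode == "missing":
            assert row.true_accession == ""
        else:
            assert _pacs_rows_for(small_bundle, row.true_accession)


def test_fixture_solvability(small_bundle, small_result):
    """For every recoverable exam the cascade recovers the true accession."""
    truth = small_bundle.ground_truth.set_index(["patient_id", "registry_accession"])
    unrecoverable = set(NON_RECOVERABLE_MODES) | {"adversarial_misresolution"}
    res = small_result.resolutions  # post manual-correction replay
    checked = 0
    for row in res.itertuples():
        t = truth.loc[(row.patient_id_canonical, row.accession_canonical)]
        if t["injected_mode"] in unrecoverable or t["injected_mode"] == "mislabeled_interventional":
            continue
        assert row.status == "resolved"
        assert row.chosen_accession == t["true_accession"]
        checked += 1
    assert checked == small_result.attrition["cohort after keyword exclusion"] - 8 - 2


def test_adversarial_records_fool_the_cascade_by_construction(small_bundle):
    index = PacsIndex(small_bundle.pacs)
    truth = small_bundle.ground_truth
    dates = {
        (t.patient_id, t.registry_accession): r.exam_date
        for t, r in zip(truth.itertuples(), small_bundle.registry.itertuples())
    }
    adversarial = truth.query("injected_mode == 'adversarial_misresolution'")
    assert len(adversarial) == 2
    for row in adversarial.itertuples():
        key = (row.patient_id, row.registry_accession)
        date = pd.Timestamp(dates[key]).date()
        res = resolve_accession(
            key, date,
            find_candidates(index, key[0], date, 0),
            find_candidates(index, key[0], date, 4),
        )
        assert res.status == "resolved"
        assert res.chosen_accession == row.registry_accession  # the decoy
        assert res.chosen_accession != row.true_accession
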