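import pytest

from cohortforge.fixtures import (
    DECOY_KINDS,
    FixtureConfig,
    generate_fixture,
    paper_replica_config,
)
from cohortforge.pipeline import run_bundle

#: Injection counts for a desk-sized fixture exercising every failure mode.
SMALL_MODE_COUNTS = {
    "mislabeled_interventional": 3,
    "mrn_zero_dropped": 4,
    "acc_prefix_added": 3,
    "billing_only_acc": 3,
    "linkage_pelvis": 2,
    "linkage_chest": 2,
    "date_offset": 3,
    "adversarial_misresolution": 2,
    "mrn_acc_discrepancy": 2,
    "topogram_only": 1,
    "missing": 2,
    "corrupted": 1,
    "test_patient": 1,
    "encoding_error": 1,
}


def small_config(seed: int = 7, **overrides) -> FixtureConfig:
    """A 60-patient fixture with every injected mode represented."""
    kwargs = dict(
        n_patients=60,
        n_exams=80,
        seed=seed,
        mode_counts=dict(SMALL_MODE_COUNTS),
        decoy_counts={kind: 2 for kind in DECOY_KINDS},
        n_render_clean=3,
    )
    kwargs.update(overrides)
    return FixtureConfig(**kwargs)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_fixture(small_config())


@pytest.fixture(scope="session")
def small_result(small_bundle, tmp_path_factory):
    work = tmp_path_factory.mktemp("small_pipeline")
    return run_bundle(small_bundle, work, write_intermediates=True)


@pytest.fixture(scope="session")
def replica_bundle():
    return generate_fixture(paper_replica_config())


@pytest.fixture(scope="session")
def replica_result(replica_bundle, tmp_path_factory):
    work = tmp_path_factory.mktemp("replica_pipeline")
    return run_bundle(replica_bundle, work)
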