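import pytest

from riskproxy import RunConfig, build_study_replica, load_protocol_table, run_pipeline


@pytest.fixture(scope="session")
def replica_patients():
    return build_study_replica()


@pytest.fixture(scope="session")
def replica_records(replica_patients):
    return [p.record for p in replica_patients]


@pytest.fixture(scope="session")
def protocol_table():
    return load_protocol_table()


@pytest.fixture(scope="session")
def replica_result(tmp_path_factory):
    """Full pipeline run on the deterministic replica cohort."""
    out = tmp_path_factory.mktemp("replica_run")
    return run_pipeline(RunConfig(replica=True, out_dir=out))
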