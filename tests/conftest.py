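import pytest

from emocready import (
    build_paper_replica,
    build_tables,
    default_definitions_path,
    load_definitions,
    replica_definitions,
)
from emocready.synthetic_data import ReplicaCountSpec


@pytest.fixture(scope="session")
def default_defs():
    return load_definitions(default_definitions_path())


@pytest.fixture(scope="session")
def replica_spec():
    return ReplicaCountSpec.from_printed_tables()


@pytest.fixture(scope="session")
def replica_defs(replica_spec):
    return replica_definitions(replica_spec)


@pytest.fixture(scope="session")
def replica_cohort(replica_defs, replica_spec):
    return build_paper_replica(replica_defs, replica_spec)


@pytest.fixture(scope="session")
def replica_tables(replica_cohort, replica_defs):
    return build_tables(
        replica_cohort, replica_defs, strata=["csec_capable", "ownership", "country"]
    )
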