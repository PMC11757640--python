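"""Shared fixtures: the episode set and replicate archives.

Training archives are session-scoped because the replicate runs (10 GA and
10 BP replicates per master seed, three master seeds) dominate the suite's
runtime; every test that needs trained networks shares them.
"""

import numpy as np
import pytest

from acpflow.acp_task import generate_dataset
from acpflow.experiments import ReplicateArchive, replication_config, run_replicates

MASTER_SEEDS = (1, 2, 3)
N_REPLICATES = 10


@pytest.fixture(scope="session")
def data():
    return generate_dataset()


@pytest.fixture(scope="session")
def archives(data) -> dict[tuple[str, int], ReplicateArchive]:
    """Replication-profile archives for both methods and all master seeds."""
    out = {}
    for master in MASTER_SEEDS:
        for method in ("GA", "BP"):
            out[(method, master)] = run_replicates(
                method,
                N_REPLICATES,
                base_seed=1000 * master,
                config=replication_config(method),
                data=data,
            )
    return out


@pytest.fixture(scope="session")
def ga_archive(archives):
    return archives[("GA", 1)]


@pytest.fixture(scope="session")
def bp_archive(archives):
    return archives[("BP", 1)]
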