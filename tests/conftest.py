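"""Shared fixtures: one default simulated run and its pipeline stages.

The heavy artifacts (simulated run, demultiplexing, QC cascade) are
session-scoped so every test file reads from the same run instead of
re-simulating.
"""

import numpy as np
import pytest

from ampliwell.demux import demultiplex_run
from ampliwell.model import CCSRecord
from ampliwell.qc import run_qc
from ampliwell.simulate import SimulationConfig, simulate_run

DEFAULT_SEED = 3


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition synthetic run: 5 plates, ~2,000 reads."""
    return simulate_run(SimulationConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def reference_db(default_sim):
    return list(default_sim.pool.sequences.items())


@pytest.fixture(scope="session")
def ccs_records(default_sim):
    return [
        CCSRecord(rec.id, str(rec.seq), int(total))
        for rec, total in zip(
            default_sim.records, default_sim.sidecar.subread_total_nt
        )
    ]


@pytest.fixture(scope="session")
def truth_by_id(default_sim):
    return default_sim.truth.set_index("ccs_id")


@pytest.fixture(scope="session")
def demuxed(ccs_records, default_sim):
    return demultiplex_run(ccs_records, default_sim.manifest)


@pytest.fixture(scope="session")
def qc_result(demuxed, reference_db):
    bins, _, ledger = demuxed
    return run_qc(bins, reference_db, reference_db, ledger=ledger)


@pytest.fixture(scope="session")
def well_otus(qc_result):
    from ampliwell.cluster import cluster_all_wells

    return cluster_all_wells(qc_result.usable)


@pytest.fixture()
def rng():
    return np.random.default_rng(20160712)


def random_seq(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def mutate(rng, seq, rate):
    """Substitute each position independently with probability ``rate``."""
    arr = list(seq)
    for i in np.nonzero(rng.random(len(arr)) < rate)[0]:
        arr[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[i]]
    return "".join(arr)
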