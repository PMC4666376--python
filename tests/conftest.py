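import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import branchselex as bx
from branchselex.simulate import (
    SimConfig,
    make_affinity_model,
    make_truth_pool,
    simulate_run,
)

settings.register_profile(
    "suite",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def design():
    return bx.default_library_design()


@pytest.fixture(scope="session")
def sheet():
    return bx.default_sample_sheet()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_pair(design, entry, variable, read_id="r"):
    """Error-free read pair for one amplicon (test helper)."""
    amp = (
        entry.barcode_fwd
        + design.fwd_constant
        + variable
        + design.rev_constant
        + bx.revcomp(entry.barcode_rev)
    )
    fwd = amp[: design.read_length]
    rev = bx.revcomp(amp)[: design.read_length]
    return bx.ReadPair(read_id, fwd, "I" * len(fwd), rev, "I" * len(rev))


@pytest.fixture(scope="session")
def full_run(design, sheet):
    """One full branched-selection study: simulate, sequence, analyse.

    7-mutant alanine panel in two immobilisation modes plus latent and
    target:ligand-complex branches; 5 planted families over a background
    tail; 2e5 read pairs per sample with 0.1% substitution error.
    """
    pool = make_truth_pool(seed=1, n_background=3000)
    model = make_affinity_model(pool, seed=1)
    config = SimConfig(
        design=design, sheet=sheet, n_reads=200_000, error_rate=0.001, seed=1
    )
    run = simulate_run(pool, model, config)
    result = bx.analyze_pairs(run.all_pairs(), design, sheet)
    return pool, model, run, result


def family_cluster_ids(pool, cluster_table):
    """Map family_id -> cluster id of the cluster containing the family master."""
    seq2cluster = {}
    for c in cluster_table.clusters:
        for s in c.members:
            seq2cluster[s] = c.cluster_id
    return {
        fid: seq2cluster[fam.master]
        for fid, fam in pool.families.items()
        if fam.master in seq2cluster
    }
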