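"""Shared fixtures.

The expensive objects (the 30-residue structure-based model, its
denatured state and the staged-cooling refold runs) are session-scoped so
that unit tests and the end-to-end recovery tests share one computation.
"""

import numpy as np
import pytest

from foldkit import extract_ca_trace
from foldkit.refolding import (
    build_go_model,
    mc_run,
    run_refolding_protocol,
    unfold_stage,
)
from foldkit.synthetic_fixtures import (
    helix_bundle,
    ideal_helix,
    ideal_strand,
    random_coil,
    strand_pair,
)

REFOLD_SEEDS = (7, 1, 2, 3, 4)


@pytest.fixture(scope="session")
def helix20():
    return ideal_helix(20)


@pytest.fixture(scope="session")
def strand20():
    return ideal_strand(20)


@pytest.fixture(scope="session")
def coil20():
    return random_coil(20, seed=3)


@pytest.fixture(scope="session")
def bundle():
    return helix_bundle()


@pytest.fixture(scope="session")
def paired_strands():
    return strand_pair(8)


@pytest.fixture(scope="session")
def go_model():
    return build_go_model(extract_ca_trace(ideal_helix(30)))


@pytest.fixture(scope="session")
def unfolded(go_model):
    """Denaturation segment of the 30-residue model, seed 1."""
    return unfold_stage(go_model, seed=1)


@pytest.fixture(scope="session")
def refold_traces(go_model, unfolded):
    """Staged-cooling recovery runs from the shared denatured state,
    one per seed."""
    start = unfolded.final_positions()
    return {
        seed: run_refolding_protocol(go_model, start, seed=seed)
        for seed in REFOLD_SEEDS
    }


@pytest.fixture(scope="session")
def quench_final_qs(go_model, unfolded, refold_traces):
    """Final Q of single-stage quenches at the coldest ladder temperature,
    matched in total step budget to the corresponding staged runs."""
    from foldkit.refolding import DEFAULT_LADDER, native_contact_fraction

    cold = DEFAULT_LADDER.stages[-1].reduced_t
    interval = DEFAULT_LADDER.snapshot_interval
    out = {}
    for seed, trace in refold_traces.items():
        pos = unfolded.final_positions().copy()
        for k in range(len(trace.snapshots)):
            pos = mc_run(go_model, pos, cold, interval, seed=90_000 + seed * 137 + k)
        out[seed] = native_contact_fraction(go_model, pos)
    return out
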