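"""Shared fixtures: small simulated experiments reused across test modules."""

import numpy as np
import pytest

from bmtime import synth
from bmtime.pipeline import PipelineConfig, simulate_and_run


@pytest.fixture(scope="session")
def times30():
    """The study time grid (plus a t = 0 anchor), three replicates per level."""
    return np.repeat([0.0, 1, 2, 4, 6, 8, 12, 16, 20, 24], 3).astype(float)


@pytest.fixture(scope="session")
def small_sim():
    """A small two-compound experiment (one active, one inert) with truth."""
    cfg = synth.SimulationConfig(
        n_probes=300,
        pathway_sizes={"metal_stress": 25, "unfolded_protein": 25},
        compounds=[
            synth.CompoundArchetype("metalotox", concentration=10.0, responses={
                "metal_stress": synth.PathwayResponse(
                    "Hill", amplitude=3.5, onset_h=3.0, shape=3.0),
                "unfolded_protein": synth.PathwayResponse(
                    "Exp5", amplitude=3.0, onset_h=10.0, shape=2.0),
            }),
            synth.CompoundArchetype("inert_control", inert=True),
        ],
        seed=11,
    )
    counts, metadata, truth = synth.simulate_experiment(cfg)
    return cfg, counts, metadata, truth


@pytest.fixture(scope="session")
def small_run(small_sim, tmp_path_factory):
    """Full pipeline run on the small experiment (shared across tests)."""
    cfg, *_ = small_sim
    workdir = tmp_path_factory.mktemp("pipeline_run")
    pl = PipelineConfig(seed=11, n_perm=300, n_boot=50)
    report, recovery = simulate_and_run(cfg, pl, workdir=workdir)
    return workdir, report, recovery
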