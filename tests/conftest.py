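"""Shared fixtures: one synthetic study bundle reused across the suite."""

from __future__ import annotations

import pytest

from mirnascape.discovery import discover
from mirnascape.synthetic import (SimulationSpec, generate_genome,
                                  generate_targets_and_phasing,
                                  miniature_catalog, simulate_reads)


@pytest.fixture(scope="session")
def sim_spec():
    return SimulationSpec(seed=1)


@pytest.fixture(scope="session")
def sim_bundle(sim_spec):
    """(genome, truth, reads) for the default planted-locus study."""
    genome, truth = generate_genome(sim_spec)
    reads = simulate_reads(sim_spec, truth, genome)
    return genome, truth, reads


@pytest.fixture(scope="session")
def sim_targets(sim_spec, sim_bundle):
    """(transcripts, transcript reads) with the designed site patterns."""
    genome, truth, _reads = sim_bundle
    return generate_targets_and_phasing(sim_spec, truth)


@pytest.fixture(scope="session")
def catalog():
    return miniature_catalog()


@pytest.fixture(scope="session")
def discovered_loci(sim_bundle, catalog):
    """Full discovery on the default bundle (the expensive stage, run once)."""
    genome, _truth, reads = sim_bundle
    return discover(reads, genome, catalog)


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """Two identical full pipeline runs, for determinism checks."""
    from mirnascape.pipeline import RunConfig, run_all

    base = tmp_path_factory.mktemp("pipeline")
    out1 = run_all(RunConfig(seed=1), base / "run1")
    out2 = run_all(RunConfig(seed=1), base / "run2")
    return out1, out2
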