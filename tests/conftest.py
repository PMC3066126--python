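from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def truth_set():
    """The default synthetic truth set (seed 1), built once per session."""
    from germmir.simulate import generate_truth_set

    return generate_truth_set(seed=1)


@pytest.fixture(scope="session")
def sim_libraries(truth_set):
    from germmir.simulate import simulate_reads

    return (simulate_reads(truth_set, "lib1", seed=11),
            simulate_reads(truth_set, "lib2", seed=12))


@pytest.fixture(scope="session")
def sim_resources(truth_set, tmp_path_factory):
    from germmir.annotate import GeneModel
    from germmir.conserved import KnownMiRNARef
    from germmir.mapping import GenomeIndex
    from germmir.pipeline import Resources

    gff = tmp_path_factory.mktemp("gff") / "genes.gff3"
    gff.write_text(truth_set.gff3)
    return Resources(
        genome_index=GenomeIndex(truth_set.genome),
        ncrna_refs=truth_set.ncrna_refs,
        known_ref=KnownMiRNARef.from_records(truth_set.known_matures,
                                             truth_set.known_hairpins),
        gene_model=GeneModel.from_gff3(str(gff)),
        transcripts=truth_set.transcripts)


@pytest.fixture(scope="session")
def sim_run(truth_set, sim_libraries, sim_resources):
    """Full two-library pipeline run on the synthetic truth set."""
    from germmir.pipeline import run_pipeline

    lib1, lib2 = sim_libraries
    return run_pipeline({"lib1": lib1.reads, "lib2": lib2.reads},
                        adapter3=truth_set.manifest.params.adapter3,
                        resources=sim_resources)
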