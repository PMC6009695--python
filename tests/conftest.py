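import pytest

from ribostitch import annotate, cluster as cluster_mod, simulate as sim
from ribostitch.config import PipelineConfig


@pytest.fixture(scope="session")
def repeat_fixture():
    """3 identical operons with distinct flanks, 30x error-free 100 bp pairs."""
    genome, features = sim.synth_operon_genome(
        3, operon_length=5000, flank_length=1500, genome_length=28000, seed=1
    )
    pairs, truth = sim.simulate_reads(
        genome, sim.SimulationConfig(coverage=30, per_base_error=0.0, seed=1)
    )
    return {"genome": genome, "features": features, "pairs": pairs, "truth": truth}


@pytest.fixture(scope="session")
def repeat_clusters(repeat_fixture):
    rrna = annotate.scan([repeat_fixture["genome"]], features=repeat_fixture["features"])
    return cluster_mod.select(rrna, genome=[repeat_fixture["genome"]], flank=1000)


@pytest.fixture(scope="session")
def repeat_pipeline(repeat_fixture):
    """One full pipeline run on the repeat fixture, shared by read-only tests."""
    from ribostitch import pipeline

    return pipeline.run_de_fere_novo(
        [repeat_fixture["genome"]],
        repeat_fixture["features"],
        repeat_fixture["pairs"],
        PipelineConfig(iterations=2),
    )
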