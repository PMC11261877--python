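import numpy as np
import pytest

from rrndb import operon_extract, synth


@pytest.fixture(scope="session")
def templates():
    return synth.build_templates()


@pytest.fixture(scope="session")
def clean_fixture():
    """Small fixture with no anomalies and low mutation rates: every
    planted operon should survive extraction."""
    config = synth.SynthConfig(
        n_genomes=4, n_lineages=2, copy_number=3, copy_number_dist="fixed",
        seed=11)
    return synth.generate_fixture(config)


@pytest.fixture(scope="session")
def anomaly_fixture():
    """Fixture planting all three anomaly classes."""
    config = synth.SynthConfig(
        n_genomes=8, n_lineages=2, copy_number=4, copy_number_dist="fixed",
        partial_fraction=0.2, oversized_its_fraction=0.2,
        origin_crossing_fraction=0.15, seed=23)
    return synth.generate_fixture(config)


def extract_fixture_operons(fixture, max_its=1500):
    """Run the extraction pipeline over every genome of a fixture."""
    operons = []
    reports = {}
    for genome_id, (contigs, features) in fixture.genomes.items():
        level = fixture.manifest.set_index("genome_id").loc[
            genome_id, "assembly_level"]
        ops, report = operon_extract.extract_genome_operons(
            contigs, features, genome_id=genome_id, assembly_level=level,
            max_its=max_its)
        operons.extend(ops)
        reports[genome_id] = report
    return operons, reports


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
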