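import numpy as np
import pytest

from transloscan.synthetic_data import (
    ScenarioConfig,
    SimulationConfig,
    TranslocationSpec,
    apply_translocation,
    plant_microhomology,
    simulate_reference,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Two-chromosome toy genome: 12 genes of 800 bp, 700 bp intergenic,
    focal gene in the middle of chr2 (>5 kb upstream for promoter windows)."""
    return SimulationConfig(
        seed=1,
        n_chromosomes=2,
        genes_per_chromosome=12,
        gene_length=800,
        intergenic_length=700,
        focal_chromosome="chr2",
        focal_index=6,
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    genome, omap = simulate_reference(small_config)
    return genome, omap, small_config.focal_ortholog


@pytest.fixture()
def translocated_pair(small_reference, small_config):
    """(reference-with-tract, derived strain, truth) for a planted
    chr1-partner translocation 339 bp upstream with 8 bp microhomology."""
    genome, _, focal = small_reference
    spec = TranslocationSpec("chr1", offset=339, microhomology=8, seed=5)
    ref, _ = plant_microhomology(genome, focal, spec)
    derived, truth = apply_translocation(ref, focal, spec, strain_id="T1")
    return ref, derived, truth, focal


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250928)
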