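import numpy as np
import pytest

from tnseqfit import SimulationConfig
from tnseqfit.genome import FeatureAnnotation, Genome
from tnseqfit.simulate import simulate_to_dir


@pytest.fixture
def toy_genome():
    #            0123456789012345678901234
    residues = "GGTACCTTAAGGCCTATAGGCCGTA"
    return Genome.from_string(residues)


@pytest.fixture(scope="session")
def small_config():
    """A fast end-to-end configuration used by multiple modules."""
    return SimulationConfig(
        seed=7,
        genome_length=40_000,
        n_features=30,
        target_unique_insertions=600,
        sequencing_depth=40_000,
        fraction_lethal_fumarate=0.2,
        fraction_electrode_defective=0.1,
    )


@pytest.fixture(scope="session")
def small_run(small_config, tmp_path_factory):
    """Simulated dataset (genome, annotation, FASTQ, truth) on disk."""
    outdir = tmp_path_factory.mktemp("small_run")
    out = simulate_to_dir(small_config, outdir)
    out["outdir"] = outdir
    return out


def random_feature(rng: np.random.Generator, genome_len: int, min_len: int = 40):
    """A random feature placed inside a genome, for property tests."""
    length = int(rng.integers(min_len, max(min_len + 1, genome_len // 3)))
    start0 = int(rng.integers(0, genome_len - length))
    strand = "+" if rng.random() < 0.5 else "-"
    return FeatureAnnotation(
        f"f{start0}", "chr", start0 + 1, start0 + length, strand
    )
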