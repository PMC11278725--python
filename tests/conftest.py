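import numpy as np
import pytest

from genedepth import fixtures


@pytest.fixture(scope="session")
def exact_community(tmp_path_factory):
    """Noise-free two-genome community with known score 1.75."""
    spec = fixtures.CommunitySpec(
        gene_plan={"K00927": [1, 2]},
        n_samples=1,
        n_genomes=2,
        contigs_per_genome=3,
        abundances=np.array([[2.0], [6.0]]),
        seed=7,
    )
    out = tmp_path_factory.mktemp("exact_community")
    manifest, truth = fixtures.generate_community(spec, out)
    return manifest, truth


@pytest.fixture(scope="session")
def small_community(tmp_path_factory):
    """Random noise-free community: 8 genomes, 3 samples, 2 queries."""
    rng = np.random.default_rng(11)
    spec = fixtures.CommunitySpec(
        gene_plan={
            "K00134": list(rng.integers(0, 3, size=8)),
            "K00150": list(rng.integers(0, 2, size=8)),
        },
        n_samples=3,
        n_genomes=8,
        contigs_per_genome=4,
        noise_sd=0.0,
        seed=11,
    )
    out = tmp_path_factory.mktemp("small_community")
    manifest, truth = fixtures.generate_community(spec, out)
    return manifest, truth


@pytest.fixture(scope="session")
def hmm_fixture(tmp_path_factory):
    """Real searchable profile + targets with planted matches and decoys."""
    out = tmp_path_factory.mktemp("hmm_fixture")
    return fixtures.generate_hmm_fixture(out, seed=3)
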