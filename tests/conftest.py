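import pytest
from hypothesis import settings

from spacerscope.io_core import RunConfig
from spacerscope.synthetic_data import (
    ProtospacerSpec,
    SynthHostSpec,
    generate_host,
    generate_phage,
    random_repeat_pair,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

# tRNA-Ile-like reference plus two decoys for normalization tests
TRNA_ILE = (
    "GGGCTTGTAGCTCAGGTGGTTAGAGCGCACCCCTGATAAGGGTGAGGTCGGTGGTTCAAGTCCACTCAGGCCCACCA"
)
TRNA_ALA = (
    "GGGGCTATAGCTCAGCTGGGAGAGCGCTTGCATGGCATGCAAGAGGTCAGCGGTTCGATCCCGCTTAGCTCCACCA"
)
TRNA_GLY = (
    "GCGGGAATAGCTCAGTTGGTAGAGCACGACCTTGCCAAGGTCGGGGTCGCGAGTTCGAGTCTCGTTTCCCGCTCCA"
)


@pytest.fixture(scope="session")
def config():
    return RunConfig(seed=11)


@pytest.fixture(scope="session")
def repeats():
    return random_repeat_pair(28, seed=7)


@pytest.fixture(scope="session")
def host(repeats):
    r1, r2 = repeats
    spec = SynthHostSpec(
        genome_length=100_000,
        intergenic_fraction=0.114,
        n_genes=100,
        arrays=[(r1, 8, 32), (r2, 8, 32)],
    )
    return generate_host(spec, seed=42)


@pytest.fixture(scope="session")
def trna_set():
    return [("tRNA-Ile", TRNA_ILE), ("tRNA-Ala", TRNA_ALA), ("tRNA-Gly", TRNA_GLY)]


@pytest.fixture(scope="session")
def escape_phage(host, config):
    """Phage carrying the three-protospacer design plus one repeat-flanked
    control protospacer."""
    _genome, arrays, _truth = host
    aid = arrays[0].array_id
    specs = [
        ProtospacerSpec((aid, 0), "antisense", pam="AG", n_mismatches=1),
        ProtospacerSpec((aid, 1), "antisense", pam="GG", n_mismatches=0),
        ProtospacerSpec((aid, 2), "sense", pam="TG", n_mismatches=3, seed_mismatch=True),
        ProtospacerSpec((aid, 3), "antisense", flank_mode="repeat"),
    ]
    return generate_phage(arrays, specs, 40_000, seed=5, config=config)
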