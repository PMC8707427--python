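import pytest

import mitostruct as ms


def simulate_scenario(genome_len, iso_spec, depth, lib_seed, genome_seed=11, error_rate=0.0):
    """Generate genome + molecules + reads and run the full assessment."""
    genome, _ = ms.generate_genome(ms.GenomeSpec(length=genome_len, seed=genome_seed))
    molecules = ms.build_isoforms(genome, iso_spec)
    lib = ms.LibrarySpec(depth_target=depth, error_rate=error_rate, seed=lib_seed)
    reads1, reads2, truth = ms.simulate_pairs(molecules, lib)
    return genome, reads1, reads2, truth


@pytest.fixture(scope="session")
def circle_sim():
    """A 50 kb single circular molecule sequenced at 20x."""
    L = 50000
    iso = ms.IsoformSpec([ms.MoleculeSpec("circle", "circular", [(1, L, "+")], 1.0)])
    genome, r1, r2, truth = simulate_scenario(L, iso, depth=20, lib_seed=101)
    return genome, r1, r2, truth, ms.assess_structure(genome, r1, r2)


@pytest.fixture(scope="session")
def linear_sim():
    """A 30 kb linear molecule sequenced at 20x."""
    L = 30000
    iso = ms.IsoformSpec([ms.MoleculeSpec("mol", "linear", [(1, L, "+")], 1.0)])
    genome, r1, r2, truth = simulate_scenario(L, iso, depth=20, lib_seed=102)
    return genome, r1, r2, truth, ms.assess_structure(genome, r1, r2)


BRIDGE_START, BRIDGE_END = 50001, 53000


@pytest.fixture(scope="session")
def bridge_sim():
    """100 kb scaffold: two circles interconverting with a linearized form
    through a 3 kb bridge at a 3:1 depth ratio, sequenced at 30x."""
    L = 100000
    iso = ms.two_circle_bridge_spec(L, BRIDGE_START, BRIDGE_END, ratio=3.0)
    genome, r1, r2, truth = simulate_scenario(L, iso, depth=30, lib_seed=103)
    return genome, r1, r2, truth, ms.assess_structure(genome, r1, r2)
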