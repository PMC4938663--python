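import numpy as np
import pytest

from srnaplace import align, sim
from srnaplace.align import AlignmentGroup, AlignmentSite


@pytest.fixture(scope="session")
def small_simulation():
    """A shared 100-kb simulation with repeat families of copy number 2-4:
    genome, library (20k reads), index, and all-alignment groups."""
    gcfg = sim.SimGenomeConfig(
        n_references=2,
        reference_length=50_000,
        n_loci=24,
        repeat_families=[(2, 150), (3, 180), (4, 200), (2, 220)],
        rng_seed=101,
    )
    sg = sim.generate_genome(gcfg)
    lib = sim.simulate_library(
        sg.references, sg.loci, sim.SimLibraryConfig(n_reads=20_000, rng_seed=102)
    )
    index = align.GenomeIndex(sg.references)
    groups = align.align_library(zip(lib.read_ids, lib.sequences), index)
    return sg, lib, index, groups


def build_worked_example():
    """The two-locus textbook configuration: a two-site read whose first
    vicinity holds seven uniquely aligned reads and whose second holds one
    unique read plus three two-site reads (fractional weight 2.5)."""
    ref_lengths = {"ref1": 100_000}
    L = 21
    green = AlignmentGroup(
        "green",
        "A" * L,
        [AlignmentSite("ref1", 1000, "+", L), AlignmentSite("ref1", 5000, "+", L)],
    )
    groups = [green]
    for i in range(7):
        groups.append(
            AlignmentGroup(f"u1_{i}", "C" * L, [AlignmentSite("ref1", 950 + 10 * i, "+", L)])
        )
    groups.append(AlignmentGroup("u2_0", "G" * L, [AlignmentSite("ref1", 5010, "+", L)]))
    for i in range(3):
        groups.append(
            AlignmentGroup(
                f"m2_{i}",
                "T" * L,
                [
                    AlignmentSite("ref1", 4990 + 30 * i, "+", L),
                    AlignmentSite("ref1", 50_000 + 1000 * i, "+", L),
                ],
            )
        )
    return ref_lengths, groups, green


@pytest.fixture
def worked_example():
    return build_worked_example()


@pytest.fixture
def random_genome():
    rng = np.random.default_rng(7)
    return {"chrA": "".join(rng.choice(list("ACGT"), size=10_000))}
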