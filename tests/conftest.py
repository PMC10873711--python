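import numpy as np
import pytest
from hypothesis import settings

from hapsoma.simgen import CloneTree, GenomeConfig, generate_diploid, spike_somatic

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def small_config(**overrides):
    """50-kb sweet-orange-like genome, cheap enough for per-test pipelines."""
    base = dict(
        contigs={"chr1": 50_000},
        n_hap_specific_segments=2,
        hap_specific_len=(1_000, 3_000),
        ancestry_block_mean=15_000,
        seed=101,
    )
    base.update(overrides)
    return GenomeConfig(**base)


@pytest.fixture(scope="session")
def small_genome():
    return generate_diploid(small_config())


@pytest.fixture(scope="session")
def small_truth(small_genome):
    return spike_somatic(small_genome, CloneTree.linear(1), 80, seed=7)


@pytest.fixture(scope="session")
def plain_genome():
    """Repeat-free 30-kb genome: fast, fully mappable."""
    return generate_diploid(small_config(contigs={"chr1": 30_000}, repeat_fraction=0.0,
                                         n_hap_specific_segments=0, seed=55))


class TruthCall:
    """Minimal call-like adapter for building population maps from truth."""

    def __init__(self, m):
        self.contig = m.contig
        self.pos0 = m.pos0
        self.ref = m.ref
        self.alt = m.alt
        self.haplotype = m.haplotype_id
        self.genotype = ()
        self.retained = True


def truth_callsets(genome, tree, truth):
    """Per-leaf call sets implied by the clone tree (no read simulation)."""
    out = {}
    for leaf in sorted(tree.leaves):
        branches = set(tree.path_branches(leaf))
        out[leaf] = [TruthCall(m) for m in truth if m.branch_id in branches]
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(0)
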