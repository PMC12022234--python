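import pytest

from nivgeno import (
    GenotypeCall,
    Locus,
    LocusPanel,
    ReplicateRecord,
    SampleConsensus,
    default_wolf_panel,
)


@pytest.fixture(scope="session")
def panel():
    return default_wolf_panel()


@pytest.fixture(scope="session")
def two_locus_panel():
    return LocusPanel((
        Locus("L1", 1, (100, 160)),
        Locus("L2", 1, (120, 180)),
    ))


def make_replicate(sample_id, idx, panel, calls):
    """ReplicateRecord with unspecified panel loci scored missing."""
    full = {name: GenotypeCall.missing() for name in panel.locus_names}
    full.update(calls)
    return ReplicateRecord(sample_id, idx, full)


def make_sample(sample_id, panel, genotype, mean_qi=1.0):
    """SampleConsensus straight from a {locus: (a, b) | None} genotype map."""
    calls = {}
    for name in panel.locus_names:
        pair = genotype.get(name)
        calls[name] = GenotypeCall.called(*pair) if pair else GenotypeCall.missing()
    return SampleConsensus(
        sample_id=sample_id, calls=calls, n_replicates=4, mean_qi=mean_qi
    )


@pytest.fixture
def replicate_factory():
    return make_replicate


@pytest.fixture
def sample_factory():
    return make_sample
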