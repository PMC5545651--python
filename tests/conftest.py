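import pytest

from cnvassoc.simulate import fixture_small


@pytest.fixture(scope="session")
def small_bundle():
    """The hand-checkable 200-sample bundle (shared, read-only)."""
    return fixture_small()


@pytest.fixture(scope="session")
def small_discovery(small_bundle):
    """Full discovery run on the small bundle (shared, read-only)."""
    from cnvassoc.pipeline import RunConfig, run_discovery

    return run_discovery(
        small_bundle.manifest,
        small_bundle.calls_a,
        small_bundle.calls_b,
        small_bundle.dgv,
        small_bundle.genes,
        config=RunConfig(n_permutations=500),
    )
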