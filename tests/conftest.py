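import numpy as np
import pytest

import trindex as tx


@pytest.fixture(scope="session")
def scheme() -> tx.SchemeSpec:
    """The packaged default triple-index scheme (12 fwd + 8 rev barcodes)."""
    return tx.default_scheme()


@pytest.fixture(scope="session")
def templates() -> tx.TemplateSet:
    """33-species mock community spanning the 30-69% GC gradient."""
    return tx.make_mock_templates(n_species=33, seed=11)


@pytest.fixture(scope="session")
def small_templates() -> tx.TemplateSet:
    return tx.make_mock_templates(n_species=5, length=120, gc_min=0.4, gc_max=0.6, seed=3)


@pytest.fixture
def toy_parts() -> tx.PrimerParts:
    return tx.PrimerParts(
        partial_adapter_fwd="ACGT",
        partial_adapter_rev="TTTT",
        priming_fwd="GGGG",
        priming_rev="CCCC",
        pcr2_adapter_fwd="AAAA",
        pcr2_adapter_rev="CCCC",
        pcr2_indices=("ATCACG",),
    )


def make_well_list(scheme: tx.SchemeSpec, n: int, pool: str = "i1"):
    """First n wells of the default plate as (pool, fwd, rev) triples."""
    layout = tx.build_plate_layout(scheme.forward, scheme.reverse)
    assert len(layout) >= n
    return [(pool, w.fwd, w.rev) for w in layout.wells[:n]]


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20261001)
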