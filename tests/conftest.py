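import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from cansys.enrichment import GeneSet, RankedUniverse
from cansys.fixtures import FixtureSpec, make_sample


def make_universe(impacts, genes=None) -> RankedUniverse:
    """Build a RankedUniverse directly from an impact vector (desc order)."""
    impacts = np.asarray(impacts, dtype=float)
    if genes is None:
        genes = tuple(f"g{i:03d}" for i in range(len(impacts)))
    return RankedUniverse(genes=tuple(genes), impacts=impacts)


def random_universe(rng, n, zeros_fraction=0.3):
    """Random non-negative impacts sorted descending, some exact zeros."""
    impacts = rng.random(n)
    impacts[rng.random(n) < zeros_fraction] = 0.0
    impacts = np.sort(impacts)[::-1]
    return make_universe(impacts)


@pytest.fixture(scope="session")
def sample_bundle(tmp_path_factory):
    """One deterministic synthetic sample on disk, shared across tests."""
    outdir = tmp_path_factory.mktemp("fixture_sample")
    spec = FixtureSpec(seed=42)
    return spec, make_sample(spec, outdir)


@pytest.fixture()
def geneset():
    def _make(set_id, genes):
        return GeneSet(id=set_id, name=set_id, genes=frozenset(genes))
    return _make
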