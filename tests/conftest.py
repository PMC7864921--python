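import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from crustassembly import OtuTable, PhyloTree, SampleMetadata, make_fixture


@pytest.fixture(scope="session")
def toy_tree() -> PhyloTree:
    """The 3-taxon worked-example tree ((A:1,B:1):1,C:2)."""
    return PhyloTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def small_table() -> OtuTable:
    df = pd.DataFrame(
        [[5, 0, 2], [1, 3, 0], [0, 2, 2], [4, 4, 4]],
        index=["s1", "s2", "s3", "s4"],
        columns=["OTU_1", "OTU_2", "OTU_3"],
        dtype=float,
    )
    return OtuTable(df)


@pytest.fixture(scope="session")
def mixed_fixture_dir(tmp_path_factory) -> Path:
    """The mixed_succession scenario written to disk once per session."""
    out = tmp_path_factory.mktemp("fixtures") / "mixed_succession"
    return make_fixture("mixed_succession", out, seed=7)


@pytest.fixture(scope="session")
def drift_fixture_dir(tmp_path_factory) -> Path:
    out = tmp_path_factory.mktemp("fixtures") / "drift"
    return make_fixture("drift", out, seed=3)


def make_metadata(lons, lats=None, stages=None, maps=None, sites=None):
    """Helper to assemble a SampleMetadata table from short vectors."""
    n = len(lons)
    lats = lats if lats is not None else [40.0] * n
    stages = stages if stages is not None else ["A"] * n
    maps = maps if maps is not None else [100.0] * n
    sites = sites if sites is not None else [f"site{i}" for i in range(n)]
    idx = [f"s{i}" for i in range(n)]
    return SampleMetadata(pd.DataFrame(
        dict(site_id=sites, lat=lats, lon=lons, stage=stages,
             map_mm=maps, replicate=1), index=idx))
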