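import pytest

from trackfig.fixtures import FixtureParams, write_fixture_set
from trackfig.layout import GenomicInterval, RegionSet, build_canvas_map


@pytest.fixture(scope="session")
def fixture_params():
    return FixtureParams(seed=1)


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory, fixture_params):
    """Full synthetic input set (all dialects + ready-to-run config)."""
    out = tmp_path_factory.mktemp("fixture_set")
    return write_fixture_set(out, fixture_params)


@pytest.fixture
def two_regions():
    """The canonical worked example: chr3:100-200 and chr8:500-600."""
    return RegionSet(
        (GenomicInterval("chr3", 100, 200), GenomicInterval("chr8", 500, 600))
    )


@pytest.fixture
def two_region_map(two_regions):
    """Canvas map with gap 0.1: segments [0, 0.45] and [0.55, 1.0]."""
    return build_canvas_map(two_regions, gap=0.1)
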