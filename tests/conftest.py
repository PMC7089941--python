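import numpy as np
import pytest

from hgsoc_strat.simulate import default_signature, gen_cohort
from hgsoc_strat.types import MB, Segment, SegmentProfile


def seg(chrom, start_mb, end_mb, cn, major=None):
    """Segment from Mb coordinates: [start_mb, end_mb) as 1-based closed bp."""
    return Segment(chrom, int(start_mb * MB) + 1, int(end_mb * MB), cn, major)


@pytest.fixture
def make_profile():
    def _make(*segments, sample_id="S1"):
        return SegmentProfile(sample_id, list(segments))
    return _make


@pytest.fixture
def fibrosis_signature():
    return default_signature()


@pytest.fixture(scope="session")
def synthetic_cohort():
    """One shared default cohort (n = 4 x 50, seed 7) for pipeline tests."""
    return gen_cohort(seed=7)


@pytest.fixture(scope="session")
def cohort_dir(synthetic_cohort, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("cohort")
    paths = synthetic_cohort.write(outdir)
    return paths
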