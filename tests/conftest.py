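import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from poolsweep.types import SiteCounts, sites_frame

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_sites(rows):
    """Rows of (contig, pos, qual, a_major, a_minor, b_major, b_minor)."""
    return sites_frame([SiteCounts(*r) for r in rows])


@pytest.fixture
def random_sites():
    """~2000 segregating sites on one 500-kb contig, both groups covered."""
    rng = np.random.default_rng(42)
    n = 2000
    pos = np.sort(rng.choice(np.arange(1, 500_001), size=n, replace=False))
    counts = rng.integers(1, 60, size=(n, 4))
    return pd.DataFrame({
        "contig": "chr1",
        "pos": pos,
        "qual": rng.uniform(20, 60, n),
        "a_major": counts[:, 0] + counts[:, 1],
        "a_minor": counts[:, 1],
        "b_major": counts[:, 2] + counts[:, 3],
        "b_minor": counts[:, 3],
    })


@pytest.fixture
def qc_fixture_12():
    """Hand-traced 12-site QC fixture.

    Two sites fail the quality filter (qual 10 and 15), two 2-site clusters
    (4003-4005 and 6000-6002) fail spacing, and one site with group-A depth
    300 fails the depth filter (post-spacing mean_A = 75, bounds [25, 150]);
    five sites survive.
    """
    rows = [
        ("chr1", 1000, 50.0, 20, 10, 20, 10),
        ("chr1", 2000, 10.0, 20, 10, 20, 10),   # fails quality
        ("chr1", 3000, 50.0, 20, 10, 20, 10),
        ("chr1", 4003, 50.0, 20, 10, 20, 10),   # cluster: fails spacing
        ("chr1", 4005, 50.0, 20, 10, 20, 10),   # cluster: fails spacing
        ("chr1", 5000, 50.0, 20, 10, 20, 10),
        ("chr1", 6000, 50.0, 20, 10, 20, 10),   # cluster: fails spacing
        ("chr1", 6002, 50.0, 20, 10, 20, 10),   # cluster: fails spacing
        ("chr1", 7000, 15.0, 20, 10, 20, 10),   # fails quality
        ("chr1", 8000, 50.0, 200, 100, 20, 10),  # fails depth (A depth 300)
        ("chr1", 9000, 50.0, 20, 10, 20, 10),
        ("chr1", 10000, 50.0, 20, 10, 20, 10),
    ]
    return make_sites(rows)
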