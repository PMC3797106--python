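import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    database=None,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def exhaustive_segmentation(y, k):
    """Independent oracle: global least-squares optimum by full enumeration.

    Returns (best_rss, best_breakpoints) minimizing the within-segment sum
    of squares over every placement of k breakpoints (1-based boundaries).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    best_rss, best_bps = np.inf, ()
    for bps in itertools.combinations(range(1, n), k):
        bounds = (0, *bps, n)
        rss = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg = y[a:b]
            rss += float(((seg - seg.mean()) ** 2).sum())
        if rss < best_rss - 1e-12:
            best_rss, best_bps = rss, bps
    return best_rss, best_bps


def segmentation_rss(y, bps):
    """Residual sum of squares of a given breakpoint placement."""
    y = np.asarray(y, dtype=float)
    bounds = (0, *[int(b) for b in bps], len(y))
    return sum(
        float(((y[a:b] - y[a:b].mean()) ** 2).sum())
        for a, b in zip(bounds[:-1], bounds[1:])
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
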