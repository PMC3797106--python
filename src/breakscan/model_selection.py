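"""Selection of the breakpoint number from a cost curve.

The final breakpoint number of each chromosome is chosen with the
Zhang-Siegmund modified Bayes information criterion (mBIC) for the Gaussian
mean-shift change-point model.  The screening round that precedes outlier
removal uses a deliberately liberal penalty instead (see
:func:`screening_criterion`).
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

#: Relative floor applied to rss[k] before taking logs, as a fraction of
#: rss[0] (i.e. of n * var(signal)); keeps noiseless toy signals finite.
RSS_FLOOR = 1e-12


class SelectionResult:
    """Chosen breakpoint number and the per-k criterion values."""

    __slots__ = ("k_selected", "criterion_values")

    def __init__(self, k_selected: int, criterion_values: np.ndarray):
        self.k_selected = int(k_selected)
        self.criterion_values = np.asarray(criterion_values, dtype=float)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SelectionResult(k_selected={self.k_selected})"


def _likelihood_gain(cost, k: int) -> float:
    """Profile Gaussian log-likelihood improvement of k breakpoints over none.

    With the common variance profiled out, the maximized log-likelihood of a
    segmentation with residual sum of squares RSS is
    -(n/2) log(RSS / n) + const, so the improvement over the single-segment
    model is (n/2) log(rss[0] / rss[k]).  rss[k] is floored at
    ``RSS_FLOOR * rss[0]`` so that exactly-fitting toy signals stay finite;
    an exactly constant signal (rss[0] = 0) has zero gain for every k.
    """
    rss0 = float(cost.rss[0])
    if rss0 <= 0.0:
        return 0.0
    floor = RSS_FLOOR * rss0
    rssk = float(cost.rss[k])
    if rssk < floor:
        logger.debug("rss[%d]=%g floored at %g for the likelihood term", k, rssk, floor)
        rssk = floor
    return 0.5 * cost.n * np.log(rss0 / rssk)


def mbic_criterion(cost, k: int) -> float:
    """Modified BIC of the optimal k-breakpoint segmentation (larger is better).

    The criterion approximates the log Bayes factor of the k-change-point
    Gaussian mean-shift model against the no-change model:

        mBIC(k) = (n/2) log(rss[0] / rss[k])
                  - (3k/2) log n
                  + (1/2) sum_{j=1}^{k+1} log(n_j / n)

    where ``n_j`` are the probe counts of the k+1 optimal segments.  The
    penalty structure follows the Laplace-approximation accounting for
    change-point models: each additional segment mean is a regular parameter
    ((1/2) log n apiece), while each change-point location is a discrete,
    non-regular parameter whose uniform prior over the n possible positions
    contributes a further log n -- hence (3/2) log n per breakpoint rather
    than the (2/2) log n that naive parameter counting would give.  The
    relative-segment-length term (always <= 0) penalizes uneven
    segmentations, most strongly those with very short segments, so the
    criterion prefers evenly spaced change points at equal fit.

    Because only the rss *ratio* enters, the criterion is invariant under
    shifting and positive rescaling of the signal; mBIC(0) = 0 by
    construction.
    """
    if not 0 <= k <= cost.k_max:
        raise ValueError(f"k={k} outside 0..{cost.k_max}")
    n = cost.n
    gain = _likelihood_gain(cost, k)
    lam = cost.segment_lengths(k) / n
    return gain - 1.5 * k * np.log(n) + 0.5 * float(np.sum(np.log(lam)))


def screening_criterion(cost, k: int) -> float:
    """Liberal selection criterion for the outlier-screening round.

    Uses the same profile-likelihood gain as the mBIC but charges only
    (1/2) log n per breakpoint and drops the segment-length term.  The
    screening round exists solely to flag probes that become singleton
    segments; over-segmentation here is harmless (non-singleton segments
    are discarded), while a missed singleton puts a spurious breakpoint
    pair into the final count.  The weak penalty therefore trades
    parsimony for sensitivity: isolating a probe still requires roughly a
    3.6-sigma excursion at n = 500, so false removals stay rare while
    genuine outlier spikes are caught reliably.
    """
    if not 0 <= k <= cost.k_max:
        raise ValueError(f"k={k} outside 0..{cost.k_max}")
    return _likelihood_gain(cost, k) - 0.5 * k * np.log(cost.n)


_CRITERIA = {"mbic": mbic_criterion, "screen": screening_criterion}


def select_k(cost, criterion: str = "mbic") -> SelectionResult:
    """Breakpoint number maximizing the chosen criterion; ties pick the smallest k."""
    try:
        crit = _CRITERIA[criterion]
    except KeyError:
        raise ValueError(
            f"unknown criterion {criterion!r}; choose from {sorted(_CRITERIA)}"
        ) from None
    values = np.array([crit(cost, k) for k in range(cost.k_max + 1)])
    return SelectionResult(int(np.argmax(values)), values)
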