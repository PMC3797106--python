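"""Exact least-squares change-point segmentation of copy-number signal.

A chromosome's normalized log-signal is modelled as piecewise constant with
homoscedastic Gaussian noise.  For every candidate number of breakpoints
``k`` up to ``k_max``, :func:`optimal_segmentation` recovers the global
minimum of the within-segment sum of squared deviations from segment means
by dynamic programming.  Two engines are provided:

``dp``
    the classical segment-neighbourhood dynamic program, vectorized over
    split points (O(k n^2) time, O(n^2) memory for the segment-cost table);
``pruned``
    functional pruning: the layer-``k`` cost is maintained as a piecewise
    quadratic function of the last segment's mean, and candidate change
    points whose quadratic never attains the lower envelope are discarded.
    This is the almost-linear-complexity formulation used by exact
    copy-number segmenters; it returns the identical optimum as ``dp``.

Whole tumors are processed by :func:`segment_tumor`: each chromosome
independently goes through a first segmentation round whose only purpose is
to discard outlier probes that land in singleton (length-1) segments, then
a final round whose breakpoint number is selected by the modified BIC.  The
genome-wide breakpoint count is the sum over chromosomes of (segments - 1),
so chromosome junctions are never counted as breakpoints.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import ProbeTrack, SegmentRecord
from .model_selection import select_k

logger = logging.getLogger(__name__)

#: Hard cap on probes per chromosome for the O(n^2) dp engine.
_DP_MAX_N = 20_000


@dataclass(frozen=True)
class CostCurve:
    """Optimal residual sums of squares and breakpoints for k = 0..k_max.

    ``breakpoints_per_k[k]`` holds the k optimal breakpoint positions as
    1-based boundaries: a breakpoint at ``i`` separates probe ``i`` from
    probe ``i + 1``, so admissible values lie in ``[1, n - 1]``.
    """

    n: int
    k_max: int
    rss: np.ndarray
    breakpoints_per_k: tuple

    def segment_lengths(self, k: int) -> np.ndarray:
        """Probe counts of the k + 1 segments of the optimal k-segmentation."""
        bounds = np.concatenate(([0], self.breakpoints_per_k[k], [self.n]))
        return np.diff(bounds)


@dataclass(frozen=True)
class OutlierReport:
    """Probes discarded by the first (screening) segmentation round.

    ``removed_probe_indices`` are 0-based indices into the original track;
    every removed probe formed a length-1 segment in the round-1 optimum.
    """

    removed_probe_indices: np.ndarray
    round1_k: int


@dataclass
class SegmentationParams:
    """Tunable knobs of the two-round segmentation.

    k_max defaults to ``min(ceil(n / 4), k_max_cap)`` per chromosome, far
    above breakpoint counts seen in practice while bounding runtime.  The
    final breakpoint number is selected by the modified BIC; the screening
    round uses a deliberately liberal penalty (see
    :func:`breakscan.model_selection.screening_criterion`).
    """

    k_max: int | None = None
    k_max_cap: int = 60
    k_max_frac: float = 0.25
    engine: str = "dp"
    round1_rule: str = "screen"
    selection_rule: str = "mbic"


@dataclass
class TumorProfile:
    """Per-tumor segmentation summary: segments and genome-wide breakpoint count."""

    tumor_id: str
    segments: list = field(default_factory=list)
    breakpoints_per_chromosome: dict = field(default_factory=dict)
    outliers: dict = field(default_factory=dict)
    breakpoint_count: int = 0
    risk_class: str | None = None

    @property
    def n_probes_removed(self) -> int:
        return sum(len(rep.removed_probe_indices) for rep in self.outliers.values())


def segment_cost_matrix(signal: np.ndarray) -> np.ndarray:
    """Sum of squared deviations from the mean for every probe interval.

    Returns C with ``C[i, j]`` the least-squares cost of one segment
    covering probes ``i..j`` (0-based inclusive); entries with ``i > j``
    are +inf.  Computed from cumulative sums after centring the signal,
    clipped at zero against catastrophic cancellation.
    """
    y = np.asarray(signal, dtype=np.float64)
    y = y - y.mean()  # location shift leaves all costs unchanged
    n = len(y)
    s1 = np.concatenate(([0.0], np.cumsum(y)))
    s2 = np.concatenate(([0.0], np.cumsum(y * y)))
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    length = j - i + 1
    with np.errstate(divide="ignore", invalid="ignore"):
        cost = (s2[j + 1] - s2[i]) - (s1[j + 1] - s1[i]) ** 2 / length
    cost = np.where(length >= 1, np.maximum(cost, 0.0), np.inf)
    return cost


def _dp_engine(y: np.ndarray, k_max: int):
    """Vectorized segment-neighbourhood DP; exact minimum for every k."""
    n = len(y)
    cost = segment_cost_matrix(y)
    rss = np.empty(k_max + 1)
    d_prev = cost[0].copy()  # D[0, j]: one segment covering 0..j
    rss[0] = d_prev[n - 1]
    last = np.zeros((k_max + 1, n), dtype=np.int64)
    d_layers = [d_prev]
    for k in range(1, k_max + 1):
        # candidate start s of the last segment: D[k, j] = min_s D[k-1, s-1] + C[s, j]
        cand = d_prev[: n - 1, None] + cost[1:, :]
        if k - 1 > 0:
            cand[: k - 1, :] = np.inf  # need at least k probes before s
        best = np.argmin(cand, axis=0)  # first occurrence = smallest split, deterministic
        d_new = cand[best, np.arange(n)]
        last[k] = best + 1
        rss[k] = d_new[n - 1]
        d_layers.append(d_new)
        d_prev = d_new
    breakpoints = _backtrack(last, n, k_max)
    return rss, breakpoints


def _backtrack(last: np.ndarray, n: int, k_max: int) -> tuple:
    out = [np.empty(0, dtype=np.int64)]
    for k in range(1, k_max + 1):
        bps = np.empty(k, dtype=np.int64)
        j = n - 1
        for kk in range(k, 0, -1):
            s = int(last[kk, j])
            bps[kk - 1] = s  # boundary after 1-based probe s
            j = s - 1
        out.append(bps)
    return tuple(out)


def _pruned_engine(y: np.ndarray, k_max: int):
    """Functional-pruning DP: identical optimum as the naive engine.

    The layer-k cost as a function of the current segment mean mu is a
    piecewise quadratic lower envelope; each piece remembers which last
    change point generated it.  Candidates are introduced as constants
    (their segment is empty at birth), the envelope is re-minimized, and
    every observation adds (y - mu)^2 to all pieces.
    """
    n = len(y)
    y = np.asarray(y, dtype=np.float64)
    mu_lo, mu_hi = float(y.min()) - 1.0, float(y.max()) + 1.0

    # D[0, t] directly from cumulative sums
    s1 = np.cumsum(y)
    s2 = np.cumsum(y * y)
    t_idx = np.arange(1, n + 1)
    d0 = s2 - s1**2 / t_idx
    dmat = np.full((k_max + 1, n), np.inf)
    dmat[0] = np.maximum(d0, 0.0)
    last = np.zeros((k_max + 1, n), dtype=np.int64)

    for k in range(1, k_max + 1):
        pieces: list = []  # [a, b, c, lo, hi, cand]
        for t in range(k, n):
            v = dmat[k - 1, t - 1]
            pieces = _introduce_constant(pieces, v, t, mu_lo, mu_hi)
            yt = y[t]
            for p in pieces:
                p[0] += 1.0
                p[1] -= 2.0 * yt
                p[2] += yt * yt
            best_val, best_cand = np.inf, 0
            for a, b, c, lo, hi, cand in pieces:
                if a > 0:
                    mu = -b / (2.0 * a)
                    if lo <= mu <= hi:
                        val = c - b * b / (4.0 * a)
                    else:
                        val = min(a * lo * lo + b * lo + c, a * hi * hi + b * hi + c)
                else:
                    val = c
                if val < best_val:
                    best_val, best_cand = val, cand
            dmat[k, t] = max(best_val, 0.0)
            last[k, t] = best_cand
    rss = dmat[:, n - 1]
    breakpoints = _backtrack(last, n, k_max)
    return rss, breakpoints


def _introduce_constant(pieces, v, cand, mu_lo, mu_hi):
    """Min-envelope of the current pieces with the constant function v."""
    if not np.isfinite(v):
        return pieces
    if not pieces:
        return [[0.0, 0.0, v, mu_lo, mu_hi, cand]]
    out: list = []

    def push_const(lo, hi):
        if hi - lo <= 0:
            return
        if out and out[-1][5] == cand and out[-1][0] == 0.0 and out[-1][4] == lo:
            out[-1][4] = hi  # merge adjacent constant pieces
        else:
            out.append([0.0, 0.0, v, lo, hi, cand])

    for a, b, c, lo, hi, pc in pieces:
        # q(mu) - v = a mu^2 + b mu + (c - v); a >= 1 for established pieces
        disc = b * b - 4.0 * a * (c - v)
        if disc <= 0:  # q >= v on the whole real line
            push_const(lo, hi)
            continue
        root = np.sqrt(disc)
        r1 = (-b - root) / (2.0 * a)
        r2 = (-b + root) / (2.0 * a)
        keep_lo, keep_hi = max(lo, r1), min(hi, r2)
        if keep_hi <= keep_lo:  # q >= v on [lo, hi)
            push_const(lo, hi)
            continue
        push_const(lo, keep_lo)
        out.append([a, b, c, keep_lo, keep_hi, pc])
        push_const(keep_hi, hi)
    return out


def optimal_segmentation(
    signal, k_max: int | None = None, engine: str = "dp"
) -> CostCurve:
    """Globally optimal least-squares segmentations for k = 0..k_max breakpoints.

    Parameters
    ----------
    signal : array-like
        Ordered, finite log-scale probe signal of one chromosome (n >= 2).
    k_max : int, optional
        Largest breakpoint number considered.  Defaults to
        ``min(ceil(n / 4), 60)``; values >= n are capped at n - 1 with a
        warning.
    engine : {"dp", "pruned"}
        Exact engines that return the identical optimum (see module
        docstring).

    Returns
    -------
    CostCurve
        For every k the global-minimum residual sum of squares and the
        optimal breakpoint boundaries.  Ties between optimal placements are
        broken deterministically towards the smallest split index.
    """
    y = np.asarray(signal, dtype=np.float64)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("signal must be 1-D with at least 2 probes")
    if not np.all(np.isfinite(y)):
        raise ValueError("signal must be finite (filter non-finite probes on load)")
    n = len(y)
    if k_max is None:
        k_max = min(int(np.ceil(n / 4)), 60)
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    if k_max >= n:
        warnings.warn(f"k_max={k_max} >= n={n}; capped at n-1", stacklevel=2)
        k_max = n - 1
    if engine == "dp":
        if n > _DP_MAX_N:
            raise ValueError(
                f"n={n} exceeds the dp engine limit ({_DP_MAX_N}); use engine='pruned'"
            )
        rss, bps = _dp_engine(y, k_max)
    elif engine == "pruned":
        rss, bps = _pruned_engine(y, k_max)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return CostCurve(n=n, k_max=k_max, rss=rss, breakpoints_per_k=bps)


def remove_singleton_outliers(
    track: ProbeTrack, params: SegmentationParams | None = None
):
    """First segmentation round: drop probes that form singleton segments.

    The track is segmented once, the round-1 breakpoint number is selected
    by the (liberal) screening rule in ``params.round1_rule``, and every
    probe sitting alone in a length-1 segment of that optimum is discarded.
    All other probes are retained in order.

    Returns the cleaned track and an :class:`OutlierReport`.  Raises if the
    removal would leave fewer than two probes (a pathological all-singleton
    segmentation that calls for a parameter review).
    """
    params = params or SegmentationParams()
    cost = optimal_segmentation(
        track.signal, k_max=params.k_max, engine=params.engine
    )
    k1 = select_k(cost, criterion=params.round1_rule).k_selected
    lengths = cost.segment_lengths(k1)
    bounds = np.concatenate(([0], cost.breakpoints_per_k[k1]))
    removed = bounds[lengths == 1]  # 0-based index of each singleton probe
    keep = np.setdiff1d(np.arange(track.n_probes), removed)
    if len(keep) < 2:
        raise RuntimeError(
            f"tumor {track.tumor_id} chrom {track.chromosome}: singleton removal "
            "would leave <2 probes; review segmentation parameters"
        )
    cleaned = ProbeTrack(
        tumor_id=track.tumor_id,
        chromosome=track.chromosome,
        positions=track.positions[keep],
        signal=track.signal[keep],
    )
    report = OutlierReport(
        removed_probe_indices=np.asarray(removed, dtype=np.int64), round1_k=int(k1)
    )
    return cleaned, report


def segment_tumor(tracks, params: SegmentationParams | None = None) -> TumorProfile:
    """Two-round segmentation of all chromosomes of one tumor.

    Each chromosome independently passes round 1 (singleton-outlier
    removal) and round 2 (optimal segmentation with modified-BIC selection
    of the breakpoint number).  The genome-wide breakpoint count is the sum
    of per-chromosome breakpoint numbers; chromosome boundaries are never
    counted.  Chromosomes with fewer than two retained probes contribute
    zero breakpoints with a warning.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("segment_tumor requires at least one chromosome track")
    tumor_ids = {t.tumor_id for t in tracks}
    if len(tumor_ids) != 1:
        raise ValueError(f"tracks belong to multiple tumors: {sorted(tumor_ids)}")
    params = params or SegmentationParams()
    profile = TumorProfile(tumor_id=tracks[0].tumor_id)

    for track in tracks:
        chrom = track.chromosome
        if track.n_probes < 2:
            logger.warning(
                "tumor %s chrom %s: <2 probes, contributes 0 breakpoints",
                track.tumor_id,
                chrom,
            )
            profile.breakpoints_per_chromosome[chrom] = 0
            continue
        try:
            cleaned, report = remove_singleton_outliers(track, params)
        except RuntimeError as exc:
            logger.warning("%s; chromosome contributes 0 breakpoints", exc)
            profile.breakpoints_per_chromosome[chrom] = 0
            continue
        profile.outliers[chrom] = report
        cost = optimal_segmentation(
            cleaned.signal, k_max=params.k_max, engine=params.engine
        )
        k2 = select_k(cost, criterion=params.selection_rule).k_selected
        profile.breakpoints_per_chromosome[chrom] = int(k2)
        bounds = np.concatenate(([0], cost.breakpoints_per_k[k2], [cleaned.n_probes]))
        prev_end_bp = None
        for start, end in zip(bounds[:-1], bounds[1:]):
            # segments tile the probed interval: the boundary sits right after
            # the last probe of the left segment
            start_bp = (
                int(cleaned.positions[start]) if prev_end_bp is None else prev_end_bp + 1
            )
            prev_end_bp = int(cleaned.positions[end - 1])
            profile.segments.append(
                SegmentRecord(
                    chromosome=chrom,
                    start_probe_index=int(start) + 1,
                    end_probe_index=int(end),
                    start_bp=start_bp,
                    end_bp=prev_end_bp,
                    mean_signal=float(cleaned.signal[start:end].mean()),
                )
            )
    profile.breakpoint_count = int(sum(profile.breakpoints_per_chromosome.values()))
    return profile
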