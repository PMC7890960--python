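"""Histogram-based threshold selection.

All automated selectors operate on an intensity :class:`Histogram` and
evaluate their criterion exhaustively at every cut point between bins, so
each is exactly the maximizer (or minimizer) of its criterion — no
stochastic optimization.  Thresholds are reported as bin *lower edges* in
original intensity units, the "lower threshold" convention selects values
``>= t`` (bright nuclear structures are foreground), and ties are broken
toward the lowest qualifying edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .core import BinaryMask, LabelMap, Spacing

__all__ = [
    "Histogram",
    "ThresholdResult",
    "build_histogram",
    "otsu",
    "multi_otsu",
    "renyi_entropy_threshold",
    "shanbhag_threshold",
    "apply_threshold",
    "range_threshold",
    "classify_multilevel",
    "THRESHOLD_METHODS",
    "select_threshold",
]


@dataclass(frozen=True)
class Histogram:
    """Intensity histogram: ``n+1`` ascending bin edges and ``n`` counts.

    The rightmost bin is closed (the maximum value belongs to the last bin).
    """

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)
        if edges.ndim != 1 or counts.ndim != 1 or len(edges) != len(counts) + 1:
            raise ValueError("shape mismatch: need n+1 edges for n counts")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly ascending")
        if counts.min(initial=0) < 0:
            raise ValueError("negative counts")
        if counts.sum() <= 0:
            raise ValueError("degenerate histogram: no counts")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.counts))


@dataclass(frozen=True)
class ThresholdResult:
    """One or more ascending thresholds plus provenance of their selection."""

    thresholds: tuple[float, ...]
    method: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ts = tuple(float(t) for t in self.thresholds)
        object.__setattr__(self, "thresholds", ts)
        if len(ts) < 1:
            raise ValueError("need at least one threshold")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError(f"thresholds not strictly ascending: {ts}")

    @property
    def single(self) -> float:
        if len(self.thresholds) != 1:
            raise ValueError(
                f"multi-threshold result: {len(self.thresholds)} thresholds, expected 1"
            )
        return self.thresholds[0]


DEFAULT_FLOAT_BINS = 1024
MAX_INTEGER_RANGE = 65536


def build_histogram(
    channel: np.ndarray,
    n_bins: int | None = None,
    mask: BinaryMask | np.ndarray | None = None,
) -> Histogram:
    """Histogram of a single channel, optionally restricted to a mask.

    Integer images whose value range fits get one exact bin per integer
    value (edge ``v`` .. ``v+1`` covers exactly value ``v``, so thresholds
    are integers); float images get ``n_bins`` equal-width bins spanning
    [min, max] with the rightmost bin closed.
    """
    values = np.asarray(channel)
    if mask is not None:
        member = mask.member if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
        if member.shape != values.shape:
            raise ValueError(f"shape mismatch: mask {member.shape} vs channel {values.shape}")
        values = values[member]
    values = values.ravel()
    if values.size == 0:
        raise ValueError("empty selection: mask excludes every voxel")
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        raise ValueError(f"degenerate histogram: all selected voxels equal {vmin}")
    integral = np.issubdtype(values.dtype, np.integer)
    per_value_cap = MAX_INTEGER_RANGE if n_bins is None else n_bins
    if n_bins is None:
        n_bins = DEFAULT_FLOAT_BINS
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    if integral and (span := int(vmax) - int(vmin) + 1) <= per_value_cap:
        edges = np.arange(int(vmin), int(vmax) + 2, dtype=float)
        counts = np.bincount((values - vmin).astype(np.int64), minlength=span)
    else:
        counts, edges = np.histogram(values.astype(float), bins=n_bins)
    return Histogram(edges, counts)


def _check_nondegenerate(hist: Histogram) -> None:
    if hist.n_occupied() < 2:
        raise ValueError("degenerate histogram: fewer than two occupied bins")


def _cut_points(hist: Histogram) -> np.ndarray:
    """Valid cut indices t (background bins [0,t), foreground [t,n)).

    Cuts that differ only across empty bins induce identical class
    partitions; the lowest-edge tie rule picks the representative
    immediately after an occupied bin, so only those cuts are searched.
    """
    ts = 1 + np.flatnonzero(hist.counts[:-1] > 0)
    return ts


# ---------------------------------------------------------------------------
# Otsu family: maximize between-class variance.
# ---------------------------------------------------------------------------


def _class_stats(hist: Histogram):
    """Prefix sums of weight and weighted intensity over bins."""
    w = hist.counts.astype(float)
    c = hist.centers
    W = np.concatenate([[0.0], np.cumsum(w)])
    S = np.concatenate([[0.0], np.cumsum(w * c)])
    return W, S


def _between_class_objective(W: np.ndarray, S: np.ndarray, cuts: tuple[int, ...], n: int) -> float:
    """sum_c S_c^2 / W_c over the classes induced by the cut vector.

    Equivalent (up to an additive constant) to the total between-class
    variance; -inf when any class is empty.
    """
    bounds = (0,) + tuple(cuts) + (n,)
    total = 0.0
    for a, b in zip(bounds, bounds[1:]):
        wc = W[b] - W[a]
        if wc <= 0:
            return -math.inf
        sc = S[b] - S[a]
        total += sc * sc / wc
    return total


# Exhaustive search is exact; fall back to dynamic programming only when the
# number of cut combinations would be unreasonable.
_BRUTE_FORCE_LIMIT = 400_000


def multi_otsu(hist: Histogram, n_classes: int) -> ThresholdResult:
    """k-class Otsu: k-1 thresholds maximizing total between-class variance.

    Exact search (exhaustive for tractable sizes, dynamic programming
    otherwise); ties resolve to the lexicographically smallest threshold
    vector.
    """
    if not 2 <= n_classes <= 8:
        raise ValueError(f"n_classes must be in 2..8, got {n_classes}")
    if hist.n_occupied() < n_classes:
        raise ValueError(
            f"insufficient distinct values: {hist.n_occupied()} occupied bins for {n_classes} classes"
        )
    W, S = _class_stats(hist)
    n = hist.n_bins
    k = n_classes
    cuts_range = _cut_points(hist)
    if k == 2 or math.comb(len(cuts_range), k - 1) <= _BRUTE_FORCE_LIMIT:
        best: tuple[int, ...] | None = None
        best_val = -math.inf
        # combinations() yields cut vectors in lexicographic order; strict >
        # therefore keeps the lexicographically smallest maximizer.
        for cuts in combinations(cuts_range.tolist(), k - 1):
            val = _between_class_objective(W, S, cuts, n)
            if val > best_val:
                best_val = val
                best = cuts
    else:
        best = _multi_otsu_dp(W, S, n, k)
        best_val = _between_class_objective(W, S, best, n)
    if best is None or not math.isfinite(best_val):
        raise ValueError("insufficient distinct values: no valid class partition")
    thresholds = tuple(float(hist.bin_edges[t]) for t in best)
    return ThresholdResult(thresholds, "multi_otsu", {"n_classes": k})


def _multi_otsu_dp(W: np.ndarray, S: np.ndarray, n: int, k: int) -> tuple[int, ...]:
    """O(k n^2) dynamic program over class boundaries (large-histogram
    fallback; may return a non-canonical member of a tied cut class)."""

    def val(a: int, b: int) -> float:
        wc = W[b] - W[a]
        if wc <= 0:
            return -math.inf
        sc = S[b] - S[a]
        return sc * sc / wc

    # dp[c][j]: best objective for c classes covering bins [0, j)
    dp = [[-math.inf] * (n + 1) for _ in range(k + 1)]
    back = [[0] * (n + 1) for _ in range(k + 1)]
    for j in range(1, n + 1):
        dp[1][j] = val(0, j)
    for c in range(2, k + 1):
        for j in range(c, n + 1):
            for s in range(c - 1, j):
                cand = dp[c - 1][s] + val(s, j)
                if cand > dp[c][j]:
                    dp[c][j] = cand
                    back[c][j] = s
    cuts = []
    j = n
    for c in range(k, 1, -1):
        j = back[c][j]
        cuts.append(j)
    return tuple(reversed(cuts))


def otsu(hist: Histogram) -> ThresholdResult:
    """Single Otsu threshold (the 2-class case of :func:`multi_otsu`)."""
    _check_nondegenerate(hist)
    result = multi_otsu(hist, 2)
    return ThresholdResult(result.thresholds, "otsu", {})


# ---------------------------------------------------------------------------
# Entropy criteria.
# ---------------------------------------------------------------------------


def renyi_entropy_threshold(hist: Histogram, alpha: float = 2.0) -> ThresholdResult:
    """Threshold maximizing the summed Rényi entropies of the two classes.

    For class probabilities p_i (normalized within the class),
    ``H_a = ln(sum p_i^a) / (1 - a)``; ``alpha=1`` is handled as the
    Shannon limit (the Kapur maximum-entropy threshold).
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    _check_nondegenerate(hist)
    w = hist.counts.astype(float)
    n = hist.n_bins
    Wc = np.concatenate([[0.0], np.cumsum(w)])
    cuts = _cut_points(hist)
    w0 = Wc[cuts]
    w1 = Wc[n] - w0
    valid = (w0 > 0) & (w1 > 0)
    if alpha == 1.0:
        with np.errstate(divide="ignore", invalid="ignore"):
            e = np.where(w > 0, w * np.log(w), 0.0)
        Ec = np.concatenate([[0.0], np.cumsum(e)])
        # Shannon entropy of a class = ln W_c - E_c / W_c
        with np.errstate(divide="ignore", invalid="ignore"):
            h0 = np.log(w0) - Ec[cuts] / w0
            h1 = np.log(w1) - (Ec[n] - Ec[cuts]) / w1
    else:
        a = w**alpha
        Ac = np.concatenate([[0.0], np.cumsum(a)])
        with np.errstate(divide="ignore", invalid="ignore"):
            # ln(sum (c_i/W)^a) / (1-a) = (ln A_c - a ln W_c) / (1-a)
            h0 = (np.log(Ac[cuts]) - alpha * np.log(w0)) / (1.0 - alpha)
            h1 = (np.log(Ac[n] - Ac[cuts]) - alpha * np.log(w1)) / (1.0 - alpha)
    crit = np.where(valid, h0 + h1, -np.inf)
    t = int(cuts[np.argmax(crit)])
    return ThresholdResult(
        (float(hist.bin_edges[t]),), "renyi", {"alpha": alpha}
    )


def shanbhag_threshold(hist: Histogram) -> ThresholdResult:
    """Shanbhag's fuzzy-membership information threshold.

    Each class weights its bins by a cumulative fuzzy membership that is 1
    far from the threshold and approaches 1/2 at it; the threshold
    minimizes the absolute difference of the two class information
    measures.
    """
    _check_nondegenerate(hist)
    p = hist.counts.astype(float)
    p = p / p.sum()
    n = hist.n_bins
    P = np.concatenate([[0.0], np.cumsum(p)])  # P[i] = sum of bins < i
    best_t = -1
    best_val = math.inf
    for t in _cut_points(hist):
        w0 = P[t]
        w1 = 1.0 - w0
        if w0 <= 0 or w1 <= 0:
            continue
        # background bins i in [0, t): membership 1 - P(<i) / (2 w0)
        i = np.arange(t)
        mu_b = 1.0 - P[i] / (2.0 * w0)
        ent_back = -np.sum(p[i] * np.log(mu_b)) / (2.0 * w0)
        # foreground bins i in [t, n): membership 1 - P(>i) / (2 w1)
        j = np.arange(t, n)
        tail = 1.0 - P[j + 1]  # sum of bins > j
        mu_f = 1.0 - tail / (2.0 * w1)
        ent_obj = -np.sum(p[j] * np.log(mu_f)) / (2.0 * w1)
        val = abs(ent_back - ent_obj)
        if val < best_val:
            best_val = val
            best_t = int(t)
    if best_t < 0:
        raise ValueError("degenerate histogram: no valid cut point")
    return ThresholdResult((float(hist.bin_edges[best_t]),), "shanbhag", {})


# ---------------------------------------------------------------------------
# Applying thresholds.
# ---------------------------------------------------------------------------


def apply_threshold(
    channel: np.ndarray,
    result: ThresholdResult,
    direction: str = "lower",
    spacing: Spacing | None = None,
) -> BinaryMask:
    """Binarize a channel with a single threshold.

    ``lower`` keeps values >= t (bright foreground); ``upper`` keeps
    values <= t.
    """
    t = result.single
    if direction == "lower":
        member = np.asarray(channel) >= t
    elif direction == "upper":
        member = np.asarray(channel) <= t
    else:
        raise ValueError(f"direction must be 'lower' or 'upper', got {direction!r}")
    return BinaryMask(member, spacing if spacing is not None else DEFAULT_UNIT_SPACING)


def range_threshold(
    channel: np.ndarray,
    low: float,
    high: float,
    spacing: Spacing | None = None,
) -> BinaryMask:
    """Keep values in [low, high]; excludes both dim background staining and
    saturated voxels."""
    if low > high:
        raise ValueError(f"inverted range: low {low} > high {high}")
    arr = np.asarray(channel)
    member = (arr >= low) & (arr <= high)
    return BinaryMask(member, spacing if spacing is not None else DEFAULT_UNIT_SPACING)


def classify_multilevel(
    channel: np.ndarray,
    result: ThresholdResult,
    spacing: Spacing | None = None,
) -> LabelMap:
    """Assign each voxel the index of its inter-threshold interval.

    Class 0 (background) is below the first threshold; class c >= 1 means
    ``t_c <= value < t_{c+1}``.  Note the classes are intensity levels, not
    connected components.
    """
    arr = np.asarray(channel)
    ts = np.asarray(result.thresholds)
    classes = np.searchsorted(ts, arr, side="right").astype(np.int32)
    # Every class in 0..k-1 need not occur; LabelMap requires consecutive
    # labels, so relabel occupied classes consecutively while keeping order.
    present = np.unique(classes)
    present = present[present > 0]
    lut = np.zeros(len(ts) + 1, dtype=np.int32)
    lut[present] = np.arange(1, len(present) + 1)
    return LabelMap(
        lut[classes], spacing if spacing is not None else DEFAULT_UNIT_SPACING
    )


DEFAULT_UNIT_SPACING = Spacing(1.0, 1.0, 1.0)


def select_threshold(
    channel: np.ndarray,
    method: str,
    mask: BinaryMask | np.ndarray | None = None,
    n_bins: int | None = None,
    **params,
) -> ThresholdResult:
    """Select a threshold by registry name on a channel's histogram."""
    if method == "manual":
        return ThresholdResult((float(params["threshold"]),), "manual", dict(params))
    if method == "range":
        low, high = float(params["low"]), float(params["high"])
        if low > high:
            raise ValueError(f"inverted range: low {low} > high {high}")
        return ThresholdResult((low, high), "range", dict(params))
    try:
        selector = THRESHOLD_METHODS[method]
    except KeyError:
        raise ValueError(f"unknown threshold method {method!r}") from None
    hist = build_histogram(channel, n_bins=n_bins, mask=mask)
    return selector(hist, **params)


#: Histogram-based selectors addressable from profile JSON.
THRESHOLD_METHODS = {
    "otsu": otsu,
    "multi_otsu": multi_otsu,
    "renyi": renyi_entropy_threshold,
    "shanbhag": shanbhag_threshold,
}
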