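"""All-pairs association: Pearson correlation and the Maximal Information
Coefficient (MIC).

The MIC estimator follows the MINE scheme: for a pair (x, y) and a grid
budget B(n) = max(n^alpha, 4), the y-axis is equipartitioned into l rows
(ties never split); candidate x-axis partitions are restricted to clump
boundaries (superclumps cap their number at c * k_max) and optimized by
dynamic programming over bin counts k with k * l <= B; each grid's mutual
information is normalized by log2(min(k, l)); both orientations are computed
and the overall maximum taken, so MIC is symmetric by construction.

At very small n — exactly the regime where MIC is least trustworthy and the
equipartition heuristic can sit far from the optimal grid — the admissible
grid space is tiny, so the estimator switches to exhaustive enumeration of
all admissible grids (identical to the verification oracle) instead of the
DP approximation; the crossover is ``MicParams.small_n_exact_threshold``.
An exhaustive small-n oracle (all axis partitions enumerated) verifies the
approximation in tests.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from numba import njit

from .blocks import FusedMatrix, ValidationError

log = logging.getLogger(__name__)


class SmallSampleWarning(UserWarning):
    """MIC on fewer than ~30 points can report spurious dependence."""


@dataclass(frozen=True)
class MicParams:
    """MIC hyperparameters (canonical MINE defaults)."""

    alpha: float = 0.6
    clump_factor: int = 15
    min_pairwise_n: int = 8
    small_n_warning_threshold: int = 30
    small_n_exact_threshold: int = 16

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValidationError("alpha must lie in (0, 1]")
        if self.clump_factor < 1:
            raise ValidationError("clump_factor must be a positive integer")

    def budget(self, n: int) -> float:
        """Grid budget B(n); floored at 4 so a 2x2 grid is always admissible."""
        return max(float(n) ** self.alpha, 4.0)


# ---------------------------------------------------------------------------
# numba kernels

@njit(cache=True)
def _equipartition(sorted_vals, n_rows):
    """Assign sorted values to ~equal rows, never splitting ties.

    Returns (row assignment over the sorted order, actual number of rows).
    """
    n = len(sorted_vals)
    rows = np.empty(n, dtype=np.int64)
    i = 0
    curr = 0
    assigned = 0
    desired = n / n_rows
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        size = j - i
        if (assigned != 0 and curr + 1 < n_rows
                and abs(assigned + size - desired) >= abs(assigned - desired)):
            curr += 1
            assigned = 0
            desired = (n - i) / (n_rows - curr)
        for k in range(i, j):
            rows[k] = curr
        assigned += size
        i = j
    return rows, curr + 1


@njit(cache=True)
def _clump_ids(xs_sorted, rows_xorder):
    """Clump id per point (x-sorted): maximal runs sharing one y-row; x ties
    are atomic, and a tie group spanning several rows is its own clump."""
    n = len(xs_sorted)
    out = np.empty(n, dtype=np.int64)
    c = -1
    prev_row = -1
    prev_ok = False
    i = 0
    while i < n:
        j = i
        while j < n and xs_sorted[j] == xs_sorted[i]:
            j += 1
        homogeneous = True
        for k in range(i + 1, j):
            if rows_xorder[k] != rows_xorder[i]:
                homogeneous = False
                break
        if not (homogeneous and prev_ok and rows_xorder[i] == prev_row):
            c += 1
        for k in range(i, j):
            out[k] = c
        prev_ok = homogeneous
        prev_row = rows_xorder[i] if homogeneous else -1
        i = j
    return out, c + 1


@njit(cache=True)
def _optimize_axis(cum, crows, k_max, n_rows, h_q, n):
    """DP over clump boundaries: best I(P;Q) for each number of x bins.

    ``cum``: cumulative point counts at clump boundaries (len m+1);
    ``crows``: cumulative per-row counts at the same boundaries.
    Returns I values indexed by k (0 for k < 2 or k > m).
    """
    m = len(cum) - 1
    kk = min(k_max, m)
    F = np.full((m + 1, kk + 1), -np.inf)

    for t in range(1, m + 1):
        cnt = cum[t] - cum[0]
        s0 = 0.0
        for r in range(n_rows):
            nr = crows[t, r] - crows[0, r]
            if nr > 0:
                s0 += nr * math.log2(nr / cnt)
        F[t, 1] = s0 / n

    for k in range(2, kk + 1):
        for t in range(k, m + 1):
            best = -np.inf
            for s in range(k - 1, t):
                if F[s, k - 1] == -np.inf:
                    continue
                cnt = cum[t] - cum[s]
                contrib = 0.0
                for r in range(n_rows):
                    nr = crows[t, r] - crows[s, r]
                    if nr > 0:
                        contrib += nr * math.log2(nr / cnt)
                v = F[s, k - 1] + contrib / n
                if v > best:
                    best = v
            F[t, k] = best

    out = np.zeros(k_max + 1)
    for k in range(2, kk + 1):
        if F[m, k] > -np.inf:
            out[k] = h_q + F[m, k]
    return out


@njit(cache=True)
def _orientation_max(xs_sorted, ys_xorder, y_sorted, budget, clump_factor):
    """Max normalized I over grids for one orientation (x optimized, y
    equipartitioned)."""
    n = len(xs_sorted)
    best = 0.0
    max_l = int(budget / 2.0)
    for l in range(2, max_l + 1):
        rows_sorted, n_rows = _equipartition(y_sorted, l)
        if n_rows < 2:
            continue
        # thresholds: row of a point = row of its value in the sorted order
        # build value->row via the sorted arrays
        k_max = int(budget / n_rows)
        if k_max < 2:
            continue
        # map each x-ordered point's y value to its row
        rows_xorder = np.empty(n, dtype=np.int64)
        for i in range(n):
            v = ys_xorder[i]
            lo, hi = 0, n - 1
            while lo < hi:
                mid = (lo + hi) // 2
                if y_sorted[mid] < v:
                    lo = mid + 1
                else:
                    hi = mid
            rows_xorder[i] = rows_sorted[lo]
        # entropy of the y partition
        h_q = 0.0
        for r in range(n_rows):
            nr = 0
            for i in range(n):
                if rows_xorder[i] == r:
                    nr += 1
            if nr > 0:
                h_q -= (nr / n) * math.log2(nr / n)
        clumps, n_clumps = _clump_ids(xs_sorted, rows_xorder)
        k_hat = max(clump_factor * k_max, 2)
        if n_clumps > k_hat:
            sc, n_clumps = _equipartition(clumps.astype(np.float64), k_hat)
            clumps = sc
        # cumulative boundaries
        cum = np.zeros(n_clumps + 1, dtype=np.int64)
        crows = np.zeros((n_clumps + 1, n_rows), dtype=np.int64)
        for i in range(n):
            cum[clumps[i] + 1] += 1
            crows[clumps[i] + 1, rows_xorder[i]] += 1
        for t in range(1, n_clumps + 1):
            cum[t] += cum[t - 1]
            for r in range(n_rows):
                crows[t, r] += crows[t - 1, r]
        ivals = _optimize_axis(cum, crows, k_max, n_rows, h_q, n)
        for k in range(2, k_max + 1):
            if k * n_rows > budget:
                break
            denom = math.log2(min(k, n_rows))
            v = ivals[k] / denom
            if v > best:
                best = v
    return best


# ---------------------------------------------------------------------------
# public API

def pearson(x, y) -> float:
    """Sample Pearson r on pairwise-complete observations; NaN (with a
    warning) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    both = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[both], y[both]
    if len(x) < 3:
        raise ValidationError("need at least 3 pairwise-complete observations")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        log.warning("constant vector in Pearson computation; returning missing")
        return float("nan")
    r = float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
    return max(-1.0, min(1.0, r))


def _mic_clean(x, y, params: MicParams) -> tuple[np.ndarray, np.ndarray] | None:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    both = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[both], y[both]
    if len(x) < params.min_pairwise_n:
        log.info("MIC skipped: only %d pairwise-complete observations", len(x))
        return None
    if np.all(x == x[0]) or np.all(y == y[0]):
        log.warning("constant vector in MIC computation; returning missing")
        return None
    if len(x) < params.small_n_warning_threshold:
        warnings.warn(
            f"MIC computed on n={len(x)} < {params.small_n_warning_threshold} points; "
            "values may be inflated", SmallSampleWarning, stacklevel=3)
    return x, y


def mic_approx(x, y, params: MicParams | None = None) -> float:
    """MIC via the MINE dynamic-programming approximation; in [0, 1]."""
    params = params or MicParams()
    cleaned = _mic_clean(x, y, params)
    if cleaned is None:
        return float("nan")
    x, y = cleaned
    return _mic_approx_arrays(x, y, params)


def _mic_approx_arrays(x: np.ndarray, y: np.ndarray, params: MicParams) -> float:
    n = len(x)
    budget = params.budget(n)
    if n <= params.small_n_exact_threshold:
        # grid space is tiny: enumerate it exactly instead of approximating;
        # canonical argument order keeps the result bit-identical under swap
        if x.tobytes() > y.tobytes():
            x, y = y, x
        return _mic_exhaustive(x, y, budget, max_axis=max(2, int(budget / 2)))
    ox = np.argsort(x, kind="stable")
    oy = np.argsort(y, kind="stable")
    xs, ys_x = x[ox], y[ox]
    ys, xs_y = y[oy], x[oy]
    a = _orientation_max(xs, ys_x, ys, budget, params.clump_factor)
    b = _orientation_max(ys, xs_y, xs, budget, params.clump_factor)
    return float(min(max(a, b), 1.0))


def _partition_assignments(values: np.ndarray, n_bins: int):
    """All assignments of sorted values into n_bins ordered, nonempty bins,
    with cuts only between distinct values (ties inseparable)."""
    order = np.argsort(values, kind="stable")
    sv = values[order]
    gaps = [i for i in range(1, len(sv)) if sv[i] != sv[i - 1]]
    for cuts in combinations(gaps, n_bins - 1):
        bins = np.zeros(len(sv), dtype=np.int64)
        for b, cut in enumerate(cuts):
            bins[cut:] = b + 1
        out = np.empty(len(sv), dtype=np.int64)
        out[order] = bins
        yield out


def mic_exact_oracle(x, y, params: MicParams | None = None,
                     max_n: int = 12, max_axis: int = 4) -> float:
    """Exact MIC by exhaustive enumeration of every admissible grid
    (k, l <= max_axis, k*l <= B(n)); verification oracle for small n."""
    params = params or MicParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    n = len(x)
    if n > max_n:
        raise ValidationError(f"oracle limited to n <= {max_n}")
    if n < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("oracle requires nonconstant x and y")
    return _mic_exhaustive(x, y, params.budget(n), max_axis)


def _mic_exhaustive(x: np.ndarray, y: np.ndarray, budget: float,
                    max_axis: int) -> float:
    n = len(x)
    best = 0.0
    for k in range(2, max_axis + 1):
        for l in range(2, max_axis + 1):
            if k * l > budget:
                continue
            y_parts = list(_partition_assignments(y, l))
            for xb in _partition_assignments(x, k):
                for yb in y_parts:
                    table = np.zeros((k, l))
                    np.add.at(table, (xb, yb), 1.0)
                    p = table / n
                    px = p.sum(axis=1)
                    py = p.sum(axis=0)
                    nz = p > 0
                    mi = float((p[nz] * np.log2(p[nz] / np.outer(px, py)[nz])).sum())
                    v = mi / math.log2(min(k, l))
                    if v > best:
                        best = v
    return min(best, 1.0)


def all_pairs(fused: FusedMatrix, params: MicParams | None = None) -> pd.DataFrame:
    """Pearson r and MIC for every unordered row pair of the fused matrix.

    Returns the pair table (one row per pair, in row-index order) with
    columns feature_a, platform_a, feature_b, platform_b, n_used, pearson_r,
    mic and weight = max(|pearson_r|, mic).
    """
    params = params or MicParams()
    if fused.n_features < 2:
        raise ValidationError("need at least 2 rows for all-pairs analysis")
    mat = fused.values.to_numpy(dtype=float)
    feats = list(fused.values.index)
    plats = fused.platforms.to_numpy()
    finite = ~np.isnan(mat)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("once", SmallSampleWarning)
        for i in range(len(feats)):
            for j in range(i + 1, len(feats)):
                both = finite[i] & finite[j]
                n_used = int(both.sum())
                xi, yj = mat[i, both], mat[j, both]
                r = float("nan")
                mic = float("nan")
                if n_used >= 3 and xi.std() > 0 and yj.std() > 0:
                    sx = (xi - xi.mean()) / xi.std()
                    sy = (yj - yj.mean()) / yj.std()
                    r = float(np.clip((sx * sy).mean(), -1.0, 1.0))
                    if n_used >= params.min_pairwise_n:
                        mic = _mic_approx_arrays(xi, yj, params)
                weight = np.nanmax([abs(r), mic]) if not (
                    np.isnan(r) and np.isnan(mic)) else float("nan")
                rows.append((feats[i], plats[i], feats[j], plats[j],
                             n_used, r, mic, weight))
    return pd.DataFrame(rows, columns=["feature_a", "platform_a", "feature_b",
                                       "platform_b", "n_used", "pearson_r",
                                       "mic", "weight"])
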