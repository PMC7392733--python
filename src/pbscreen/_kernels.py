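"""Numba inner loops for Gaussian kernel convolution and the Monte-Carlo null.

Everything here operates on one chromosome at a time with plain int64/float64
arrays; orchestration, seeding policy and DataFrame plumbing live in
:mod:`pbscreen.gkc`.
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def gauss_heights_exact(pos, w, grid, h):
    """Exact unnormalized Gaussian kernel sum: f(g) = sum_i w_i exp(-(g-x_i)^2 / 2h^2)."""
    m = grid.shape[0]
    n = pos.shape[0]
    out = np.zeros(m)
    inv = 1.0 / (2.0 * h * h)
    for j in range(m):
        s = 0.0
        g = grid[j]
        for i in range(n):
            d = g - pos[i]
            s += w[i] * np.exp(-d * d * inv)
        out[j] = s
    return out


@njit(cache=False, fastmath=True)
def gauss_heights_trunc(pos, w, grid, h, radius):
    """Windowed kernel sum: contributions beyond ``radius*h`` are dropped.

    ``pos`` and ``grid`` must be sorted ascending.  The absolute truncation
    error is bounded by ``sum(w) * exp(-radius^2/2)``.
    """
    m = grid.shape[0]
    n = pos.shape[0]
    out = np.zeros(m)
    inv = 1.0 / (2.0 * h * h)
    r = radius * h
    lo = 0
    hi = 0
    for j in range(m):
        g = grid[j]
        while lo < n and pos[lo] < g - r:
            lo += 1
        while hi < n and pos[hi] <= g + r:
            hi += 1
        s = 0.0
        for i in range(lo, hi):
            d = g - pos[i]
            s += w[i] * np.exp(-d * d * inv)
        out[j] = s
    return out


#: resolution of the exp lookup table used by the screening engine
EXP_TABLE_N = 8192


def make_exp_table(radius: float) -> np.ndarray:
    """Tabulated ``exp(-u)`` for ``u in [0, radius^2/2]`` (float32).

    The screening engine evaluates the kernel through linear interpolation of
    this table; with 8192 bins the relative error is < 1e-6, far below the
    Monte-Carlo noise of the null, and the loop vectorizes where a libm exp
    call would not.
    """
    umax = radius * radius / 2.0
    return np.exp(-np.linspace(0.0, umax, EXP_TABLE_N + 1)).astype(np.float32)


@njit(cache=False, fastmath=True)
def gauss_heights_trunc32(pos, w, grid, h, radius, tab):
    """Single-precision windowed kernel sum used by the CIS caller.

    Observed and null profiles go through this same routine, so peak-height
    comparisons are internally consistent; the ~1e-6 relative error of the
    interpolated exp is far below Monte-Carlo noise.  Positions up to 2^24
    are exact in float32; beyond that they round to within 16 bp, negligible
    against kernel widths of >= 10 kb.
    """
    m = grid.shape[0]
    n = pos.shape[0]
    out = np.zeros(m, np.float32)
    inv = np.float32(1.0 / (2.0 * h * h))
    r = np.float32(radius * h)
    ntab = tab.shape[0] - 1
    uscale = np.float32(ntab / (radius * radius / 2.0))
    lo = 0
    hi = 0
    for j in range(m):
        g = grid[j]
        while lo < n and pos[lo] < g - r:
            lo += 1
        while hi < n and pos[hi] <= g + r:
            hi += 1
        s = np.float32(0.0)
        for i in range(lo, hi):
            d = g - pos[i]
            x = d * d * inv * uscale
            k = np.int64(x)
            if k >= ntab:
                continue
            frac = x - np.float32(k)
            s += w[i] * (tab[k] + (tab[k + 1] - tab[k]) * frac)
        out[j] = s
    return out


@njit(cache=False)
def local_maxima(heights):
    """Indices of strict local maxima; plateaus yield their leftmost point.

    A boundary point counts as a maximum when it exceeds its single inner
    neighbour; an all-constant profile has no maxima.
    """
    m = heights.shape[0]
    out = np.empty(m, np.int64)
    k = 0
    i = 0
    while i < m:
        j = i
        while j + 1 < m and heights[j + 1] == heights[i]:
            j += 1
        left_ok = i == 0 or heights[i - 1] < heights[i]
        right_ok = j == m - 1 or heights[j + 1] < heights[i]
        if left_ok and right_ok and not (i == 0 and j == m - 1):
            out[k] = i
            k += 1
        i = j + 1
    return out[:k]


@njit(cache=False, fastmath=True)
def null_peak_scan(ttaa, counts, h, grid_regular, radius, min_ins, seed, weight_pool, tab):
    """Monte-Carlo null for one chromosome and one kernel width.

    For each replicate r, ``counts[r]`` insertions are placed uniformly (with
    replacement) on the TTAA positions, the kernel profile is evaluated on the
    regular grid merged with the sampled positions, and the heights of local
    maxima supported by at least ``min_ins`` insertions within +-h are
    recorded.  When ``weight_pool`` is non-empty each null insertion draws its
    kernel weight uniformly from it (read-count-weighted mode); otherwise all
    weights are 1.

    Returns ``(pooled_heights, rep_max, rep_npeaks)`` where ``rep_max[r]`` is
    the maximum peak height of replicate r (0 when it has no qualifying peak).
    """
    np.random.seed(seed)
    n_perm = counts.shape[0]
    nt = ttaa.shape[0]
    cap = 1024
    pooled = np.empty(cap)
    total = 0
    rep_max = np.zeros(n_perm)
    rep_npeaks = np.zeros(n_perm, np.int64)
    for r in range(n_perm):
        n = counts[r]
        if n == 0:
            continue
        pos = np.empty(n, np.int64)
        for i in range(n):
            pos[i] = ttaa[np.random.randint(0, nt)]
        pos = np.sort(pos)
        if weight_pool.shape[0] > 0:
            w = np.empty(n, np.float32)
            for i in range(n):
                w[i] = weight_pool[np.random.randint(0, weight_pool.shape[0])]
        else:
            w = np.ones(n, np.float32)
        pos32 = pos.astype(np.float32)
        grid = np.unique(np.concatenate((grid_regular, pos32)))
        heights = gauss_heights_trunc32(pos32, w, grid, np.float32(h),
                                        np.float32(radius), tab)
        peaks = local_maxima(heights)
        best = 0.0
        npk = 0
        for pidx in peaks:
            apex = np.float64(grid[pidx])
            lo = np.searchsorted(pos32, np.float32(apex - h), side="left")
            hi = np.searchsorted(pos32, np.float32(apex + h), side="right")
            if hi - lo < min_ins:
                continue
            val = np.float64(heights[pidx])
            if total == cap:
                cap *= 2
                bigger = np.empty(cap)
                bigger[:total] = pooled[:total]
                pooled = bigger
            pooled[total] = val
            total += 1
            npk += 1
            if val > best:
                best = val
        rep_max[r] = best
        rep_npeaks[r] = npk
    return pooled[:total], rep_max, rep_npeaks
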