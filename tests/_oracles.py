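"""Independent brute-force oracles used by the test suite.

Everything here is written as plainly as possible (explicit loops,
textbook formulas, direct numerical integration) and never calls the
library code paths it is used to check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import integrate
from scipy.special import gammaln

_OFFSETS = {
    6: [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    18: [
        o
        for o in itertools.product((-1, 0, 1), repeat=3)
        if o != (0, 0, 0) and sum(abs(v) for v in o) <= 2
    ],
    26: [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)],
}


def brute_shell(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Shell membership by explicit neighbor enumeration."""
    shell = np.zeros_like(mask, dtype=bool)
    shape = mask.shape
    for z, y, x in np.argwhere(mask):
        for dz, dy, dx in _OFFSETS[connectivity]:
            nz, ny, nx = z + dz, y + dy, x + dx
            if 0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]:
                if not mask[nz, ny, nx]:
                    shell[nz, ny, nx] = True
    return shell


def brute_surface_area(mask: np.ndarray, voxel_size) -> float:
    """Exposed-face counting by explicit loops."""
    dz, dy, dx = voxel_size
    face = {0: dy * dx, 1: dz * dx, 2: dz * dy}
    shape = mask.shape
    total = 0.0
    for z, y, x in np.argwhere(mask):
        for axis, (oz, oy, ox) in (
            (0, (1, 0, 0)), (0, (-1, 0, 0)),
            (1, (0, 1, 0)), (1, (0, -1, 0)),
            (2, (0, 0, 1)), (2, (0, 0, -1)),
        ):
            nz, ny, nx = z + oz, y + oy, x + ox
            outside = not (0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2])
            if outside or not mask[nz, ny, nx]:
                total += face[axis]
    return total


def brute_contact_percent(shell: np.ndarray, iba1: np.ndarray) -> float:
    n_shell = 0
    n_hit = 0
    for idx in np.argwhere(shell):
        n_shell += 1
        if iba1[tuple(idx)]:
            n_hit += 1
    return 100.0 * n_hit / n_shell


def brute_ball_voxels(center, radius: float, shape, voxel_size) -> int:
    """Count voxels whose center is within the radius, by explicit loops."""
    dz, dy, dx = voxel_size
    cz, cy, cx = center
    lo = [max(0, int((c - radius) / v) - 2) for c, v in zip(center, voxel_size)]
    hi = [
        min(s, int((c + radius) / v) + 3)
        for c, v, s in zip(center, voxel_size, shape)
    ]
    n = 0
    for z in range(lo[0], hi[0]):
        for y in range(lo[1], hi[1]):
            for x in range(lo[2], hi[2]):
                d2 = (z * dz - cz) ** 2 + (y * dy - cy) ** 2 + (x * dx - cx) ** 2
                if d2 <= radius * radius:
                    n += 1
    return n


def brute_min_distance_um(point_um, mask: np.ndarray, pixel_size: float) -> float:
    """Distance from a point to the nearest positive pixel center, by loops."""
    best = math.inf
    py, px = point_um
    for y, x in np.argwhere(mask):
        d = math.hypot(y * pixel_size - py, x * pixel_size - px)
        best = min(best, d)
    return best


def balanced_two_way_ss(values: np.ndarray, a: np.ndarray, b: np.ndarray) -> dict:
    """Classic balanced two-way ANOVA sums-of-squares decomposition."""
    values = np.asarray(values, float)
    a_levels = sorted(set(a))
    b_levels = sorted(set(b))
    grand = values.mean()
    n = len(values)
    ss_a = sum(
        (values[a == la]).size * (values[a == la].mean() - grand) ** 2 for la in a_levels
    )
    ss_b = sum(
        (values[b == lb]).size * (values[b == lb].mean() - grand) ** 2 for lb in b_levels
    )
    ss_cells = 0.0
    ss_within = 0.0
    for la in a_levels:
        for lb in b_levels:
            cell = values[(a == la) & (b == lb)]
            ss_cells += cell.size * (cell.mean() - grand) ** 2
            ss_within += ((cell - cell.mean()) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    df_a = len(a_levels) - 1
    df_b = len(b_levels) - 1
    df_ab = df_a * df_b
    df_res = n - len(a_levels) * len(b_levels)
    return {
        "ss_a": ss_a, "ss_b": ss_b, "ss_ab": ss_ab, "ss_res": ss_within,
        "df_a": df_a, "df_b": df_b, "df_ab": df_ab, "df_res": df_res,
        "F_a": (ss_a / df_a) / (ss_within / df_res),
        "F_b": (ss_b / df_b) / (ss_within / df_res),
        "F_ab": (ss_ab / df_ab) / (ss_within / df_res),
    }


def t_two_sided_p(t: float, df: int) -> float:
    """Two-sided t-test p by numerical integration of the t density."""

    def pdf(x):
        logc = gammaln((df + 1) / 2) - gammaln(df / 2) - 0.5 * math.log(df * math.pi)
        return math.exp(logc - (df + 1) / 2 * math.log1p(x * x / df))

    tail, _ = integrate.quad(pdf, abs(t), np.inf)
    return 2.0 * tail


def studentized_range_sf(q: float, k: int, df: int) -> float:
    """Upper tail of the studentized range by direct double integration.

    P(Q > q) with Q = range of k standard normals divided by an independent
    chi(df)/sqrt(df); textbook integral over the scale s and the minimum
    normal z.
    """
    from scipy.stats import norm

    def inner(s):
        def f(z):
            return norm.pdf(z) * (norm.cdf(z + q * s) - norm.cdf(z)) ** (k - 1)

        val, _ = integrate.quad(f, -8.5, 8.5, limit=200)
        return k * val

    logc = (df / 2) * math.log(df) - gammaln(df / 2) - (df / 2 - 1) * math.log(2)

    def outer(s):
        return math.exp(logc + (df - 1) * math.log(s) - df * s * s / 2) * inner(s)

    cdf, _ = integrate.quad(outer, 1e-9, 10, limit=200)
    return max(0.0, 1.0 - cdf)
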