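"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive each quantity from first principles (explicit
enumeration, all-pairs scans) without sharing code paths with the package
implementations they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_ball_fraction(mask: np.ndarray, spacing_zyx, center_zyx, radius: float,
                        in_bounds_denominator: bool = True) -> float:
    """Foreground fraction of the discrete ball around one center voxel.

    Enumerates every integer offset within the physical radius, filters
    offsets falling outside the array, and counts foreground directly.
    """
    dz, dy, dx = spacing_zyx
    nz, ny, nx = mask.shape
    # enumerate one step beyond the nominal range so borderline offsets whose
    # rounded physical distance equals the radius are decided by the predicate
    kz = int(np.ceil(radius / dz)) + 1
    ky = int(np.ceil(radius / dy)) + 1
    kx = int(np.ceil(radius / dx)) + 1
    oz, oy, ox = np.meshgrid(
        np.arange(-kz, kz + 1), np.arange(-ky, ky + 1), np.arange(-kx, kx + 1),
        indexing="ij",
    )
    inside = (oz * dz) ** 2 + (oy * dy) ** 2 + (ox * dx) ** 2 <= radius**2
    oz, oy, ox = oz[inside], oy[inside], ox[inside]
    cz, cy, cx = center_zyx
    z, y, x = cz + oz, cy + oy, cx + ox
    ok = (z >= 0) & (z < nz) & (y >= 0) & (y < ny) & (x >= 0) & (x < nx)
    count = int(mask[z[ok], y[ok], x[ok]].sum())
    denom = int(ok.sum()) if in_bounds_denominator else len(oz)
    return count / denom


def brute_min_distance(source_vox: np.ndarray, other_vox: np.ndarray, spacing_zyx) -> float:
    """All-pairs minimum center-to-center distance between two voxel sets (um)."""
    if len(other_vox) == 0:
        return np.inf
    s = np.asarray(spacing_zyx, dtype=float)
    a = source_vox * s
    b = other_vox * s
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def mwu_exact_enumeration(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all C(n+m, n) labelings."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    pooled = np.concatenate([x, y])
    idx = range(len(pooled))
    u_obs = _u_statistic(x, y)
    us = []
    for combo in combinations(idx, n):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(combo)] = True
        us.append(_u_statistic(pooled[sel], pooled[~sel]))
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs + 1e-12)
    p_ge = np.mean(us >= u_obs - 1e-12)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_exact_enumeration(x, y) -> tuple[float, float]:
    """Exact two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = len(d)
    ranks = np.empty(n)
    order = np.argsort(np.abs(d))
    # midranks of |d|
    ad = np.abs(d)[order]
    r = np.arange(1, n + 1, dtype=float)
    for v in np.unique(ad):
        sel = ad == v
        r[sel] = r[sel].mean()
    ranks[order] = r
    w_obs = float(ranks[d > 0].sum())
    ws = []
    for signs in range(2**n):
        bits = (signs >> np.arange(n)) & 1
        ws.append(float(ranks[bits == 1].sum()))
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return w_obs, min(1.0, 2.0 * min(p_le, p_ge))
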