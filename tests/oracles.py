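"""Independent brute-force oracles used to verify the vectorised kernels.

Everything here is written as plain per-cell / per-pair Python loops with no
reuse of the package's implementations (only its documented conventions:
border handling, population SD, Horn stencil, Zevenbergen–Thorne
coefficients, Jenness triangulation).
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def _pad_nearest(z: np.ndarray) -> np.ndarray:
    out = np.empty((z.shape[0] + 2, z.shape[1] + 2))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            out[i, j] = z[min(max(i - 1, 0), z.shape[0] - 1),
                          min(max(j - 1, 0), z.shape[1] - 1)]
    return out


def focal_sd_oracle(z: np.ndarray) -> np.ndarray:
    """3x3 population SD, window shrinking at borders."""
    ny, nx = z.shape
    out = np.empty_like(z, dtype=float)
    for i in range(ny):
        for j in range(nx):
            vals = []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < ny and 0 <= jj < nx:
                        vals.append(z[ii, jj])
            m = sum(vals) / len(vals)
            out[i, j] = math.sqrt(sum((v - m) ** 2 for v in vals) / len(vals))
    return out


def horn_slope_oracle(z: np.ndarray, cell: float) -> np.ndarray:
    zp = _pad_nearest(z)
    ny, nx = z.shape
    out = np.empty_like(z, dtype=float)
    for i in range(ny):
        for j in range(nx):
            a, b, c = zp[i, j], zp[i, j + 1], zp[i, j + 2]
            d, f = zp[i + 1, j], zp[i + 1, j + 2]
            g, h, k = zp[i + 2, j], zp[i + 2, j + 1], zp[i + 2, j + 2]
            dzdx = ((c + 2 * f + k) - (a + 2 * d + g)) / (8 * cell)
            dzdy = ((g + 2 * h + k) - (a + 2 * b + c)) / (8 * cell)
            out[i, j] = math.degrees(math.atan(math.hypot(dzdx, dzdy)))
    return out


def plan_curvature_oracle(z: np.ndarray, cell: float, scale: float = 100.0) -> np.ndarray:
    """Zevenbergen–Thorne plan curvature on the elevation (-depth) surface."""
    zp = -_pad_nearest(z)
    ny, nx = z.shape
    out = np.empty_like(z, dtype=float)
    for i in range(ny):
        for j in range(nx):
            z1, z2, z3 = zp[i, j], zp[i, j + 1], zp[i, j + 2]
            z4, z5, z6 = zp[i + 1, j], zp[i + 1, j + 1], zp[i + 1, j + 2]
            z7, z8, z9 = zp[i + 2, j], zp[i + 2, j + 1], zp[i + 2, j + 2]
            D = ((z4 + z6) / 2 - z5) / cell**2
            E = ((z2 + z8) / 2 - z5) / cell**2
            F = (-z1 + z3 + z7 - z9) / (4 * cell**2)
            G = (-z4 + z6) / (2 * cell)
            H = (z2 - z8) / (2 * cell)
            denom = G * G + H * H
            if denom == 0:
                out[i, j] = 0.0
            else:
                out[i, j] = -2.0 * (D * H * H + E * G * G - F * G * H) / denom * scale
    return out


def _heron(a: float, b: float, c: float) -> float:
    s = (a + b + c) / 2.0
    return math.sqrt(max(s * (s - a) * (s - b) * (s - c), 0.0))


def rugosity_oracle(z: np.ndarray, cell: float) -> np.ndarray:
    """Jenness 8-triangle surface-area ratio, nearest-edge padding."""
    zp = _pad_nearest(z)
    ny, nx = z.shape
    ring = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
    out = np.empty_like(z, dtype=float)
    for i in range(ny):
        for j in range(nx):
            zc = zp[i + 1, j + 1]
            area = 0.0
            for k in range(8):
                dr1, dc1 = ring[k]
                dr2, dc2 = ring[(k + 1) % 8]
                zn1 = zp[i + 1 + dr1, j + 1 + dc1]
                zn2 = zp[i + 1 + dr2, j + 1 + dc2]
                e1 = 0.5 * math.sqrt((cell * math.hypot(dr1, dc1)) ** 2 + (zn1 - zc) ** 2)
                e2 = 0.5 * math.sqrt((cell * math.hypot(dr2, dc2)) ** 2 + (zn2 - zc) ** 2)
                e3 = 0.5 * math.sqrt((cell * math.hypot(dr1 - dr2, dc1 - dc2)) ** 2
                                     + (zn1 - zn2) ** 2)
                area += _heron(e1, e2, e3)
            out[i, j] = max(area / cell**2, 1.0)
    return out


def isobath_distance_oracle(z: np.ndarray, cell: float, level: float) -> np.ndarray:
    """All-pairs Euclidean distance (km) to threshold-crossing cells."""
    ny, nx = z.shape
    iso = []
    for i in range(ny):
        for j in range(nx):
            if z[i, j] < level:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ii, jj = i + di, j + dj
                if 0 <= ii < ny and 0 <= jj < nx and z[ii, jj] < level:
                    iso.append((i, j))
                    break
    if not iso:
        raise ValueError("no isobath in oracle grid")
    out = np.empty_like(z, dtype=float)
    for i in range(ny):
        for j in range(nx):
            out[i, j] = min(math.hypot(i - a, j - b) for a, b in iso) * cell / 1000.0
    return out


def focal_mean_oracle(z: np.ndarray, cell: float, radius: float) -> np.ndarray:
    ny, nx = z.shape
    r_cells = int(radius // cell)
    out = np.empty_like(z, dtype=float)
    for i in range(ny):
        for j in range(nx):
            vals = []
            for di in range(-r_cells, r_cells + 1):
                for dj in range(-r_cells, r_cells + 1):
                    if (di * di + dj * dj) * cell * cell <= radius * radius:
                        ii, jj = i + di, j + dj
                        if 0 <= ii < ny and 0 <= jj < nx:
                            vals.append(z[ii, jj])
            out[i, j] = sum(vals) / len(vals)
    return out


# ---------------------------------------------------------------------------
# metric oracles

def auc_concordance_oracle(scores, labels) -> float:
    """AUC as the concordant-pair fraction (ties count 1/2)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def jenks_exhaustive_oracle(values, k: int) -> float:
    """Minimal within-class SSE over all ordered partitions into k classes."""
    v = sorted(values)
    n = len(v)

    def sse(seg):
        m = sum(seg) / len(seg)
        return sum((x - m) ** 2 for x in seg)

    best = math.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        edges = (0, *cuts, n)
        cost = sum(sse(v[edges[i]:edges[i + 1]]) for i in range(k))
        best = min(best, cost)
    return best


def jenks_sse(values, thresholds) -> float:
    """Within-class SSE of the classification induced by the thresholds."""
    groups: dict[int, list] = {}
    for x in values:
        g = 0
        for t in thresholds:
            if x > t:
                g += 1
        groups.setdefault(g, []).append(x)
    total = 0.0
    for seg in groups.values():
        m = sum(seg) / len(seg)
        total += sum((x - m) ** 2 for x in seg)
    return total


def global_morans_oracle(xy: np.ndarray, values: np.ndarray, power: float = 1.0) -> float:
    """Global Moran's I with row-standardised IDW weights, from scratch."""
    n = len(values)
    z = values - values.mean()
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d = math.hypot(*(xy[i] - xy[j]))
                w[i, j] = 1.0 / d**power
        w[i] /= w[i].sum()
    num = sum(w[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return (n / w.sum()) * num / (z @ z)
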