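"""Model-transfer validation: ROC/AUC with confidence intervals, Jenks
density classes, pairwise and Hand–Till multiclass AUC, MAE/RMSE with
MAE-relative residual classes, variogram-based spatial thinning, and
Local Moran's I error clustering.

The workflow these pieces support: predictions made in a second, independent
survey area are compared with observations there; because adjacent sample
bins are spatially autocorrelated, the validation points are first thinned to
a minimum spacing equal to the range of a spherical semivariogram fitted to
locally-detrended residuals, and the spatial structure of the remaining
errors is characterised with the Local Moran's I statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import roc_curve as _sk_roc_curve

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ROC / AUC

@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci_halfwidth: float
    n_pos: int
    n_neg: int


def roc_auc(scores, labels) -> RocResult:
    """AUC by the rank (Mann–Whitney) formulation with tie correction.

    The 95% confidence half-width uses the Hanley–McNeil variance formula.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(s)  # midranks handle ties
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2)
           + (n_neg - 1) * (q2 - auc**2)) / (n_pos * n_neg)
    fpr, tpr, _ = _sk_roc_curve(y, s)
    return RocResult(fpr=fpr, tpr=tpr, auc=float(auc),
                     ci_halfwidth=float(1.96 * np.sqrt(max(var, 0.0))),
                     n_pos=n_pos, n_neg=n_neg)


@dataclass
class MulticlassAucResult:
    classes: list
    pairwise: dict          # (class_i, class_j) -> AUC (i below j in rank order)
    m: float                # Hand–Till average over usable pairs
    excluded_pairs: list = field(default_factory=list)


def multiclass_auc(scores, class_labels) -> MulticlassAucResult:
    """Pairwise AUCs of a continuous score over ordered classes and their
    Hand–Till average M.

    For each class pair the higher class is treated as the positive and the
    binary AUC of the score restricted to those classes is computed; M is the
    mean of all c(c-1)/2 pairwise values.  Pairs involving a class with fewer
    than 2 members are excluded from M with a warning.
    """
    s = np.asarray(scores, dtype=float)
    labels = np.asarray(class_labels)
    classes = sorted(np.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes present")
    counts = {c: int((labels == c).sum()) for c in classes}
    pairwise: dict[tuple, float] = {}
    excluded = []
    vals = []
    for a in range(len(classes)):
        for b in range(a + 1, len(classes)):
            ci, cj = classes[a], classes[b]
            if counts[ci] < 2 or counts[cj] < 2:
                excluded.append((ci, cj))
                warnings.warn(f"pair ({ci}, {cj}) excluded from M: class with < 2 members")
                pairwise[(ci, cj)] = float("nan")
                continue
            mask = (labels == ci) | (labels == cj)
            r = roc_auc(s[mask], (labels[mask] == cj).astype(int))
            pairwise[(ci, cj)] = r.auc
            vals.append(r.auc)
    if not vals:
        raise ValueError("no class pair has enough members for an AUC")
    return MulticlassAucResult(classes=classes, pairwise=pairwise,
                               m=float(np.mean(vals)), excluded_pairs=excluded)


# ---------------------------------------------------------------------------
# Jenks natural breaks

DENSITY_CLASS_NAMES = ("absent_to_low", "low", "medium", "high")


@dataclass
class DensityClassing:
    thresholds: np.ndarray       # k-1 upper bounds of the lower classes
    labels: list                 # class name per input value
    class_names: list
    frequencies: dict            # class name -> fraction of records


def jenks_breaks(values, k: int = 4, class_names=None) -> DensityClassing:
    """Exact Fisher–Jenks optimal 1-D classification into k classes.

    Dynamic program minimising the within-class sum of squared deviations.
    Thresholds are the maxima of the lower k-1 classes; a value belongs to
    the lowest class whose threshold it does not exceed.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if len(np.unique(v)) < k:
        raise ValueError(f"need at least {k} distinct values for {k} classes")
    # prefix sums for O(1) segment SSE
    S = np.concatenate([[0.0], np.cumsum(v)])
    S2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def seg_sse(i: np.ndarray, j: int) -> np.ndarray:
        """SSE of v[i..j] inclusive (i may be a vector)."""
        cnt = j - i + 1
        tot = S[j + 1] - S[i]
        return (S2[j + 1] - S2[i]) - tot * tot / cnt

    # D[j] = minimal SSE of v[0..j] split into the current number of classes
    D = np.array([float(seg_sse(np.array([0]), j)[0]) for j in range(n)])
    B = np.zeros((k, n), dtype=int)
    for c in range(1, k):
        D_new = np.full(n, np.inf)
        for j in range(c, n):
            i = np.arange(c, j + 1)  # first index of the last class
            cost = D[i - 1] + seg_sse(i, j)
            best = int(np.argmin(cost))
            D_new[j] = cost[best]
            B[c, j] = i[best]
        D = D_new
    # recover break positions
    bounds = []
    j = n - 1
    for c in range(k - 1, 0, -1):
        i = B[c, j]
        bounds.append(v[i - 1])  # max of the class below
        j = i - 1
    thresholds = np.array(bounds[::-1])
    if class_names is None:
        class_names = list(DENSITY_CLASS_NAMES) if k == 4 else [f"class_{i+1}" for i in range(k)]
    labels = classify_by_breaks(values, thresholds, class_names)
    freqs = {cn: float(np.mean([lb == cn for lb in labels])) for cn in class_names}
    return DensityClassing(thresholds=thresholds, labels=labels,
                           class_names=list(class_names), frequencies=freqs)


def classify_by_breaks(values, thresholds, class_names) -> list:
    """Assign each value to the lowest class whose threshold it does not exceed."""
    v = np.asarray(values, dtype=float)
    idx = np.searchsorted(np.asarray(thresholds, dtype=float), v, side="left")
    return [class_names[i] for i in idx]


# ---------------------------------------------------------------------------
# error metrics

@dataclass
class ErrorMetrics:
    mae: float
    rmse: float
    r: float
    residuals: np.ndarray
    residual_classes: list   # per residual: neg_gt_mae / neg_le_mae / pos_le_mae / pos_gt_mae


def error_metrics(predicted, observed) -> ErrorMetrics:
    """MAE, RMSE, Pearson r, and residual classes relative to the MAE.

    Residuals are predicted - observed (positive = over-prediction).
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed must have equal length")
    if len(p) < 2:
        raise ValueError("need at least 2 values")
    e = p - o
    mae = float(np.mean(np.abs(e)))
    rmse = float(np.sqrt(np.mean(e * e)))
    if np.ptp(p) == 0 or np.ptp(o) == 0:
        r = 0.0  # correlation undefined for a constant margin
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = float(stats.pearsonr(p, o)[0])
        if not np.isfinite(r):
            r = 0.0
    classes = []
    for err in e:
        sign = "pos" if err >= 0 else "neg"
        mag = "le_mae" if abs(err) <= mae else "gt_mae"
        classes.append(f"{sign}_{mag}")
    return ErrorMetrics(mae=mae, rmse=rmse, r=r, residuals=e, residual_classes=classes)


# ---------------------------------------------------------------------------
# detrending and semivariogram

def detrend_residuals(points, values, span: float = 0.5, degree: int = 2) -> np.ndarray:
    """Residuals from a local polynomial (LOESS-style) trend surface in (x, y).

    At each point a degree-2 polynomial in easting/northing is fit by
    weighted least squares to the nearest ``span`` fraction of the data with
    tricube weights.  Degenerate local geometry falls back to a global
    quadratic with a warning.
    """
    from scipy.spatial import cKDTree

    xy = np.asarray(points, dtype=float)
    z = np.asarray(values, dtype=float)
    n = len(z)
    if n < 10:
        raise ValueError("need at least 10 points to detrend")

    def design(px, py):
        cols = [np.ones_like(px), px, py]
        if degree >= 2:
            cols += [px * px, px * py, py * py]
        return np.column_stack(cols)

    k = max(design(xy[:1, 0], xy[:1, 1]).shape[1] + 2, int(np.ceil(span * n)))
    k = min(k, n)
    tree = cKDTree(xy)
    dists, idx = tree.query(xy, k=k)
    fitted = np.empty(n)
    fallback = False
    for i in range(n):
        nb, d = idx[i], dists[i]
        dmax = d[-1] if d[-1] > 0 else 1.0
        w = np.clip(1 - (d / dmax) ** 3, 0.0, None) ** 3
        w[d >= dmax] = np.finfo(float).tiny  # keep the farthest point from zeroing out
        px = xy[nb, 0] - xy[i, 0]
        py = xy[nb, 1] - xy[i, 1]
        A = design(px, py) * np.sqrt(w)[:, None]
        b = z[nb] * np.sqrt(w)
        sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
        if rank < A.shape[1]:
            fallback = True
            break
        fitted[i] = sol[0]  # polynomial centred on the point: intercept = fit
    if fallback:
        warnings.warn("degenerate local geometry: falling back to a global quadratic trend")
        A = design(xy[:, 0] - xy[:, 0].mean(), xy[:, 1] - xy[:, 1].mean())
        sol, *_ = np.linalg.lstsq(A, z, rcond=None)
        fitted = A @ sol
    return z - fitted


def empirical_semivariogram(points, residuals, n_lags: int = 15,
                            max_lag: float | None = None) -> np.ndarray:
    """Equal-width-binned empirical semivariance.

    Returns an (n_lags, 3) array of (lag-bin centre, semivariance, pair
    count); empty bins carry count 0 and NaN semivariance.
    """
    xy = np.asarray(points, dtype=float)
    r = np.asarray(residuals, dtype=float)
    if len(r) < 2:
        raise ValueError("need at least 2 points")
    d = pdist(xy)
    dz2 = pdist(r[:, None], metric="sqeuclidean")
    if max_lag is None:
        max_lag = d.max() / 2.0
    edges = np.linspace(0.0, max_lag, n_lags + 1)
    which = np.digitize(d, edges) - 1
    out = np.full((n_lags, 3), np.nan)
    for b in range(n_lags):
        sel = which == b
        n_pairs = int(sel.sum())
        out[b, 0] = 0.5 * (edges[b] + edges[b + 1])
        out[b, 2] = n_pairs
        if n_pairs:
            out[b, 1] = 0.5 * dz2[sel].mean()
    return out


@dataclass
class VariogramModel:
    nugget: float
    partial_sill: float
    range_m: float
    empirical: np.ndarray
    flagged: bool = False

    def __call__(self, h) -> np.ndarray:
        return spherical_model(np.asarray(h, dtype=float), self.nugget,
                               self.partial_sill, self.range_m)


def spherical_model(h: np.ndarray, c0: float, c: float, a: float) -> np.ndarray:
    """Spherical semivariogram: rises as 1.5 h/a - 0.5 (h/a)^3, flat past the range."""
    a = max(a, 1e-12)
    hr = np.minimum(np.asarray(h, dtype=float) / a, 1.0)
    return c0 + c * (1.5 * hr - 0.5 * hr**3)


def fit_spherical_variogram(empirical: np.ndarray,
                            weights: str = "n_over_h2") -> VariogramModel:
    """Weighted least-squares spherical fit of (nugget, partial sill, range).

    Default weights are N(h)/h^2 (pair counts downweighted by squared lag, as
    in gstat): the short lags that identify the range would otherwise be
    swamped by the far bins, which hold most pairs but only sill information.
    ``weights="n"`` uses plain pair-count weights.  Multi-start bounded
    trust-region least squares with non-negativity; a fit whose structured
    component vanishes (pure nugget, range unidentifiable) or whose range
    hits the lag-support bound is flagged.
    """
    emp = np.asarray(empirical, dtype=float)
    ok = np.isfinite(emp[:, 1]) & (emp[:, 2] > 0)
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-empty lag bins")
    h, g, w = emp[ok, 0], emp[ok, 1], emp[ok, 2]
    if weights == "n_over_h2":
        sw = np.sqrt(w / np.maximum(h, 1e-12) ** 2)
    elif weights == "n":
        sw = np.sqrt(w)
    else:
        raise ValueError(f"unknown weights mode '{weights}'")

    def resid(theta):
        return sw * (spherical_model(h, *theta) - g)

    gmax = max(g.max(), 1e-12)
    hmax = h.max()
    # the range is only identifiable inside the empirical lag support
    a_max = 3.0 * hmax
    best = None
    for a0 in (0.2, 0.5, 1.0):
        for c00 in (0.0, 0.5):
            x0 = np.array([c00 * gmax, max(gmax - c00 * gmax, 1e-6), a0 * hmax])
            try:
                sol = optimize.least_squares(resid, x0, bounds=([0, 0, 1e-9],
                                                                [np.inf, np.inf, a_max]))
            except Exception:  # pragma: no cover - defensive
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise RuntimeError("variogram fit failed from every start")
    c0, c, a = best.x
    flagged = (not best.success) or c < 1e-6 * max(c0 + c, 1e-12) or a > 0.99 * a_max
    if flagged:
        logger.warning("variogram fit flagged: c0=%.4g c=%.4g a=%.4g", c0, c, a)
    return VariogramModel(nugget=float(c0), partial_sill=float(c), range_m=float(a),
                          empirical=emp, flagged=flagged)


# ---------------------------------------------------------------------------
# spatial thinning

def thin_by_range(points, range_m: float, seed: int = 0,
                  order: np.ndarray | None = None) -> np.ndarray:
    """Greedy minimum-spacing thinning; returns indices of retained points.

    Points are visited in a seeded random order (or a caller-supplied one);
    each is kept iff it lies at least ``range_m`` from every point already
    kept.  The result therefore has min pairwise distance >= range_m and is
    maximal: every removed point is within range of a kept one.
    """
    if range_m <= 0:
        raise ValueError("range_m must be positive")
    xy = np.asarray(points, dtype=float)
    n = len(xy)
    if n == 0:
        return np.array([], dtype=int)
    if order is None:
        order = np.random.default_rng(seed).permutation(n)
    kept: list[int] = []
    kept_xy = np.empty((0, 2))
    for i in order:
        if kept_xy.size:
            d2 = np.sum((kept_xy - xy[i]) ** 2, axis=1)
            if d2.min() < range_m**2:
                continue
        kept.append(int(i))
        kept_xy = np.vstack([kept_xy, xy[i]])
    return np.sort(np.array(kept, dtype=int))


# ---------------------------------------------------------------------------
# Local Moran's I

@dataclass
class LisaResult:
    local_i: np.ndarray
    p_values: np.ndarray
    labels: list                 # HH / LL / HL / LH / not-significant
    global_i: float


def _idw_weights(xy: np.ndarray, power: float) -> np.ndarray:
    d = squareform(pdist(xy))
    with np.errstate(divide="ignore"):
        w = 1.0 / d**power
    np.fill_diagonal(w, 0.0)
    if np.isinf(w).any():
        raise ValueError("coincident points give infinite inverse-distance weights")
    rowsum = w.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    return w / rowsum


def local_morans(points, values, idw_power: float = 1.0, n_permutations: int = 999,
                 alpha: float = 0.05, seed: int = 0) -> LisaResult:
    """Anselin Local Moran's I with inverse-distance weights and
    conditional-permutation inference.

    I_i = (z_i / m2) * sum_j w_ij z_j with z the mean-deviates, m2 their mean
    square, and w row-standardised inverse-distance weights.  The pseudo
    p-value for each point holds z_i fixed and permutes the remaining values;
    significant points are labelled HH/LL clusters or HL/LH outliers by the
    signs of z_i and its spatial lag.  With row-standardised weights the mean
    of I_i equals the global Moran's I.
    """
    xy = np.asarray(points, dtype=float)
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    z = x - x.mean()
    if np.all(z == 0):
        return LisaResult(local_i=np.zeros(n), p_values=np.ones(n),
                          labels=["not-significant"] * n, global_i=0.0)
    m2 = float(np.mean(z * z))
    w = _idw_weights(xy, idw_power)
    lag = w @ z
    local_i = z / m2 * lag
    global_i = float(np.mean(local_i))  # row-standardised identity
    rng = np.random.default_rng(seed)
    p = np.ones(n)
    for i in range(n):
        others = np.delete(z, i)
        wi = np.delete(w[i], i)
        perms = np.tile(others, (n_permutations, 1))
        perms = rng.permuted(perms, axis=1)
        lag_perm = perms @ wi
        i_perm = z[i] / m2 * lag_perm
        greater = np.sum(i_perm >= local_i[i])
        lesser = np.sum(i_perm <= local_i[i])
        p[i] = min(1.0, 2.0 * (min(greater, lesser) + 1) / (n_permutations + 1))
    labels = []
    for i in range(n):
        if p[i] >= alpha:
            labels.append("not-significant")
        elif z[i] > 0:
            labels.append("HH" if lag[i] > 0 else "HL")
        else:
            labels.append("LL" if lag[i] < 0 else "LH")
    return LisaResult(local_i=local_i, p_values=p, labels=labels, global_i=global_i)
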