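"""Stratified-heterogeneity detectors (the Geodetector family).

The factor detector's q-statistic measures how much of the variance of a
continuous outcome a categorical stratification explains:

    q = 1 − Σ_h N_h σ_h² / (N σ²)          (population variances, ÷N_h)

with q ∈ [0, 1]; q = 0 when strata are uninformative, q = 1 when each
stratum is internally constant. Significance uses the noncentral-F
approximation from the Geodetector literature, with a seeded permutation
fallback. The ecological detector F-compares two stratifications' within-
stratum sums of squares; the interaction detector computes q on the overlay
(Cartesian pairing) of two stratifications and classifies the joint effect
against the single-factor q's.

Continuous covariates are discretized with exact natural breaks (Fisher's
dynamic program minimizing within-class sum of squared deviations), and
areal values can be resampled onto a regular point lattice clipped to the
unit polygons before detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely.strtree import STRtree

from .errors import NumericalError, ValidationError

logger = logging.getLogger(__name__)

INTERACTION_CLASSES = (
    "nonlinear_weaken", "uni_weaken", "bi_enhance", "independent",
    "nonlinear_enhance",
)


@dataclass
class StrataAssignment:
    """Categorical layer h ∈ {1..L} over sample points."""

    labels: np.ndarray  # integer codes 0..L-1
    L: int
    breaks: np.ndarray | None = None     # natural-breaks boundaries, if derived
    categories: list | None = None       # original category values, if raw

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        codes = np.unique(self.labels)
        if self.L < 1:
            raise ValidationError("L must be >= 1")
        if len(codes) != self.L:
            raise ValidationError(
                f"stratification declares L={self.L} but {len(codes)} strata are non-empty"
            )

    @classmethod
    def from_categories(cls, values) -> "StrataAssignment":
        """Build strata directly from a categorical array."""
        cats, codes = np.unique(np.asarray(values), return_inverse=True)
        return cls(labels=codes, L=len(cats), categories=cats.tolist())


@dataclass
class QResult:
    q: float
    p: float
    N: int
    L: int
    N_h: np.ndarray
    sigma2_h: np.ndarray
    sigma2: float
    F: float
    noncentrality: float
    p_method: str = "noncentral_f"


@dataclass
class GridSample:
    """Regular lattice points carrying their containing unit's attributes."""

    points: np.ndarray            # (m, 2) coordinates
    unit_index: np.ndarray        # (m,) index into units
    units: list[str]
    values: pd.DataFrame          # (m, k) attributes inherited from units
    spacing: float


# ---------------------------------------------------------------------------
# grid sampling


def grid_sample(geoms: dict, values_by_unit: pd.DataFrame,
                spacing_km: float) -> GridSample:
    """Sample unit polygons on a regular lattice (cell-center offset).

    ``geoms`` maps unit id → polygon (planar km coordinates);
    ``values_by_unit`` is indexed by unit id. Every lattice point inside a
    unit inherits that unit's attribute row.
    """
    if spacing_km <= 0:
        raise ValueError("spacing must be positive")
    units = [str(u) for u in geoms]
    glist = list(geoms.values())
    minx = min(g.bounds[0] for g in glist)
    miny = min(g.bounds[1] for g in glist)
    maxx = max(g.bounds[2] for g in glist)
    maxy = max(g.bounds[3] for g in glist)
    xs = np.arange(minx + spacing_km / 2, maxx, spacing_km)
    ys = np.arange(miny + spacing_km / 2, maxy, spacing_km)
    from shapely.geometry import Point

    tree = STRtree(glist)
    pts, uidx = [], []
    for gx in xs:
        for gy in ys:
            p = Point(gx, gy)
            for j in tree.query(p):
                if glist[int(j)].covers(p):
                    pts.append((gx, gy))
                    uidx.append(int(j))
                    break
    if not pts:
        raise NumericalError(
            f"no lattice point at spacing {spacing_km} falls inside any unit; "
            "use a smaller spacing"
        )
    uidx = np.asarray(uidx)
    vals = values_by_unit.loc[[units[i] for i in uidx]].reset_index(drop=True)
    return GridSample(points=np.asarray(pts), unit_index=uidx, units=units,
                      values=vals, spacing=spacing_km)


# ---------------------------------------------------------------------------
# natural breaks (Fisher exact dynamic program)


def discretize_natural_breaks(values, k: int) -> StrataAssignment:
    """Optimal k-class 1-D classification minimizing within-class SSD.

    Classes are contiguous in value; breakpoints are exact (Fisher's
    dynamic program, equivalent to Jenks natural breaks at the optimum).
    """
    x = np.asarray(values, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    distinct = np.unique(x)
    if len(distinct) < k:
        raise ValidationError(f"need >= {k} distinct values, got {len(distinct)}")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(xs)

    # prefix sums for O(1) within-class SSD of xs[i..j]
    cs = np.concatenate(([0.0], np.cumsum(xs)))
    cs2 = np.concatenate(([0.0], np.cumsum(xs ** 2)))

    def ssd(i: int, j: int) -> float:  # inclusive endpoints
        m = j - i + 1
        s = cs[j + 1] - cs[i]
        return (cs2[j + 1] - cs2[i]) - s * s / m

    # dp[c][j] = min SSD of splitting xs[0..j] into c+1 classes
    dp = np.full((k, n), np.inf)
    back = np.zeros((k, n), dtype=int)
    for j in range(n):
        dp[0, j] = ssd(0, j)
    for c in range(1, k):
        for j in range(c, n):
            best, arg = np.inf, c
            for i in range(c, j + 1):
                cand = dp[c - 1, i - 1] + ssd(i, j)
                if cand < best:
                    best, arg = cand, i
            dp[c, j] = best
            back[c, j] = arg

    # recover class start indices
    bounds = []
    j = n - 1
    for c in range(k - 1, 0, -1):
        i = back[c, j]
        bounds.append(i)
        j = i - 1
    bounds = bounds[::-1]

    codes_sorted = np.zeros(n, dtype=int)
    for ci, b in enumerate(bounds):
        codes_sorted[b:] = ci + 1
    codes = np.empty(n, dtype=int)
    codes[order] = codes_sorted
    breaks = np.array([(xs[b - 1] + xs[b]) / 2 for b in bounds])
    return StrataAssignment(labels=codes, L=k, breaks=breaks)


# ---------------------------------------------------------------------------
# detectors


def _within_stats(y: np.ndarray, s: StrataAssignment):
    """Per-stratum counts, means and population variances."""
    N_h = np.bincount(s.labels, minlength=s.L).astype(float)
    if (N_h == 0).any():
        raise ValidationError("empty stratum")
    sums = np.bincount(s.labels, weights=y, minlength=s.L)
    means = sums / N_h
    sq = np.bincount(s.labels, weights=y ** 2, minlength=s.L)
    var_h = sq / N_h - means ** 2
    return N_h, means, np.maximum(var_h, 0.0)


def factor_q(y, s: StrataAssignment, p_method: str = "noncentral_f",
             n_perm: int = 999, seed=None) -> QResult:
    """Factor detector: q-statistic with significance.

    ``p_method``: ``"noncentral_f"`` (default; the approximation used by the
    reference Geodetector software) or ``"permutation"`` (seeded)."""
    y = np.asarray(y, dtype=float)
    if len(y) != len(s.labels):
        raise ValidationError("y and strata lengths differ")
    N = len(y)
    sigma2 = float(np.var(y))  # population variance
    if sigma2 == 0:
        raise NumericalError("zero total variance")
    N_h, means, var_h = _within_stats(y, s)
    ssw = float((N_h * var_h).sum())
    q = 1.0 - ssw / (N * sigma2)
    q = float(min(max(q, 0.0), 1.0))

    L = s.L
    if L == 1 or q >= 1.0:
        F = np.inf if q >= 1.0 and L > 1 else 0.0
        lam = 0.0
        p = 0.0 if q >= 1.0 and L > 1 else 1.0
    else:
        F = (N - L) / (L - 1) * q / (1.0 - q)
        lam = (float((means ** 2 * N_h).sum())
               - (float((np.sqrt(N_h) * means).sum()) ** 2) / N) / sigma2
        p = float(stats.ncf.sf(F, L - 1, N - L, max(lam, 0.0)))

    if p_method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            yp = rng.permutation(y)
            _, _, vh = _within_stats(yp, s)
            qp = 1.0 - float((N_h * vh).sum()) / (N * sigma2)
            if qp >= q - 1e-14:
                count += 1
        p = (1 + count) / (1 + n_perm)
    elif p_method != "noncentral_f":
        raise ValueError("p_method must be 'noncentral_f' or 'permutation'")

    return QResult(q=q, p=p, N=N, L=L, N_h=N_h, sigma2_h=var_h, sigma2=sigma2,
                   F=float(F), noncentrality=float(lam), p_method=p_method)


def ecological_detector(y, sA: StrataAssignment, sB: StrataAssignment,
                        alpha: float = 0.05):
    """Ecological detector: do two stratifications differ significantly?

    F is the ratio of the two within-stratum sums of squares (scaled by the
    sample counts), oriented so F ≥ 1, referred to F(N−1, N−1); returns
    ``(significant: bool, F, p)``.
    """
    y = np.asarray(y, dtype=float)
    N = len(y)
    if len(sA.labels) != N or len(sB.labels) != N:
        raise ValidationError("stratifications must cover the same samples")
    NA_h, _, varA = _within_stats(y, sA)
    NB_h, _, varB = _within_stats(y, sB)
    sswA = float((NA_h * varA).sum())
    sswB = float((NB_h * varB).sum())
    if sswA == 0 and sswB == 0:
        return False, 1.0, 1.0
    hi, lo = max(sswA, sswB), min(sswA, sswB)
    if lo == 0:
        return True, np.inf, 0.0
    F = hi / lo
    p = float(stats.f.sf(F, N - 1, N - 1))
    return bool(p < alpha), float(F), p


def interaction_detector(y, sA: StrataAssignment, sB: StrataAssignment):
    """Interaction detector: q of the overlay of two stratifications.

    The overlay's strata are the distinct (h_A, h_B) pairs present in the
    data. Returns ``(q_AB, interaction_class, q_A, q_B)`` where the class is
    one of ``nonlinear_weaken`` (q_AB < min), ``uni_weaken`` (between min
    and max), ``bi_enhance`` (> max), ``independent`` (= q_A + q_B within
    1e-9) or ``nonlinear_enhance`` (> sum).
    """
    y = np.asarray(y, dtype=float)
    qA = factor_q(y, sA).q
    qB = factor_q(y, sB).q
    pair = sA.labels.astype(np.int64) * (sB.labels.max() + 1) + sB.labels
    overlay = StrataAssignment.from_categories(pair)
    if overlay.L > len(y) / 2:
        logger.warning("overlay creates %d strata for %d samples (overfit overlay)",
                       overlay.L, len(y))
    qAB = factor_q(y, overlay).q

    tol = 1e-9
    lo, hi, sm = min(qA, qB), max(qA, qB), qA + qB
    if abs(qAB - sm) <= tol:
        cls = "independent"
    elif qAB > sm:
        cls = "nonlinear_enhance"
    elif qAB > hi:
        cls = "bi_enhance"
    elif qAB >= lo:
        cls = "uni_weaken"
    else:
        cls = "nonlinear_weaken"
    return float(qAB), cls, float(qA), float(qB)
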