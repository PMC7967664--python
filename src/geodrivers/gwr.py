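"""Geographically weighted regression and its multiscale extension.

GWR fits, at every location i, a weighted least-squares regression

    y = X β(uᵢ, vᵢ) + ε,   weights wᵢⱼ = exp(−(dᵢⱼ / b)²)

with a Gaussian kernel. The bandwidth b is either a fixed distance or
*adaptive*: a neighbour count k, with bᵢ the distance from location i to its
k-th nearest site (the focal site counts as the first). The fit is a linear
smoother ŷ = S y; its hat-matrix trace gives the effective number of
parameters (ENP), and bandwidths are selected by minimizing the
small-sample-corrected AICc

    AICc = 2n·ln(σ̂) + n·ln(2π) + n·(n + tr(S)) / (n − 2 − tr(S)),

with σ̂² = RSS/n (maximum-likelihood scale).

MGWR relaxes the single bandwidth: each additive term fⱼ = βⱼ(u,v)·xⱼ
(including the intercept) gets its own bandwidth, fitted by backfitting —
cycle over terms, regress the partial residual on one covariate with a
term-specific AICc-optimal bandwidth, until the normalized root-mean-square
change of the fitted values (SOC-f) drops below tolerance. Per-term smoother
matrices are chained through the iterations so that per-covariate ENP and
total ENP are exact for the converged smoother.

Covariates and response are z-scored by default (the convention of the
standard MGWR software, which keeps coefficient magnitudes comparable);
back-transformed raw-scale coefficients are available on both fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NumericalError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class KernelSpec:
    """Gaussian kernel, fixed-distance or adaptive (k nearest neighbours)."""

    mode: str = "adaptive"          # "adaptive" | "fixed"
    bandwidth: float = 0.0          # neighbour count (adaptive) or distance

    def __post_init__(self) -> None:
        if self.mode not in ("adaptive", "fixed"):
            raise ValueError("mode must be 'adaptive' or 'fixed'")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


def kernel_weights(dists, spec: KernelSpec) -> np.ndarray:
    """Gaussian kernel weights for one focal unit's distance vector.

    Adaptive mode takes bᵢ as the k-th smallest entry of ``dists`` (the
    focal unit's own zero distance included)."""
    d = np.asarray(dists, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    if spec.mode == "fixed":
        b = spec.bandwidth
    else:
        k = int(round(spec.bandwidth))
        if not 1 <= k <= len(d):
            raise ValueError(f"adaptive bandwidth {k} outside [1, {len(d)}]")
        b = np.sort(d)[k - 1]
        if b <= 0:
            b = np.sort(d)[-1] * 1e-6 + 1e-12
    return np.exp(-((d / b) ** 2))


def _kernel_matrix(D: np.ndarray, spec: KernelSpec) -> np.ndarray:
    if spec.mode == "fixed":
        return np.exp(-((D / spec.bandwidth) ** 2))
    k = int(round(spec.bandwidth))
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"adaptive bandwidth {k} outside [1, {n}]")
    b = np.sort(D, axis=1)[:, k - 1]
    b = np.where(b > 0, b, D.max() * 1e-6 + 1e-12)
    return np.exp(-((D / b[:, None]) ** 2))


def _distance_matrix(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def _aicc(n: int, rss: float, trS: float) -> float:
    if n - 2 - trS <= 0:
        return np.inf
    sigma_ml = np.sqrt(rss / n)
    if sigma_ml <= 0:
        return -np.inf
    return (2 * n * np.log(sigma_ml) + n * np.log(2 * np.pi)
            + n * (n + trS) / (n - 2 - trS))


@dataclass
class _Standardizer:
    y_mean: float
    y_sd: float
    x_mean: np.ndarray
    x_sd: np.ndarray


def _standardize(y, X):
    ym, ys = float(y.mean()), float(y.std(ddof=0))
    xm, xs = X.mean(axis=0), X.std(ddof=0, axis=0)
    if ys == 0 or (xs == 0).any():
        raise NumericalError("cannot z-score a constant column")
    return ((y - ym) / ys, (X - xm) / xs, _Standardizer(ym, ys, xm, xs))


@dataclass
class GWRFit:
    """A single-bandwidth GWR fit with hat-matrix diagnostics."""

    params: np.ndarray            # (n, p+1) local coefficients, intercept first
    names: list[str]
    fitted: np.ndarray
    residuals: np.ndarray
    hat: np.ndarray               # (n, n) smoother matrix S
    enp: float                    # tr(S)
    rss: float
    sigma: float                  # sqrt(RSS / (n - tr(S)))
    aicc: float
    r2: float
    adj_r2: float
    local_r2: np.ndarray
    spec: KernelSpec
    standardized: bool
    scaler: _Standardizer | None = None

    @property
    def n(self) -> int:
        return len(self.fitted)

    def raw_params(self) -> np.ndarray:
        """Coefficients on the raw data scale (undo z-scoring)."""
        if not self.standardized:
            return self.params
        s = self.scaler
        out = np.empty_like(self.params)
        out[:, 1:] = self.params[:, 1:] * s.y_sd / s.x_sd[None, :]
        out[:, 0] = (s.y_mean + s.y_sd * self.params[:, 0]
                     - (out[:, 1:] * s.x_mean[None, :]).sum(axis=1))
        return out


def fit_gwr(coords, y, X, spec: KernelSpec, names: list[str] | None = None,
            standardize: bool = False) -> GWRFit:
    """Fit GWR at every unit with the given kernel.

    ``coords``: (n, 2) planar; ``y``: (n,); ``X``: (n, p) covariates (an
    intercept column is added internally). Raises on singular local designs
    (bandwidth too small)."""
    coords = np.asarray(coords, float)
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if n <= p + 2:
        raise ValidationError(f"need n > p+2 (= {p + 2}) units, got {n}")
    if names is None:
        names = [f"x{j + 1}" for j in range(p)]
    scaler = None
    if standardize:
        y, X, scaler = _standardize(y, X)
    D = _distance_matrix(coords)
    if (D + np.eye(n)).min() <= 0:
        jitter = 1e-9 * max(D.max(), 1.0)
        logger.warning("duplicate coordinates; jittering distances by %g", jitter)
        D = D + jitter * (1 - np.eye(n))
    K = _kernel_matrix(D, spec)

    Xd = np.column_stack([np.ones(n), X])
    pp = p + 1
    # A[i] = Xdᵀ diag(K_i) Xd ; b[i] = Xdᵀ diag(K_i) y
    A = np.einsum("ij,jp,jq->ipq", K, Xd, Xd, optimize=True)
    bvec = np.einsum("ij,jp,j->ip", K, Xd, y, optimize=True)
    try:
        params = np.linalg.solve(A, bvec[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "singular local design; increase the bandwidth"
        ) from exc
    # hat rows: s_i = x_i A_i^{-1} Xdᵀ diag(K_i)
    hat = np.empty((n, n))
    for i in range(n):
        Ci = np.linalg.solve(A[i], (Xd * K[i][:, None]).T)  # (p+1, n)
        hat[i] = Xd[i] @ Ci
    fitted = (Xd * params).sum(axis=1)
    resid = y - fitted
    rss = float(resid @ resid)
    trS = float(np.trace(hat))
    if not (pp - 1e-6 <= trS <= n + 1e-6):
        logger.warning("ENP %.3f outside [p+1, n] = [%d, %d]", trS, pp, n)
    sigma = float(np.sqrt(rss / (n - trS))) if n > trS else np.nan
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - trS - 1) if n - trS - 1 > 0 else np.nan
    # local weighted R² at each focal unit
    local_r2 = np.empty(n)
    for i in range(n):
        w = K[i]
        ybar_w = float(w @ y / w.sum())
        tss_w = float(w @ (y - ybar_w) ** 2)
        rss_w = float(w @ resid ** 2)
        local_r2[i] = 1.0 - rss_w / tss_w if tss_w > 0 else np.nan
    return GWRFit(params=params, names=["intercept"] + list(names),
                  fitted=fitted, residuals=resid, hat=hat, enp=trS, rss=rss,
                  sigma=sigma, aicc=_aicc(n, rss, trS), r2=r2, adj_r2=adj_r2,
                  local_r2=local_r2, spec=spec, standardized=standardize,
                  scaler=scaler)


# ---------------------------------------------------------------------------
# bandwidth selection


@dataclass
class BandwidthSearch:
    bandwidth: float
    aicc: float
    trace: list            # [(bandwidth, aicc), ...] in evaluation order
    method: str            # "golden" | "grid"


def _gwr_aicc_only(D, y, Xd, spec: KernelSpec) -> float:
    """AICc of a GWR fit without assembling coefficient diagnostics."""
    n = Xd.shape[0]
    K = _kernel_matrix(D, spec)
    A = np.einsum("ij,jp,jq->ipq", K, Xd, Xd, optimize=True)
    try:
        fitted = np.empty(n)
        trS = 0.0
        for i in range(n):
            Ci = np.linalg.solve(A[i], (Xd * K[i][:, None]).T)
            si = Xd[i] @ Ci
            fitted[i] = si @ y
            trS += si[i]
    except np.linalg.LinAlgError:
        return np.inf
    rss = float(((y - fitted) ** 2).sum())
    return _aicc(n, rss, trS)


def select_bandwidth(coords, y, X, mode: str = "adaptive",
                     bounds: tuple | None = None,
                     standardize: bool = False) -> BandwidthSearch:
    """Golden-section AICc minimization of the GWR bandwidth.

    Adaptive candidates are rounded to integer neighbour counts in
    [p+2, n]; ties break toward the smaller bandwidth (more local detail).
    If the evaluated trace is non-unimodal a warning is issued and an
    exhaustive grid scan is used instead (always feasible in adaptive
    mode)."""
    coords = np.asarray(coords, float)
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if standardize:
        y, X, _ = _standardize(y, X)
    Xd = np.column_stack([np.ones(n), X])
    D = _distance_matrix(coords)

    if bounds is None:
        if mode == "adaptive":
            bounds = (p + 3, n)
        else:
            dmax = D.max()
            bounds = (dmax / n, 2 * dmax)
    lo, hi = bounds
    if lo >= hi:
        raise ValueError(f"invalid bandwidth bounds {bounds}")

    cache: dict[float, float] = {}
    trace: list = []

    def f(b: float) -> float:
        if mode == "adaptive":
            b = float(int(round(b)))
        if b not in cache:
            spec = KernelSpec(mode=mode, bandwidth=b)
            cache[b] = _gwr_aicc_only(D, y, Xd, spec)
            trace.append((b, cache[b]))
        return cache[b]

    _bracketed_golden(f, float(lo), float(hi), integer=(mode == "adaptive"))
    candidates = sorted(cache.items(), key=lambda kv: (kv[1], kv[0]))
    best_b, best_a = candidates[0]

    # unimodality check along the evaluated bandwidths
    by_b = sorted(cache.items())
    vals = [v for _, v in by_b]
    sign_changes = 0
    for i in range(1, len(vals) - 1):
        if vals[i] < vals[i - 1] and vals[i] < vals[i + 1]:
            sign_changes += 1
    if sign_changes > 1:
        logger.warning("non-unimodal AICc trace; falling back to a grid scan")
        if mode == "adaptive":
            grid = range(int(lo), int(hi) + 1)
        else:
            grid = np.linspace(lo, hi, 100)
        for g in grid:
            f(float(g))
        candidates = sorted(cache.items(), key=lambda kv: (kv[1], kv[0]))
        best_b, best_a = candidates[0]
        return BandwidthSearch(best_b, best_a, trace, "grid")
    return BandwidthSearch(best_b, best_a, trace, "golden")


# ---------------------------------------------------------------------------
# MGWR


@dataclass
class MGWRFit:
    """A multiscale GWR fit: one bandwidth (and smoother) per term."""

    params: np.ndarray            # (n, p+1) local coefficients, intercept first
    names: list[str]
    bandwidths: np.ndarray        # per-term adaptive neighbour counts / distances
    enp_terms: np.ndarray         # per-term tr(S_j)
    fitted: np.ndarray
    residuals: np.ndarray
    hat: np.ndarray
    enp: float
    rss: float
    sigma: float
    aicc: float
    r2: float
    adj_r2: float
    converged: bool
    trace: list                   # [(iteration, SOC-f score), ...]
    spec_mode: str
    standardized: bool
    scaler: _Standardizer | None = None

    @property
    def n(self) -> int:
        return len(self.fitted)

    def raw_params(self) -> np.ndarray:
        if not self.standardized:
            return self.params
        s = self.scaler
        out = np.empty_like(self.params)
        out[:, 1:] = self.params[:, 1:] * s.y_sd / s.x_sd[None, :]
        out[:, 0] = (s.y_mean + s.y_sd * self.params[:, 0]
                     - (out[:, 1:] * s.x_mean[None, :]).sum(axis=1))
        return out


def _single_term_gwr(K: np.ndarray, x: np.ndarray, e: np.ndarray):
    """One-covariate no-intercept GWR of e on x; returns (beta, L)."""
    den = K @ (x * x)
    num = K @ (x * e)
    beta = num / den
    L = (x[:, None] * (K * x[None, :])) / den[:, None]
    return beta, L


def _single_term_aicc(D: np.ndarray, x: np.ndarray, e: np.ndarray,
                      spec: KernelSpec) -> float:
    n = len(x)
    K = _kernel_matrix(D, spec)
    den = K @ (x * x)
    if (den <= 0).any():
        return np.inf
    beta = (K @ (x * e)) / den
    fitted = x * beta
    trL = float((x * x * np.diag(K) / den).sum())
    rss = float(((e - fitted) ** 2).sum())
    return _aicc(n, rss, trL)


def _bracketed_golden(f, lo: float, hi: float, integer: bool,
                      coarse: int = 16) -> float:
    """Coarse geometric grid to bracket the minimum, then golden refinement.

    AICc bandwidth profiles are not always unimodal (a deep local minimum
    can coexist with a shallow dip near the global end), so a pure golden
    section can collapse to the wrong side; the coarse scan guards the
    bracket. Integer (adaptive) ranges up to 256 candidates are scanned
    exhaustively instead. Ties break toward the smaller bandwidth."""
    if integer and hi - lo <= 256:
        for b in range(int(np.ceil(lo)), int(hi) + 1):
            f(float(b))
        return None
    grid = np.geomspace(max(lo, 1e-12), hi, coarse)
    if integer:
        grid = np.unique(np.round(grid))
    vals = [f(float(g)) for g in grid]
    k = int(np.argmin(vals))
    a = float(grid[max(k - 1, 0)])
    b_ = float(grid[min(k + 1, len(grid) - 1)])
    gr = (np.sqrt(5) - 1) / 2
    c = b_ - gr * (b_ - a)
    d = a + gr * (b_ - a)
    tol = 0.5 if integer else (hi - lo) * 1e-4
    while b_ - a > tol:
        if f(c) <= f(d):
            b_ = d
        else:
            a = c
        c = b_ - gr * (b_ - a)
        d = a + gr * (b_ - a)
        if integer and int(round(c)) == int(round(d)):
            break
    return None  # caller takes the cache argmin


def _select_term_bandwidth(D, x, e, mode, bounds) -> float:
    lo, hi = bounds
    cache: dict[float, float] = {}

    def f(b):
        if mode == "adaptive":
            b = float(int(round(b)))
        if b not in cache:
            cache[b] = _single_term_aicc(D, x, e, KernelSpec(mode, b))
        return cache[b]

    _bracketed_golden(f, lo, hi, integer=(mode == "adaptive"))
    return min(cache.items(), key=lambda kv: (kv[1], kv[0]))[0]


def _gwr_term_smoothers(D, Xd, y, spec: KernelSpec):
    """GWR coefficients plus the exact per-term smoother decomposition."""
    n, pp = Xd.shape
    K = _kernel_matrix(D, spec)
    A = np.einsum("ij,jp,jq->ipq", K, Xd, Xd, optimize=True)
    params = np.empty((n, pp))
    S_terms = [np.empty((n, n)) for _ in range(pp)]
    for i in range(n):
        Ci = np.linalg.solve(A[i], (Xd * K[i][:, None]).T)  # (pp, n)
        params[i] = Ci @ y
        for j in range(pp):
            S_terms[j][i] = Xd[i, j] * Ci[j]
    return params, S_terms


def fit_mgwr(coords, y, X, names: list[str] | None = None,
             mode: str = "adaptive", tol: float = 1e-5, max_iter: int = 200,
             standardize: bool = True, bandwidths: list | None = None,
             select_iters: int | None = 5, init: str = "gwr") -> MGWRFit:
    """Backfit an MGWR model with covariate-specific bandwidths.

    Terms (intercept included) start from a GWR decomposition at the
    AICc-optimal single bandwidth (``init="ols"`` for a flat start); each
    backfitting sweep regresses every term's partial residual on its
    covariate with an AICc-optimal bandwidth, until the SOC-f score (root
    mean squared change of the fitted values, normalized by their RMS) falls
    below ``tol``. Bandwidths are re-selected during the first
    ``select_iters`` sweeps (and whenever still changing), then frozen so
    late sweeps only polish the coefficient surfaces; pass
    ``bandwidths`` to skip selection entirely (e.g. to force a common
    bandwidth). Smoother matrices are chained exactly, so per-term ENP
    reflects the full backfitting history.
    """
    coords = np.asarray(coords, float)
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if n <= p + 2:
        raise ValidationError(f"need n > p+2 (= {p + 2}) units, got {n}")
    if names is None:
        names = [f"x{j + 1}" for j in range(p)]
    scaler = None
    if standardize:
        y, X, scaler = _standardize(y, X)
    Xd = np.column_stack([np.ones(n), X])
    pp = p + 1
    D = _distance_matrix(coords)

    fixed_bw = bandwidths is not None
    if init == "gwr" and not fixed_bw:
        # start from a single-bandwidth GWR decomposition so every term
        # already carries a plausible spatial pattern
        cache: dict[float, float] = {}

        def fb(b):
            if mode == "adaptive":
                b = float(int(round(b)))
            if b not in cache:
                cache[b] = _gwr_aicc_only(D, y, Xd, KernelSpec(mode, b))
            return cache[b]

        if mode == "adaptive":
            lo0, hi0 = min(p + 3, n - 1), n
        else:
            lo0, hi0 = D.max() / n, 2 * D.max()
        _bracketed_golden(fb, float(lo0), float(hi0),
                          integer=(mode == "adaptive"))
        bw0 = min(cache.items(), key=lambda kv: (kv[1], kv[0]))[0]
        betas0, S_terms = _gwr_term_smoothers(D, Xd, y, KernelSpec(mode, bw0))
        terms = Xd * betas0
        beta0 = betas0.mean(axis=0)
    elif init in ("ols", "gwr"):
        M = np.linalg.solve(Xd.T @ Xd, Xd.T)      # (p+1, n)
        beta0 = M @ y
        terms = Xd * beta0[None, :]               # (n, p+1) additive terms
        S_terms = [np.outer(Xd[:, j], M[j]) for j in range(pp)]
    else:
        raise ValueError("init must be 'gwr' or 'ols'")
    if fixed_bw and len(bandwidths) != pp:
        raise ValueError(f"need {pp} bandwidths (intercept first)")
    bw = np.array([float(b) for b in bandwidths], dtype=float) if fixed_bw \
        else np.full(pp, np.nan)
    if mode == "adaptive":
        bounds = (min(p + 3, n - 1), n)
    else:
        dmax = D.max()
        bounds = (dmax / n, 2 * dmax)

    betas = betas0.copy() if (init == "gwr" and not fixed_bw) \
        else np.tile(beta0, (n, 1))
    fitted = terms.sum(axis=1)
    trace: list = []
    converged = False
    Ks: dict[float, np.ndarray] = {}

    for it in range(1, max_iter + 1):
        fitted_old = fitted.copy()
        for j in range(pp):
            xj = Xd[:, j]
            e_j = y - fitted + terms[:, j]
            if not fixed_bw and (it <= (select_iters or max_iter)
                                 or np.isnan(bw[j])):
                bw[j] = _select_term_bandwidth(D, xj, e_j, mode, bounds)
            key = bw[j]
            if key not in Ks:
                Ks[key] = _kernel_matrix(D, KernelSpec(mode, key))
            beta_j, L_j = _single_term_gwr(Ks[key], xj, e_j)
            S_rest = sum(S_terms[k] for k in range(pp) if k != j)
            S_terms[j] = L_j @ (np.eye(n) - S_rest)
            betas[:, j] = beta_j
            terms[:, j] = xj * beta_j
            fitted = terms.sum(axis=1)
        denom = np.sqrt((fitted ** 2).mean())
        score = np.sqrt(((fitted - fitted_old) ** 2).mean()) / max(denom, 1e-12)
        trace.append((it, float(score)))
        if score < tol:
            converged = True
            break
    if not converged:
        logger.warning("MGWR backfitting did not converge in %d iterations "
                       "(last score %.3g)", max_iter, trace[-1][1])

    S = sum(S_terms)
    resid = y - fitted
    rss = float(resid @ resid)
    trS = float(np.trace(S))
    enp_terms = np.array([float(np.trace(Sj)) for Sj in S_terms])
    sigma = float(np.sqrt(rss / (n - trS))) if n > trS else np.nan
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - trS - 1) if n - trS - 1 > 0 else np.nan
    return MGWRFit(params=betas, names=["intercept"] + list(names),
                   bandwidths=bw, enp_terms=enp_terms, fitted=fitted,
                   residuals=resid, hat=S, enp=trS, rss=rss, sigma=sigma,
                   aicc=_aicc(n, rss, trS), r2=r2, adj_r2=adj_r2,
                   converged=converged, trace=trace, spec_mode=mode,
                   standardized=standardize, scaler=scaler)


# ---------------------------------------------------------------------------
# summaries


def compare_models(gwr: GWRFit, mgwr: MGWRFit) -> pd.DataFrame:
    """Side-by-side diagnostic table for a GWR and an MGWR fit."""
    if gwr.n != mgwr.n:
        raise ValidationError("fits are not on the same panel")
    rows = {
        "Residual Squares": (gwr.rss, mgwr.rss),
        "Effective Number": (gwr.enp, mgwr.enp),
        "Sigma": (gwr.sigma, mgwr.sigma),
        "AICc": (gwr.aicc, mgwr.aicc),
        "R2": (gwr.r2, mgwr.r2),
        "R2Adjusted": (gwr.adj_r2, mgwr.adj_r2),
    }
    return pd.DataFrame(rows, index=["GWR", "MGWR"]).T.rename_axis("Analysis Index")


def regional_mean_coefficients(fit, groups, include_intercept: bool = False,
                               raw_scale: bool = False) -> pd.DataFrame:
    """Arithmetic mean of local coefficients within each group label.

    Adds a ``strongest`` column naming each group's largest-|mean|
    covariate (intercept excluded from the argmax)."""
    groups = np.asarray(groups)
    params = fit.raw_params() if raw_scale else fit.params
    if len(groups) != params.shape[0]:
        raise ValidationError("group labels do not match fit size")
    cols = fit.names
    df = pd.DataFrame(params, columns=cols)
    df["group"] = groups
    counts = df.groupby("group").size()
    if (counts == 0).any():
        raise ValidationError("empty group")
    means = df.groupby("group").mean()
    covs = [c for c in cols if c != "intercept"]
    means["strongest"] = means[covs].abs().idxmax(axis=1)
    if not include_intercept:
        means = means.drop(columns=["intercept"])
    return means
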