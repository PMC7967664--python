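"""Global and local Moran's I over binary contiguity weights.

The global statistic is

    I = n · Σᵢ Σⱼ Wᵢⱼ (xᵢ − x̄)(xⱼ − x̄) / (Σᵢ (xᵢ − x̄)² · S₀),

with S₀ = Σᵢⱼ Wᵢⱼ, expectation E[I] = −1/(n−1) and variance under either
the normality or the randomization assumption (Cliff–Ord moments); the
standard score is Z = (I − E[I]) / √Var(I). The local decomposition

    Iᵢ = n (xᵢ − x̄) Σⱼ Wᵢⱼ (xⱼ − x̄) / Σᵢ (xᵢ − x̄)²

satisfies Σᵢ Iᵢ = S₀ · I exactly. Local significance uses conditional
permutation (hold unit i, permute the remaining values over its neighbour
positions); cluster labels follow the Moran-scatterplot quadrants: H–H
("hot zone") and L–L ("cold zone") for positive association, H–L / L–H for
outliers, with two significance tiers |Z| ≥ 1.96 and |Z| ≥ 2.58.

Note: Moran's I is often described as ranging over [−1, 1]; that bound is
not exact for arbitrary weight matrices, so values outside it are warned
about, never clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NumericalError
from .weights import SpatialWeights

logger = logging.getLogger(__name__)

#: significance tiers (95% and 99% two-sided normal thresholds)
Z_TIERS = (1.96, 2.58)


@dataclass
class MoranResult:
    I: float
    EI: float
    VarI: float
    Z: float
    p: float
    n: int
    S0: float
    variance_assumption: str = "randomization"
    p_perm: float | None = None
    n_perm: int | None = None


@dataclass
class LocalMoranResult:
    """Per-unit local Moran's I with permutation inference."""

    table: pd.DataFrame  # unit, I_i, Z_i, p_i, label, lag, z (deviation)
    n_perm: int
    global_I: float
    S0: float

    def labels(self) -> pd.Series:
        return self.table.set_index("unit")["label"]


def _deviations(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be a 1-D array")
    return x - x.mean()


def _check(values, w: SpatialWeights) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if len(x) != w.n:
        raise ValueError(f"{len(x)} values for {w.n} units")
    if w.n < 3:
        raise NumericalError("Moran's I needs at least 3 units")
    if np.var(x) == 0:
        raise NumericalError("constant field: sample variance is zero")
    if w.S0 == 0:
        raise NumericalError("weights have no links (S0 = 0)")
    return x


def _moran_I(z: np.ndarray, W: np.ndarray, S0: float) -> float:
    n = len(z)
    return float(n * z @ W @ z / (z @ z) / S0)


def global_moran(values, w: SpatialWeights,
                 variance: str = "randomization") -> MoranResult:
    """Global Moran's I with analytic Z and two-sided normal p-value.

    ``variance`` selects the null moment assumption: ``"randomization"``
    (default; conditions on the empirical values) or ``"normality"``.
    """
    if variance not in ("randomization", "normality"):
        raise ValueError("variance must be 'randomization' or 'normality'")
    x = _check(values, w)
    z = x - x.mean()
    W = w.W
    n, S0 = w.n, w.S0
    I = _moran_I(z, W, S0)
    if abs(I) > 1 + 1e-12:
        logger.warning("Moran's I = %.4f lies outside [-1, 1]", I)
    EI = -1.0 / (n - 1)

    # Cliff-Ord weight sums (symmetric binary W: S1 = 2*S0)
    S1 = 0.5 * ((W + W.T) ** 2).sum()
    S2 = ((W.sum(axis=0) + W.sum(axis=1)) ** 2).sum()
    if variance == "normality":
        VarI = (n * n * S1 - n * S2 + 3 * S0 * S0) / (S0 * S0 * (n * n - 1)) - EI * EI
    else:
        b2 = n * (z ** 4).sum() / (z ** 2).sum() ** 2
        num = (n * ((n * n - 3 * n + 3) * S1 - n * S2 + 3 * S0 * S0)
               - b2 * ((n * n - n) * S1 - 2 * n * S2 + 6 * S0 * S0))
        VarI = num / ((n - 1) * (n - 2) * (n - 3) * S0 * S0) - EI * EI
    Z = (I - EI) / np.sqrt(VarI)
    p = 2 * stats.norm.sf(abs(Z))
    return MoranResult(I=I, EI=EI, VarI=float(VarI), Z=float(Z), p=float(p),
                       n=n, S0=S0, variance_assumption=variance)


def global_moran_permutation(values, w: SpatialWeights, n_perm: int = 999,
                             seed=None) -> MoranResult:
    """Global Moran's I with an empirical (pseudo) permutation p-value.

    pseudo-p = (1 + #{|I_perm − E[I]| ≥ |I_obs − E[I]|}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    res = global_moran(values, w)
    x = np.asarray(values, dtype=float)
    z = x - x.mean()
    rng = np.random.default_rng(seed)
    n = w.n
    sims = np.empty(n_perm)
    denom = z @ z
    for k in range(n_perm):
        zp = z[rng.permutation(n)]
        sims[k] = n * zp @ w.W @ zp / denom / w.S0
    extreme = int((np.abs(sims - res.EI) >= abs(res.I - res.EI) - 1e-14).sum())
    res.p_perm = (1 + extreme) / (1 + n_perm)
    res.n_perm = n_perm
    return res


def local_moran(values, w: SpatialWeights, n_perm: int = 999, seed=None,
                z_threshold: float = 1.96) -> LocalMoranResult:
    """Local Moran's Iᵢ with conditional-permutation inference and labels.

    Units with zero neighbours get undefined Iᵢ (NaN) and label ``NS`` with
    a warning. Labels are assigned by the quadrant of (own deviation,
    spatial lag of deviations) when |Zᵢ| ≥ ``z_threshold``.
    """
    x = _check(values, w)
    z = x - x.mean()
    n = w.n
    W = w.W
    denom = float(z @ z)
    lag = W @ z
    I_i = n * z * lag / denom
    card = W.sum(axis=1).astype(int)

    rng = np.random.default_rng(seed)
    Z_i = np.full(n, np.nan)
    p_i = np.full(n, np.nan)
    for i in range(n):
        k = card[i]
        if k == 0:
            logger.warning("unit %s has no neighbours; local I undefined", w.units[i])
            I_i[i] = np.nan
            continue
        others = np.delete(z, i)
        # random k-subsets of the other deviations, one per permutation
        r = rng.random((n_perm, n - 1))
        idx = np.argpartition(r, k - 1, axis=1)[:, :k]
        lag_perm = others[idx].sum(axis=1)
        sims = n * z[i] * lag_perm / denom
        mu, sd = sims.mean(), sims.std(ddof=1)
        Z_i[i] = (I_i[i] - mu) / sd if sd > 0 else 0.0
        extreme = int((np.abs(sims - mu) >= abs(I_i[i] - mu) - 1e-14).sum())
        p_i[i] = (1 + extreme) / (1 + n_perm)

    labels = _quadrant_labels(z, lag, Z_i, z_threshold)
    table = pd.DataFrame({
        "unit": w.units, "I_i": I_i, "Z_i": Z_i, "p_i": p_i,
        "label": labels, "z": z, "lag": lag,
    })
    gI = _moran_I(z, W, w.S0)
    return LocalMoranResult(table=table, n_perm=n_perm, global_I=gI, S0=w.S0)


def _quadrant_labels(z, lag, Z_i, threshold) -> list[str]:
    labels = []
    for zi, li, Zi in zip(z, lag, Z_i):
        if not np.isfinite(Zi) or abs(Zi) < threshold:
            labels.append("NS")
        elif zi > 0 and li > 0:
            labels.append("HH")
        elif zi < 0 and li < 0:
            labels.append("LL")
        elif zi > 0:
            labels.append("HL")
        else:
            labels.append("LH")
    return labels


def classify_clusters(res: LocalMoranResult,
                      alpha_levels: tuple = Z_TIERS) -> pd.DataFrame:
    """Cluster typology at multiple |Z| tiers (default 1.96 and 2.58).

    Returns the per-unit table with one significance column per tier; H–H
    units are "hot zones", L–L units "cold zones". A |Z| exactly at a tier
    counts as significant (≥ comparison).
    """
    tab = res.table.copy()
    for thr in alpha_levels:
        labels = _quadrant_labels(tab["z"].to_numpy(), tab["lag"].to_numpy(),
                                  tab["Z_i"].to_numpy(), thr - 1e-12)
        tab[f"label_z{thr:g}"] = labels
    tab["hot_zone"] = tab[f"label_z{alpha_levels[0]:g}"] == "HH"
    tab["cold_zone"] = tab[f"label_z{alpha_levels[0]:g}"] == "LL"
    return tab
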