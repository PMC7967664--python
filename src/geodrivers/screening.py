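"""Covariate pre-selection: correlation clustering and VIF filtering.

The screen mirrors a two-step practice: (1) compute the Pearson correlation
matrix of candidate covariates (plus the response), single-linkage cluster
the covariates on the distance 1 − |r| and drop near-duplicates that merge
earliest (e.g. minimum vs. average temperature); (2) compute variance
inflation factors VIF_j = 1/(1 − R_j²) on the survivors and fail any
covariate above the threshold (default 5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import NumericalError, ValidationError


def correlation_matrix(df: pd.DataFrame, columns: list[str] | None = None,
                       method: str = "pearson") -> pd.DataFrame:
    """Pearson correlation matrix over the given columns (response included).

    Raises on constant columns (their correlation is undefined)."""
    if method != "pearson":
        raise ValueError("only Pearson correlation is supported")
    sub = df[columns] if columns is not None else df
    sub = sub.select_dtypes(include=[np.number])
    if len(sub) < 3:
        raise ValidationError("need at least 3 complete rows")
    stds = sub.std(ddof=0)
    constant = stds[stds == 0].index.tolist()
    if constant:
        raise NumericalError(f"constant column(s): {constant}")
    return sub.corr(method="pearson")


@dataclass
class VariableClustering:
    """Single-linkage merge tree over variables with distance 1 − |r|."""

    variables: list[str]
    linkage: np.ndarray           # scipy linkage matrix
    distance: pd.DataFrame

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def flat_groups(self, cut: float) -> dict[str, int]:
        """Group id per variable, cutting the tree at the given distance."""
        labels = hierarchy.fcluster(self.linkage, t=cut, criterion="distance")
        return dict(zip(self.variables, labels.tolist()))

    def earliest_merge(self) -> tuple[str, str, float]:
        """The first pair to merge (the most redundant variables)."""
        i, j, h = self.linkage[0, 0], self.linkage[0, 1], self.linkage[0, 2]
        return self.variables[int(i)], self.variables[int(j)], float(h)

    def redundant(self, cut: float) -> list[str]:
        """Variables droppable at the cut: all but the first member of each
        multi-member group (input order kept)."""
        groups = self.flat_groups(cut)
        seen, drop = set(), []
        for v in self.variables:
            g = groups[v]
            if g in seen:
                drop.append(v)
            else:
                seen.add(g)
        return drop

    def to_tree_json(self) -> list[dict]:
        return [
            {"left": int(a), "right": int(b), "height": float(h), "size": int(s)}
            for a, b, h, s in self.linkage
        ]


def cluster_variables(corr: pd.DataFrame, linkage: str = "single",
                      distance: str = "abs") -> VariableClustering:
    """Hierarchically cluster variables on correlation distance.

    ``distance="abs"`` uses 1 − |r| (strong negative correlates cluster
    too); ``distance="signed"`` uses 1 − r."""
    if distance == "abs":
        D = 1.0 - corr.abs()
    elif distance == "signed":
        D = 1.0 - corr
    else:
        raise ValueError("distance must be 'abs' or 'signed'")
    D = D.clip(lower=0.0)
    np.fill_diagonal(D.values, 0.0)
    Z = hierarchy.linkage(squareform(D.to_numpy(), checks=False), method=linkage)
    return VariableClustering(variables=list(corr.columns), linkage=Z, distance=D)


def vif(df: pd.DataFrame, covariates: list[str] | None = None,
        threshold: float = 5.0) -> pd.DataFrame:
    """Variance inflation factors with a pass/fail state column.

    VIF_j = 1/(1 − R_j²) from regressing covariate j (with intercept) on the
    others. Perfect collinearity reports +inf and Failed. Returns a table
    with columns ``Variable, VIFs, State``.
    """
    cols = list(covariates) if covariates is not None else list(df.columns)
    X = df[cols].to_numpy(float)
    n, k = X.shape
    if n < k + 2:
        raise ValidationError(f"need at least {k + 2} rows for {k} covariates")
    out = []
    for j, name in enumerate(cols):
        yj = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        beta, _, _, _ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ beta
        tss = float(((yj - yj.mean()) ** 2).sum())
        if tss == 0:
            raise NumericalError(f"constant covariate {name!r}")
        r2 = 1.0 - float((resid ** 2).sum()) / tss
        v = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        out.append({"Variable": name, "VIFs": v,
                    "State": "Pass" if v <= threshold else "Failed"})
    table = pd.DataFrame(out)
    table.attrs["threshold"] = threshold
    return table
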