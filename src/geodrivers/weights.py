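"""Binary contiguity weights over areal units.

Moran statistics here use the weights *binary* (0/1, symmetric, zero
diagonal), not row-standardized; row standardization is available but off by
default. Units with no neighbours ("islands", which real study areas such as
archipelago cities do produce) are recorded and can be repaired by linking
each island to its nearest unit by centroid distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.strtree import STRtree

from .errors import ValidationError, WeightsError

logger = logging.getLogger(__name__)


@dataclass
class SpatialWeights:
    """Symmetric binary contiguity matrix with island bookkeeping."""

    units: list[str]
    W: np.ndarray
    islands: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        n = len(self.units)
        if W.shape != (n, n):
            raise WeightsError(f"W shape {W.shape} does not match {n} units")
        if not np.array_equal(W, W.T):
            raise WeightsError("W must be symmetric")
        if np.diag(W).any():
            raise WeightsError("W must have a zero diagonal")
        if not np.isin(W, (0.0, 1.0)).all():
            raise WeightsError("W entries must be binary 0/1")
        self.W = W

    @property
    def n(self) -> int:
        return len(self.units)

    @property
    def S0(self) -> float:
        return float(self.W.sum())

    def neighbor_counts(self) -> np.ndarray:
        return self.W.sum(axis=1)

    def current_islands(self) -> list[str]:
        """Units with zero row-sum in the current matrix."""
        return [u for u, c in zip(self.units, self.neighbor_counts()) if c == 0]

    def row_standardized(self) -> np.ndarray:
        """Row-standardized copy of W (island rows stay zero)."""
        rs = self.neighbor_counts()
        out = self.W.copy()
        nz = rs > 0
        out[nz] /= rs[nz, None]
        return out

    def to_triplets(self) -> pd.DataFrame:
        """Sparse triplet export (unit_a, unit_b, weight), upper triangle."""
        ii, jj = np.nonzero(np.triu(self.W))
        return pd.DataFrame({
            "unit_a": [self.units[i] for i in ii],
            "unit_b": [self.units[j] for j in jj],
            "weight": self.W[ii, jj],
        })


def _finalize(units, W, islands, coords, repair) -> SpatialWeights:
    w = SpatialWeights(list(units), W, islands)
    if w.n >= 2 and w.S0 == 0:
        if repair and coords is not None:
            return repair_islands(w, coords)
        raise WeightsError(
            "all units are islands (no adjacency); enable island repair with coordinates"
        )
    if islands and repair:
        if coords is None:
            raise WeightsError("island repair requested but no coordinates given")
        return repair_islands(w, coords)
    return w


def weights_from_adjacency(pairs, units, coords=None, repair: bool = False) -> SpatialWeights:
    """Build weights from an explicit list of adjacent unit pairs.

    Symmetric closure is applied; self-pairs are ignored with a warning.
    Unknown units raise. With ``repair=True`` and ``coords`` (n×2 array
    aligned with ``units``), islands are linked to their nearest unit.
    """
    units = [str(u) for u in units]
    index = {u: i for i, u in enumerate(units)}
    if len(index) != len(units):
        raise ValidationError("unit list contains duplicates")
    n = len(units)
    W = np.zeros((n, n))
    for a, b in pairs:
        a, b = str(a), str(b)
        if a not in index or b not in index:
            raise ValidationError(f"adjacency pair ({a}, {b}) references unknown unit")
        if a == b:
            logger.warning("ignoring self-pair (%s, %s)", a, b)
            continue
        W[index[a], index[b]] = W[index[b], index[a]] = 1.0
    islands = [u for i, u in enumerate(units) if W[i].sum() == 0]
    return _finalize(units, W, islands, coords, repair)


def weights_from_polygons(geoms: dict, rule: str = "queen",
                          coords=None, repair: bool = False) -> SpatialWeights:
    """Contiguity weights from unit polygons.

    ``geoms`` maps unit id → shapely geometry. Under ``queen`` two units are
    neighbours when their boundaries share at least one point; under
    ``rook`` they must share a boundary segment of positive length.
    """
    if rule not in ("queen", "rook"):
        raise ValueError("rule must be 'queen' or 'rook'")
    if not geoms:
        raise ValidationError("empty geometry collection")
    units = [str(u) for u in geoms]
    glist = list(geoms.values())
    for u, g in zip(units, glist):
        if g is None or g.is_empty or not g.is_valid:
            raise ValidationError(f"invalid or empty geometry for unit {u!r}")
    n = len(units)
    W = np.zeros((n, n))
    tree = STRtree(glist)
    for i, g in enumerate(glist):
        for j in tree.query(g):
            j = int(j)
            if j <= i:
                continue
            inter = g.intersection(glist[j])
            if inter.is_empty:
                continue
            touch = inter.length > 0 if rule == "rook" else True
            if touch:
                W[i, j] = W[j, i] = 1.0
    islands = [u for i, u in enumerate(units) if W[i].sum() == 0]
    if coords is None:
        coords = np.array([[g.centroid.x, g.centroid.y] for g in glist])
    return _finalize(units, W, islands, coords, repair)


def repair_islands(w: SpatialWeights, coords) -> SpatialWeights:
    """Link each island to its nearest non-self unit (symmetric edge).

    The original island list is preserved for reporting. A weights object
    without islands is returned unchanged.
    """
    if w.n < 2:
        raise WeightsError("cannot repair islands with fewer than 2 units")
    current = w.current_islands()
    if not current:
        return w
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (w.n, 2):
        raise ValidationError(f"coords must be ({w.n}, 2)")
    W = w.W.copy()
    index = {u: i for i, u in enumerate(w.units)}
    for u in current:
        i = index[u]
        d = np.hypot(coords[:, 0] - coords[i, 0], coords[:, 1] - coords[i, 1])
        d[i] = np.inf
        j = int(np.argmin(d))
        W[i, j] = W[j, i] = 1.0
        logger.info("island %s linked to nearest unit %s", u, w.units[j])
    merged = sorted(set(w.islands) | set(current))
    return SpatialWeights(list(w.units), W, merged)


def read_adjacency_csv(path) -> list[tuple[str, str]]:
    """Read a two-column adjacency CSV (unit_a, unit_b) into a pair list."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError("adjacency CSV needs two columns")
    a, b = df.columns[:2]
    return list(zip(df[a].astype(str), df[b].astype(str)))
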