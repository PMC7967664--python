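import numpy as np
import pytest

from geodrivers.weights import SpatialWeights


def lattice_weights(rows: int, cols: int, rule: str = "rook") -> SpatialWeights:
    """Rook/queen weights on a regular lattice, built by direct enumeration
    (independent of the polygon-based constructor)."""
    n = rows * cols
    W = np.zeros((n, n))
    idx = lambda r, c: r * cols + c
    for r in range(rows):
        for c in range(cols):
            steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
            if rule == "queen":
                steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
            for dr, dc in steps:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    W[idx(r, c), idx(rr, cc)] = 1.0
    units = [f"u{r}_{c}" for r in range(rows) for c in range(cols)]
    return SpatialWeights(units, W)


def lattice_coords(rows: int, cols: int, spacing: float = 1.0) -> np.ndarray:
    return np.array([[c * spacing, r * spacing]
                     for r in range(rows) for c in range(cols)])


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def rook4():
    """2x2 rook lattice."""
    return lattice_weights(2, 2, "rook")


@pytest.fixture
def queen36():
    """6x6 queen lattice."""
    return lattice_weights(6, 6, "queen")
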