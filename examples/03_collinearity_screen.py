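"""Covariate screening: correlation clustering then VIF filtering.

Duplicated meteorological-style covariates merge first in the single-linkage
tree and are dropped; the survivors are checked against a VIF threshold of 5.
"""

import numpy as np
import pandas as pd

from geodrivers import cluster_variables, correlation_matrix, vif

rng = np.random.default_rng(0)
n = 400
t_mean = rng.normal(size=n)
df = pd.DataFrame({
    "t_mean": t_mean,
    "t_min": t_mean + 0.05 * rng.normal(size=n),   # near-duplicate
    "humidity": rng.normal(size=n),
    "wind": rng.normal(size=n),
    "pressure": 0.95 * t_mean + 0.3 * rng.normal(size=n),  # collinear
})

corr = correlation_matrix(df)
clus = cluster_variables(corr)
a, b, h = clus.earliest_merge()
print(f"earliest merge: {a} + {b} at distance {h:.4f} (1 - |r|)")
drop = clus.redundant(0.2)
print(f"dropped at cut 0.2: {drop}")

survivors = [c for c in df.columns if c not in drop]
tab = vif(df, survivors, threshold=5.0)
print(tab.to_string(index=False))
print("-> VIF_j = 1/(1 - R_j^2); values above 5 signal collinearity that")
print("   would destabilize a geographically weighted regression.")
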