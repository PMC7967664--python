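"""GWR vs multiscale GWR on a lattice with known coefficient surfaces.

The truth mixes three spatial scales: a constant intercept, a linear
gradient and a sinusoid. GWR must pick one bandwidth for all three; MGWR
gives each term its own, and recovers the surfaces better.
"""

import numpy as np

from geodrivers import (KernelSpec, compare_models, fit_gwr, fit_mgwr,
                        generate_panel, select_bandwidth)
from geodrivers.synthetic import multiscale_recovery_spec

spec = multiscale_recovery_spec(seed=1)
panel, _, _, truth = generate_panel(spec)
coords, y, X = panel.coords(), panel.response(), panel.X()

search = select_bandwidth(coords, y, X, mode="adaptive", standardize=True)
print(f"GWR bandwidth (adaptive neighbours, AICc-optimal): {search.bandwidth:.0f}")
gwr = fit_gwr(coords, y, X, KernelSpec("adaptive", search.bandwidth),
              standardize=True)
mgwr = fit_mgwr(coords, y, X, standardize=True)

print("MGWR per-term bandwidths (intercept, gradient x1, sinusoid x2):",
      [f"{b:.0f}" for b in mgwr.bandwidths])
print("-> the constant surface earns a near-global bandwidth, the sinusoid a")
print("   local one: each relationship is modelled at its own spatial scale.")

tab = compare_models(gwr, mgwr)
print(tab.round(3).to_string())

tr = truth[["intercept", "x1", "x2"]].to_numpy()
for name, fit in (("GWR", gwr), ("MGWR", mgwr)):
    rmse = np.sqrt(((fit.raw_params() - tr) ** 2).mean())
    print(f"{name} coefficient-surface RMSE vs truth: {rmse:.3f}")
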