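"""The whole workflow on a synthetic three-agglomeration study panel.

Autocorrelation tables -> covariate screen -> GWR/MGWR comparison with
regional coefficient summaries, all written as CSVs with a JSON sidecar.
"""

from pathlib import Path

from geodrivers import RunConfig, default_study_spec, generate_panel, run_all

spec = default_study_spec(seed=11)
panel, weights, _, _ = generate_panel(spec)
config = RunConfig(seed=11, n_perm=199)

outdir = Path("scratch/example_run")
results = run_all(panel, weights, config, outdir)

print("selected drivers:", results["selected"])
print(results["comparison"].head(6).round(3).to_string(index=False))
print(results["regional"].round(3).head(3).to_string(index=False))
print(f"outputs in {outdir}: {sorted(p.name for p in outdir.iterdir())}")
print("-> rerunning with the same config reproduces every file byte-for-byte.")
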