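"""End-to-end orchestration: autocorrelation suite → driver screen →
varying-coefficient regression, with CSV outputs and a JSON run sidecar.

A single seed in the run configuration controls every stochastic step
(permutation inference and synthetic generation), so two runs from the same
configuration produce file-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .errors import GeodriversError, ValidationError
from .geodetector import (StrataAssignment, discretize_natural_breaks,
                          ecological_detector, factor_q, interaction_detector)
from .gwr import (KernelSpec, compare_models, fit_gwr, fit_mgwr,
                  regional_mean_coefficients, select_bandwidth)
from .moran import classify_clusters, global_moran, local_moran
from .panel import CityPanel
from .screening import cluster_variables, correlation_matrix, vif
from .weights import SpatialWeights

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated options for a full pipeline run."""

    panel_path: str | None = None
    adjacency_path: str | None = None
    geojson_path: str | None = None
    output_dir: str = "results"
    seed: int = 0
    # weights
    contiguity_rule: str = "queen"
    repair_islands: bool = True
    # Moran
    variance_assumption: str = "randomization"
    n_perm: int = 999
    z_tiers: tuple = (1.96, 2.58)
    # geodetector
    grid_spacing_km: float = 10.0
    n_classes: int = 8
    detector_alpha: float = 0.05
    # screening
    vif_threshold: float = 5.0
    cluster_linkage: str = "single"
    cluster_cut: float = 0.2
    top_k: int = 5
    # regression
    kernel_mode: str = "adaptive"
    standardize: bool = True
    mgwr_tol: float = 1e-5
    mgwr_max_iter: int = 200

    def __post_init__(self) -> None:
        if self.contiguity_rule not in ("queen", "rook"):
            raise ValidationError("contiguity_rule must be queen or rook")
        if self.kernel_mode not in ("adaptive", "fixed"):
            raise ValidationError("kernel_mode must be adaptive or fixed")
        if self.n_perm < 99:
            raise ValidationError("n_perm must be >= 99")
        if not 0 < self.detector_alpha < 1:
            raise ValidationError("detector_alpha must be in (0, 1)")
        self.z_tiers = tuple(self.z_tiers)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _header_comment(config: RunConfig) -> str:
    return f"# geodrivers {__version__} config={config.config_hash()}\n"


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig,
               index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_comment(config))
        df.to_csv(fh, index=index, float_format="%.6f")


def _write_sidecar(outdir: Path, config: RunConfig, extra: dict) -> None:
    meta = {"version": __version__, "config": asdict(config),
            "config_hash": config.config_hash()}
    meta.update(extra)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2,
                                                          default=str))


# ---------------------------------------------------------------------------


def run_autocorrelation_suite(panel: CityPanel, w: SpatialWeights,
                              config: RunConfig,
                              outdir: str | Path | None = None):
    """Global Moran's I per time label (and per group), plus a LISA table.

    Returns ``(global_table, lisa_table)``; writes ``moran_global.csv`` and
    ``moran_lisa.csv`` when an output directory is given. Groups with fewer
    than 3 units are skipped with a warning.
    """
    rows = []
    times = panel.times or [None]
    unit_order = sorted(panel.data["unit_id"].unique())
    widx = {u: i for i, u in enumerate(w.units)}
    seed_root = np.random.SeedSequence(config.seed)
    lisa_frames = []
    for k, t in enumerate(times):
        sub = panel.slice_time(t) if t is not None else panel
        scopes = [("all", sub.data)]
        if sub.has_groups:
            scopes += [(g, d) for g, d in sub.data.groupby("group")]
        for scope, d in scopes:
            if len(d) < 3:
                logger.warning("scope %s at %s has n<3; skipped", scope, t)
                continue
            ids = d["unit_id"].tolist()
            sel = [widx[u] for u in ids]
            Wsub = w.W[np.ix_(sel, sel)]
            islands = [u for u, rs in zip(ids, Wsub.sum(axis=1)) if rs == 0]
            try:
                sw = SpatialWeights(ids, Wsub, islands)
                if sw.S0 == 0:
                    raise GeodriversError("no links in scope")
                res = global_moran(d["y_resp"].to_numpy(), sw,
                                   config.variance_assumption)
            except GeodriversError as exc:
                logger.warning("moran skipped for %s/%s: %s", t, scope, exc)
                continue
            rows.append({"Time": t if t is not None else "all",
                         "Group": scope, "n": sw.n, "Moran's I": res.I,
                         "Z(I)": res.Z, "p": res.p})
            if scope == "all":
                seed = np.random.SeedSequence([config.seed, k]).generate_state(1)[0] % (2 ** 31)
                loc = local_moran(d["y_resp"].to_numpy(), sw,
                                  n_perm=config.n_perm, seed=int(seed))
                tab = classify_clusters(loc, config.z_tiers)
                tab.insert(0, "Time", t if t is not None else "all")
                lisa_frames.append(tab)
    global_table = pd.DataFrame(rows)
    lisa_table = pd.concat(lisa_frames, ignore_index=True) if lisa_frames \
        else pd.DataFrame()
    if outdir is not None:
        outdir = Path(outdir)
        _write_csv(global_table, outdir / "moran_global.csv", config)
        _write_csv(lisa_table, outdir / "moran_lisa.csv", config)
    return global_table, lisa_table


def run_driver_screen(panel: CityPanel, config: RunConfig,
                      outdir: str | Path | None = None, geoms: dict | None = None):
    """Cluster-drop → VIF filter → factor/ecological/interaction detectors.

    The correlation/VIF stage always works on the panel's pooled rows (all
    time slices). The detectors run on regular grid points clipped to the
    unit polygons when ``geoms`` is supplied (spacing from
    ``config.grid_spacing_km``; each point inherits its unit's time-mean
    attributes), and on unit rows otherwise. Returns a dict with the
    correlation matrix, VIF table, factor-q ranking, ecological and
    interaction matrices, and the selected top-k covariates.
    """
    if len(panel.covariates) < 2:
        raise ValidationError("driver screen needs at least 2 covariates")
    df = panel.data
    num_cols = ["y_resp"] + panel.covariates
    corr = correlation_matrix(df, num_cols)

    clus = cluster_variables(corr.drop(index="y_resp", columns="y_resp"),
                             linkage=config.cluster_linkage)
    dropped = clus.redundant(config.cluster_cut)
    surv = [c for c in panel.covariates if c not in dropped]
    if not surv:
        raise ValidationError("all covariates eliminated at the cluster stage")

    vtab = vif(df, surv, threshold=config.vif_threshold)
    keep = vtab.loc[vtab["State"] == "Pass", "Variable"].tolist()
    if not keep:
        raise ValidationError("all covariates eliminated by the VIF filter")

    if geoms is not None:
        from .geodetector import grid_sample
        by_unit = df.groupby("unit_id")[["y_resp"] + keep].mean()
        gs = grid_sample({u: geoms[u] for u in by_unit.index}, by_unit,
                         config.grid_spacing_km)
        det_df = gs.values
    else:
        det_df = df
    y = det_df["y_resp"].to_numpy(float)
    strata = {}
    for c in keep:
        vals = det_df[c].to_numpy(float)
        k = min(config.n_classes, len(np.unique(vals)))
        strata[c] = discretize_natural_breaks(vals, k) if k >= 2 \
            else StrataAssignment.from_categories(vals)
    qrows = [{"Variable": c, "q": factor_q(y, s).q, "p": factor_q(y, s).p}
             for c, s in strata.items()]
    qtab = pd.DataFrame(qrows).sort_values("q", ascending=False).reset_index(drop=True)
    selected = qtab["Variable"].head(config.top_k).tolist()

    eco = pd.DataFrame("-", index=keep, columns=keep)
    inter = pd.DataFrame(np.nan, index=keep, columns=keep)
    for i, a in enumerate(keep):
        inter.loc[a, a] = factor_q(y, strata[a]).q
        for b in keep[:i]:
            sig, _, _ = ecological_detector(y, strata[a], strata[b],
                                            config.detector_alpha)
            eco.loc[a, b] = "Y" if sig else "N"
            qab, _, _, _ = interaction_detector(y, strata[a], strata[b])
            inter.loc[a, b] = qab

    result = {"correlation": corr, "clustering": clus, "dropped": dropped,
              "vif": vtab, "factor_q": qtab, "ecological": eco,
              "interaction": inter, "selected": selected}
    if outdir is not None:
        outdir = Path(outdir)
        _write_csv(corr, outdir / "correlation_matrix.csv", config, index=True)
        _write_csv(vtab, outdir / "vif_table.csv", config)
        _write_csv(qtab, outdir / "factor_detector.csv", config)
        _write_csv(eco, outdir / "ecological_detector.csv", config, index=True)
        _write_csv(inter, outdir / "interaction_detector.csv", config, index=True)
        (outdir / "cluster_tree.json").write_text(
            json.dumps({"variables": clus.variables, "merges": clus.to_tree_json(),
                        "dropped": dropped}, indent=2))
        pd.DataFrame({"selected": selected}).to_csv(outdir / "selected_covariates.csv",
                                                    index=False)
    return result


def run_regression_suite(panel: CityPanel, selected: list[str],
                         config: RunConfig,
                         outdir: str | Path | None = None):
    """GWR vs MGWR per time label on the selected covariates.

    Emits a model-comparison table, a per-term bandwidth/ENP table, regional
    mean coefficients with the strongest covariate flagged, and per-unit
    coefficient surfaces. Returns a dict of DataFrames.
    """
    if not selected:
        raise ValidationError("empty covariate selection")
    times = panel.times or [None]
    comp_frames, bw_frames, reg_frames, surf_frames = [], [], [], []
    for t in times:
        sub = panel.slice_time(t) if t is not None else panel
        coords = sub.coords()
        y = sub.response()
        X = sub.X(selected)
        search = select_bandwidth(coords, y, X, mode=config.kernel_mode,
                                  standardize=config.standardize)
        gfit = fit_gwr(coords, y, X, KernelSpec(config.kernel_mode, search.bandwidth),
                       names=selected, standardize=config.standardize)
        mfit = fit_mgwr(coords, y, X, names=selected, mode=config.kernel_mode,
                        tol=config.mgwr_tol, max_iter=config.mgwr_max_iter,
                        standardize=config.standardize)
        comp = compare_models(gfit, mfit).reset_index()
        comp.insert(0, "Time", t if t is not None else "all")
        comp_frames.append(comp)
        bw_frames.append(pd.DataFrame({
            "Time": t if t is not None else "all",
            "Variable": mfit.names,
            "Bandwidth": mfit.bandwidths,
            "ENP": mfit.enp_terms,
        }))
        if sub.has_groups:
            reg = regional_mean_coefficients(mfit, sub.groups()).reset_index()
            reg.insert(0, "Year", t if t is not None else "all")
            reg_frames.append(reg)
        surf = pd.DataFrame(mfit.params, columns=mfit.names)
        surf.insert(0, "unit_id", sub.data["unit_id"].to_numpy())
        surf.insert(0, "Time", t if t is not None else "all")
        surf["gwr_local_r2"] = gfit.local_r2
        surf_frames.append(surf)
    out = {
        "comparison": pd.concat(comp_frames, ignore_index=True),
        "bandwidths": pd.concat(bw_frames, ignore_index=True),
        "regional": pd.concat(reg_frames, ignore_index=True) if reg_frames
        else pd.DataFrame(),
        "surfaces": pd.concat(surf_frames, ignore_index=True),
    }
    if outdir is not None:
        outdir = Path(outdir)
        _write_csv(out["comparison"], outdir / "model_comparison.csv", config)
        _write_csv(out["bandwidths"], outdir / "mgwr_bandwidths.csv", config)
        _write_csv(out["regional"], outdir / "regional_coefficients.csv", config)
        _write_csv(out["surfaces"], outdir / "coefficient_surfaces.csv", config)
    return out


def run_all(panel: CityPanel, w: SpatialWeights, config: RunConfig,
            outdir: str | Path | None = None, geoms: dict | None = None) -> dict:
    """Full workflow: autocorrelation → driver screen → regression."""
    outdir = Path(outdir if outdir is not None else config.output_dir)
    g, lisa = run_autocorrelation_suite(panel, w, config, outdir)
    screen = run_driver_screen(panel, config, outdir, geoms=geoms)
    reg = run_regression_suite(panel, screen["selected"], config, outdir)
    _write_sidecar(outdir, config, {
        "n_units": panel.n_units, "times": [str(t) for t in panel.times],
        "selected": screen["selected"],
    })
    config.to_yaml(outdir / "config_used.yaml")
    return {"moran_global": g, "moran_lisa": lisa, **screen, **reg}
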