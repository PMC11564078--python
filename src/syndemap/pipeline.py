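"""End-to-end orchestration: simulate → integrate → rates → select → fit →
postprocess → evaluate, with a reproducibility manifest and map export.

A run is driven by a :class:`RunConfig` (loadable from YAML).  Every
stochastic stage takes an explicit seed recorded in the manifest together
with input/output file hashes, so a re-run from the same config is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geo_synth, censor_integration, descriptive, var_select, joint_model, \
    postprocess as pp, evaluate as ev

logger = logging.getLogger("syndemap")

__all__ = ["RunConfig", "run_pipeline", "export_maps"]


@dataclass
class RunConfig:
    out_dir: str = "syndemap_run"
    # either simulate...
    simulate: bool = True
    n_fine: int = 60
    n_sectors: int = 20
    n_districts: int = 4
    n_diseases: int = 3
    n_periods: int = 6
    n_covariates: int = 3
    censor_threshold: int = 5
    # ...or read these paths
    geography_csv: str | None = None
    sector_panel_csv: str | None = None
    district_panel_csv: str | None = None
    covariates_csv: str | None = None
    # stage toggles
    stages: tuple = ("simulate", "integrate", "rates", "select", "fit",
                     "postprocess", "evaluate")
    # model settings
    n_iter: int = 800
    burn_in: int = 300
    thinning: int = 1
    n_clusters: int = 3
    correlation_threshold: float = 0.3
    cv_frac: float = 0.10
    seed: int = 1
    run_baseline: bool = False

    def validate(self) -> None:
        if not self.simulate:
            for name in ("geography_csv", "sector_panel_csv"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"config field {name!r} missing or path does not exist")
        if self.censor_threshold < 1:
            raise ValueError("censor_threshold must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import scipy

    from . import __version__
    manifest: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in asdict(config).items()},
                      "versions": {"syndemap": __version__,
                                   "numpy": np.__version__,
                                   "scipy": scipy.__version__,
                                   "pandas": pd.__version__},
                      "stages": {}, "outputs": {}}
    t_all = time.time()

    def stage_done(name: str, t0: float, **extra):
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), **extra}
        logger.info("stage %-12s done in %.2fs", name, time.time() - t0)

    geo = panel = district_panel = truth = None
    try:
        if "simulate" in config.stages and config.simulate:
            t0 = time.time()
            geo = geo_synth.make_geography(config.n_fine, config.n_sectors,
                                           config.n_districts, seed=config.seed)
            cfg = geo_synth.TruthConfig(n_covariates=config.n_covariates)
            panel_true, truth = geo_synth.simulate_panel(
                geo, config.n_diseases, config.n_periods, cfg, seed=config.seed + 1)
            district_true = geo_synth.aggregate_to_parent(panel_true, geo, "district")
            panel = geo_synth.apply_confidentiality_censoring(
                panel_true, config.censor_threshold)
            district_panel = geo_synth.apply_confidentiality_censoring(
                district_true, config.censor_threshold)
            geo_synth.geography_to_csv(geo, out / "geography.csv")
            geo_synth.panel_to_csv(panel, out / "sector_panel.csv")
            geo_synth.panel_to_csv(district_panel, out / "district_panel.csv")
            panel.covariates.to_csv(out / "covariates.csv")
            (out / "truth.json").write_text(json.dumps(
                {"alpha": truth.alpha.tolist(), "beta": truth.beta.tolist(),
                 "delta": truth.delta.tolist(), "gamma": truth.gamma.tolist(),
                 "sigma2_phi": truth.sigma2_phi, "rho_phi": truth.rho_phi,
                 "sigma2_psi": truth.sigma2_psi, "rho_psi": truth.rho_psi},
                indent=2))
            stage_done("simulate", t0, n_censored=panel.n_censored)
        else:
            t0 = time.time()
            geo = geo_synth.geography_from_csv(config.geography_csv)
            cov = (pd.read_csv(config.covariates_csv, index_col=0)
                   if config.covariates_csv else None)
            panel = geo_synth.panel_from_csv(config.sector_panel_csv, covariates=cov)
            if config.district_panel_csv:
                district_panel = geo_synth.panel_from_csv(
                    config.district_panel_csv, level="district")
            stage_done("load", t0)

        if "integrate" in config.stages and district_panel is not None:
            t0 = time.time()
            rec = censor_integration.integrate_nested_counts(panel, district_panel, geo)
            panel = rec.panel
            rec.log_frame().to_csv(out / "reconciliation_log.csv", index=False)
            stage_done("integrate", t0, n_resolved=rec.n_resolved,
                       n_tightened=rec.n_tightened)

        if "rates" in config.stages:
            t0 = time.time()
            rates = descriptive.incidence_rates(panel, geo, "all")
            rates.to_csv(out / "rates.csv", index=False)
            stage_done("rates", t0)

        selected = list(panel.covariates.columns)
        if "select" in config.stages and len(panel.covariates.columns):
            t0 = time.time()
            trace = var_select.stepwise_select(panel, panel.covariates)
            trace.frame().to_csv(out / "selection_trace.csv", index=False)
            selected = trace.final_variables
            (out / "selected_variables.txt").write_text("\n".join(selected) + "\n")
            stage_done("select", t0, n_selected=len(selected))

        samples = None
        if "fit" in config.stages:
            t0 = time.time()
            spec = joint_model.ModelSpec(
                n_iter=config.n_iter, burn_in=config.burn_in,
                thinning=config.thinning, seed=config.seed + 2)
            samples = joint_model.run_mcmc(panel, selected or None, geo, spec)
            surface = joint_model.summarize_risk(samples, panel)
            surface.frame().to_csv(out / "risk_surface.csv", index=False)
            pd.DataFrame({"unit_id": surface.units,
                          "cumulative_risk": surface.cumulative,
                          "n_diseases": surface.n_diseases}).to_csv(
                out / "cumulative_risk.csv", index=False)
            stage_done("fit", t0, n_draws=samples.n_draws)

        if "postprocess" in config.stages and samples is not None:
            t0 = time.time()
            corr = pp.pairwise_coregionalisation(samples, config.correlation_threshold)
            corr.frame().to_csv(out / "coregionalisation.csv", index=False)
            latent = pp.latent_mean_matrix(samples)
            clus = pp.pca_and_cluster(latent, n_clusters=config.n_clusters,
                                      unit_ids=samples.units)
            clus.frame().to_csv(out / "clusters.csv", index=False)
            stage_done("postprocess", t0,
                       pc2_variance=float(clus.variance_explained[:2].sum()))

        if "evaluate" in config.stages and samples is not None:
            t0 = time.time()
            perf = ev.performance(samples, panel)
            dic, waic, p_d, p_w = ev.information_criteria(samples, panel)
            cvspec = joint_model.ModelSpec(
                n_iter=config.n_iter, burn_in=config.burn_in,
                thinning=config.thinning, seed=config.seed + 3)
            cv = ev.crossvalidate(panel, selected or None, geo, cvspec,
                                  frac=config.cv_frac, seed=config.seed + 4)
            perf.to_csv(out / "performance.csv", index=False)
            cv.to_csv(out / "crossvalidation.csv", index=False)
            report = {"dic": dic, "waic": waic, "p_dic": p_d, "p_waic": p_w}
            if config.run_baseline:
                _, base = ev.fit_independent_baseline(panel, selected or None, geo, cvspec)
                base.to_csv(out / "baseline.csv", index=False)
                report["baseline_mean_abs_pct_error"] = float(base["pct_error"].abs().mean())
            (out / "validation.json").write_text(json.dumps(report, indent=2))
            stage_done("evaluate", t0, **{k: round(v, 3) for k, v in report.items()})
    except Exception as e:
        stage = next(reversed(manifest["stages"]), "start") if manifest["stages"] else "start"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {e}") from e

    for f in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")) + sorted(out.glob("*.txt")):
        if f.name != "manifest.json":
            manifest["outputs"][f.name] = _hash_file(f)
    manifest["total_seconds"] = round(time.time() - t_all, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def export_maps(values: pd.DataFrame, geojson: dict, out_dir, value_col: str = "risk_mean",
                by: str = "disease", no_case_units: set | None = None) -> list[str]:
    """Choropleth export on one common colour scale across layers.

    ``values`` is keyed by unit_id (long format with a ``by`` column giving
    one map layer per level, e.g. per disease).  All layers share the global
    min/max colour scale so maps are comparable; units in ``no_case_units``
    are drawn white (no fill).  Every unit in ``values`` must have geometry;
    missing ids are reported exhaustively.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import cm, colors
    from shapely.geometry import shape

    geoms = {f["properties"]["unit_id"]: shape(f["geometry"])
             for f in geojson["features"]}
    missing = sorted(set(values["unit_id"]) - set(geoms))
    if missing:
        raise ValueError(f"units without geometry: {missing}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    no_case = no_case_units or set()
    vals = values[value_col].to_numpy(float)
    vmin, vmax = float(np.nanmin(vals)), float(np.nanmax(vals))
    norm = colors.Normalize(vmin=vmin, vmax=vmax)
    cmap = matplotlib.colormaps["viridis"]
    paths = []
    for layer, sub in values.groupby(by):
        fig, ax = plt.subplots(figsize=(6, 6))
        for _, row in sub.iterrows():
            g = geoms[row["unit_id"]]
            polys = g.geoms if g.geom_type == "MultiPolygon" else [g]
            fc = ("white" if row["unit_id"] in no_case
                  else cmap(norm(row[value_col])))
            for poly in polys:
                xs, ys = poly.exterior.xy
                ax.fill(xs, ys, facecolor=fc, edgecolor="grey", linewidth=0.3)
        ax.set_aspect("equal")
        ax.set_title(f"{layer} ({value_col})")
        sm = cm.ScalarMappable(norm=norm, cmap=cmap)
        fig.colorbar(sm, ax=ax, shrink=0.7)
        p = out / f"map_{value_col}_{layer}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        paths.append(str(p))
    return paths
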