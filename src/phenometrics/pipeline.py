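"""End-to-end orchestration: observations -> metrics -> comparison outputs.

Stages (mirrored by the CLI subcommands):

* ``simulate`` — write a synthetic woodland (observations, tree metadata,
  truth, config);
* ``fit`` — normalize each tree x method series, fit trajectory curves and
  extract half-dates;
* ``peaks`` — fit count-intensity curves and extract peak day/height;
* ``compare`` — Spearman matrices, cross-trophic and herbivory models,
  ELPD comparison, Moran's I; a plain-text report of the model tables;
* ``all`` — everything above, plus a manifest with a content hash per
  artifact.

All randomness flows from a single top-level seed split per tree x metric.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .compare import (compare_models_elpd, fit_cross_trophic_model,
                      fit_herbivory_model, spearman_matrix)
from .normalize import cumulative_proportion, normalize_bud_scores, normalize_minmax
from .peaks import extract_peak, fit_count_curve, frass_to_centigrams
from .synth import WoodlandConfig, default_config, generate_woodland
from .trajfit import extract_half_date, fit_sigmoid

log = logging.getLogger("phenometrics")

__all__ = [
    "PipelineConfig",
    "HALF_DATE_METRICS",
    "PEAK_METRICS",
    "TREE_METRICS",
    "CATERPILLAR_METRICS",
    "compute_half_dates",
    "normalize_observations",
    "compute_peaks",
    "metrics_wide",
    "run_pipeline",
]

# stream -> half-date metric name
HALF_DATE_METRICS = {
    "bud_score": "budburst",
    "lai": "half_leaf",
    "ndvi": "half_ndvi",
    "frass_mass_g": "frass_half_fall",
    "count_total": "tc_half_fall",
    "count_fwm": "fwm_half_fall",
}
PEAK_METRICS = {
    "frass_mass_g": "frass_peak",
    "count_total": "tc_peak",
    "count_fwm": "fwm_peak",
}
TREE_METRICS = ["budburst", "half_leaf", "half_ndvi"]
CATERPILLAR_METRICS = ["frass_half_fall", "tc_half_fall", "fwm_half_fall",
                       "frass_peak", "tc_peak", "fwm_peak"]


@dataclass
class PipelineConfig:
    outdir: str = "phenometrics_out"
    observations: str | None = None  # defaults to synthetic output paths
    trees: str | None = None
    woodland: WoodlandConfig | None = None
    methods: tuple = tuple(HALF_DATE_METRICS)
    n_basis: int = 8
    ensemble_size: int = 200
    minmax_winsorize: float = 0.05
    grid_step: float = 0.1
    use_exposure_offset: bool = True
    n_boot: int = 1000
    k_folds: int = 10
    knn: int = 8
    area_reference: str = "Great Wood"
    seed: int = 0
    verbosity: int = 1


def _tree_seed(seed: int, tree_id: str, metric: str) -> int:
    h = hashlib.sha256(f"{seed}:{tree_id}:{metric}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


def _series(obs: pd.DataFrame, tree_id, method):
    sub = obs[(obs["tree_id"] == tree_id) & (obs["method"] == method)]
    sub = sub.sort_values("day")
    # repeated visits on the same day are averaged (summed for counts/mass)
    return sub


def normalize_observations(obs: pd.DataFrame, trees: pd.DataFrame,
                           methods=tuple(HALF_DATE_METRICS),
                           minmax_winsorize=0.05) -> pd.DataFrame:
    """Long table of normalized trajectories (tree, metric, day, y, kind, flag)."""
    meta = trees.set_index("tree_id")
    rows = []
    for tree_id in trees["tree_id"]:
        for method in methods:
            sub = _series(obs, tree_id, method)
            if len(sub) == 0:
                continue
            days = sub["day"].to_numpy(float)
            vals = sub["value"].to_numpy(float)
            try:
                if method == "bud_score":
                    max_stage = int(meta.loc[tree_id].get("max_stage", 7) or 7)
                    traj = normalize_bud_scores(days, vals, max_stage,
                                                tree_id=tree_id)
                elif method in ("lai", "ndvi"):
                    traj = normalize_minmax(days, vals, metric=method,
                                            tree_id=tree_id,
                                            winsorize=minmax_winsorize)
                else:
                    traj = cumulative_proportion(days, vals, metric=method,
                                                 tree_id=tree_id)
            except ValueError as exc:
                rows.append({"tree_id": tree_id, "metric": method,
                             "day": np.nan, "y": np.nan, "kind": "",
                             "flag": "error", "notes": str(exc)})
                continue
            if not traj.ok:
                rows.append({"tree_id": tree_id, "metric": traj.metric,
                             "day": np.nan, "y": np.nan, "kind": traj.kind,
                             "flag": traj.flag,
                             "notes": "; ".join(map(str, traj.notes))})
                continue
            for d, y in zip(traj.days, traj.y):
                rows.append({"tree_id": tree_id, "metric": traj.metric,
                             "day": d, "y": y, "kind": traj.kind,
                             "flag": "ok", "notes": ""})
    return pd.DataFrame(rows)


def compute_half_dates(obs: pd.DataFrame, trees: pd.DataFrame,
                       methods=tuple(HALF_DATE_METRICS), ensemble_size=200,
                       n_basis=8, grid_step=0.1, seed=0,
                       minmax_winsorize=0.05) -> pd.DataFrame:
    """One row per tree x half-date metric with estimate, CI, gradient, flag.

    ``minmax_winsorize`` is the quantile used to damp outliers before the
    per-tree min/max of LAI and NDVI series is taken — the pipeline's
    automated stand-in for inspection-based outlier screening of raw imagery.
    """
    meta = trees.set_index("tree_id")
    rows = []
    for tree_id in trees["tree_id"]:
        species = meta.loc[tree_id, "species"]
        area = meta.loc[tree_id, "area"]
        for method in methods:
            metric = HALF_DATE_METRICS[method]
            sub = _series(obs, tree_id, method)
            row = {"tree_id": tree_id, "species": species, "area": area,
                   "metric": metric, "half_day": np.nan, "ci_low": np.nan,
                   "ci_high": np.nan, "ci_width": np.nan,
                   "gradient_at_half": np.nan, "flag": "undefined", "notes": ""}
            if len(sub) == 0:
                row["notes"] = "no observations"
                rows.append(row)
                continue
            try:
                days = sub["day"].to_numpy(float)
                vals = sub["value"].to_numpy(float)
                if method == "bud_score":
                    max_stage = int(meta.loc[tree_id].get("max_stage", 7) or 7)
                    traj = normalize_bud_scores(
                        days, vals, max_stage, tree_id=tree_id,
                        observer_id=sub["observer_id"].to_numpy(),
                    )
                elif method in ("lai", "ndvi"):
                    traj = normalize_minmax(days, vals, metric=method,
                                            tree_id=tree_id,
                                            winsorize=minmax_winsorize)
                else:
                    traj = cumulative_proportion(days, vals, metric=method,
                                                 tree_id=tree_id)
                if not traj.ok:
                    row["notes"] = "; ".join(map(str, traj.notes))
                    rows.append(row)
                    continue
                curve = fit_sigmoid(
                    traj, n_basis=n_basis, ensemble_size=ensemble_size,
                    grid_step=grid_step,
                    random_state=_tree_seed(seed, tree_id, metric),
                )
                curve.metric = metric
                est = extract_half_date(curve)
                row.update(
                    half_day=est.half_day, ci_low=est.ci_low, ci_high=est.ci_high,
                    ci_width=est.ci_width, gradient_at_half=est.gradient_at_half,
                    flag=est.flag, notes="; ".join(map(str, est.notes)),
                )
            except ValueError as exc:
                row["notes"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


def compute_peaks(obs: pd.DataFrame, trees: pd.DataFrame,
                  methods=tuple(PEAK_METRICS), ensemble_size=200, n_basis=8,
                  grid_step=0.1, use_exposure_offset=True, seed=0) -> pd.DataFrame:
    """One row per tree x peak metric with peak day, height and height CI."""
    meta = trees.set_index("tree_id")
    rows = []
    for tree_id in trees["tree_id"]:
        species = meta.loc[tree_id, "species"]
        area = meta.loc[tree_id, "area"]
        for method in methods:
            metric = PEAK_METRICS[method]
            sub = _series(obs, tree_id, method)
            row = {"tree_id": tree_id, "species": species, "area": area,
                   "metric": metric, "peak_day": np.nan, "peak_height": np.nan,
                   "height_ci_low": np.nan, "height_ci_high": np.nan,
                   "flag": "undefined", "notes": ""}
            if len(sub) == 0:
                row["notes"] = "no observations"
                rows.append(row)
                continue
            try:
                days = sub["day"].to_numpy(float)
                vals = sub["value"].to_numpy(float)
                counts = (frass_to_centigrams(vals) if method == "frass_mass_g"
                          else np.round(vals).astype(int))
                curve = fit_count_curve(
                    days, counts, tree_id=tree_id, metric=metric,
                    n_basis=n_basis, ensemble_size=ensemble_size,
                    grid_step=grid_step, use_exposure_offset=use_exposure_offset,
                    random_state=_tree_seed(seed, tree_id, metric),
                )
                est = extract_peak(curve)
                row.update(
                    peak_day=est.peak_day, peak_height=est.peak_height,
                    height_ci_low=est.height_ci_low,
                    height_ci_high=est.height_ci_high, flag=est.flag,
                    notes="; ".join(map(str, est.notes)),
                )
            except ValueError as exc:
                row["notes"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


def metrics_wide(half_dates: pd.DataFrame, peaks: pd.DataFrame | None,
                 trees: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long estimate tables into one row per tree (ok flags only;
    boundary/no-crossing/undefined metrics stay missing)."""
    pieces = []
    hd = half_dates[half_dates["flag"] == "ok"]
    pieces.append(hd.pivot_table(index="tree_id", columns="metric",
                                 values="half_day", aggfunc="first"))
    if peaks is not None and len(peaks):
        pk = peaks[peaks["flag"] == "ok"]
        pieces.append(pk.pivot_table(index="tree_id", columns="metric",
                                     values="peak_day", aggfunc="first"))
    wide = pd.concat(pieces, axis=1)
    keep = [c for c in ("species", "area", "x", "y", "herbivory", "canopy_level",
                        "max_stage") if c in trees.columns]
    out = trees.set_index("tree_id")[keep].join(wide, how="left")
    return out.reset_index()


# ---------------------------------------------------------------------------
# Stage runner with artifact manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineError(RuntimeError):
    pass


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing dependency {path} — run the '{produced_by}' stage first"
        )
    return path


def run_pipeline(config: PipelineConfig, stages=("all",)) -> dict:
    """Run the requested stages; returns the artifact manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = set(stages)
    if "all" in stages:
        stages = {"simulate", "normalize", "fit", "peaks", "compare", "report"}
    manifest = {"seed": config.seed, "stages": sorted(stages), "artifacts": {}}

    def record(name, path):
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(Path(path))}

    obs_path = Path(config.observations or out / "observations.csv")
    trees_path = Path(config.trees or out / "trees.csv")

    if "simulate" in stages:
        wc = config.woodland or default_config(rng_seed=config.seed)
        trees, obs, truth = generate_woodland(wc)
        trees.to_csv(trees_path, index=False, float_format="%.10g")
        pio.write_observations(obs, obs_path)
        truth.write_csv(out / "truth.csv")
        wc.to_yaml(out / "woodland_config.yaml")
        record("trees", trees_path)
        record("observations", obs_path)
        record("truth", out / "truth.csv")
        record("config", out / "woodland_config.yaml")
        log.info("simulated %d trees, %d observation rows", len(trees), len(obs))

    if stages & {"normalize", "fit", "peaks", "compare"}:
        trees = pio.read_trees(_require(trees_path, "simulate"))
        obs = pio.read_observations(_require(obs_path, "simulate"), trees=trees)

    if "normalize" in stages:
        norm = normalize_observations(
            obs, trees, methods=[m for m in config.methods if m in HALF_DATE_METRICS],
            minmax_winsorize=config.minmax_winsorize,
        )
        norm.to_csv(out / "normalized.csv", index=False, float_format="%.10g")
        record("normalized", out / "normalized.csv")

    if "fit" in stages:
        hd = compute_half_dates(
            obs, trees, methods=[m for m in config.methods if m in HALF_DATE_METRICS],
            ensemble_size=config.ensemble_size, n_basis=config.n_basis,
            grid_step=config.grid_step, seed=config.seed,
            minmax_winsorize=config.minmax_winsorize,
        )
        hd.to_csv(out / "half_dates.csv", index=False, float_format="%.6f")
        record("half_dates", out / "half_dates.csv")
        n_ok = int((hd["flag"] == "ok").sum())
        log.info("half-dates: %d ok of %d", n_ok, len(hd))

    if "peaks" in stages:
        pk = compute_peaks(
            obs, trees, ensemble_size=config.ensemble_size, n_basis=config.n_basis,
            grid_step=config.grid_step, use_exposure_offset=config.use_exposure_offset,
            seed=config.seed,
        )
        pk.to_csv(out / "peaks.csv", index=False, float_format="%.6f")
        record("peaks", out / "peaks.csv")

    if "compare" in stages or "report" in stages:
        hd_path = _require(out / "half_dates.csv", "fit")
        pk_path = out / "peaks.csv"
        hd = pd.read_csv(hd_path, dtype={"tree_id": str})
        pk = pd.read_csv(pk_path, dtype={"tree_id": str}) if pk_path.exists() else None
        trees = pio.read_trees(_require(trees_path, "simulate"))
        wide = metrics_wide(hd, pk, trees)
        wide.to_csv(out / "metrics.csv", index=False, float_format="%.6f")
        record("metrics", out / "metrics.csv")

        metric_cols = [c for c in TREE_METRICS + CATERPILLAR_METRICS
                       if c in wide.columns]
        corr = spearman_matrix(wide, metric_cols)
        corr.to_csv(out / "correlations.csv", index=False, float_format="%.6g")
        record("correlations", out / "correlations.csv")

        area_ref = (config.area_reference
                    if config.area_reference in set(wide.get("area", [])) else None)
        model_rows, report_blocks = [], []
        for resp in [m for m in CATERPILLAR_METRICS if m in wide.columns]:
            trio = []
            for pred in [m for m in TREE_METRICS if m in wide.columns]:
                if wide[[resp, pred]].dropna().shape[0] < 10:
                    continue
                try:
                    res = fit_cross_trophic_model(
                        wide, resp, pred, area_reference=area_ref,
                        n_boot=config.n_boot, k_folds=config.k_folds,
                        knn=config.knn, random_state=config.seed,
                    )
                    trio.append(res)
                except ValueError as exc:
                    log.warning("model %s ~ %s failed: %s", resp, pred, exc)
            if len(trio) >= 2:
                try:
                    compare_models_elpd(trio)
                except ValueError:
                    pass  # differing complete-row sets; delta left unset
            for res in trio:
                report_blocks.append(res.summary())
                for _, r in res.coef.iterrows():
                    model_rows.append({
                        "response": res.response, "predictor": res.predictors[0],
                        "term": r["term"], "estimate": r["estimate"],
                        "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                        "significant": bool(r["significant"]),
                        "r2": res.variance_explained, "elpd": res.elpd,
                        "delta_elpd": res.delta_elpd,
                        "moran_i": (res.moran_i or {}).get("I", np.nan),
                        "moran_p": (res.moran_i or {}).get("p", np.nan),
                        "n": res.n, "family": res.family,
                    })

        if "herbivory" in wide.columns and wide["herbivory"].notna().sum() >= 10:
            herb_models = []
            for pred in [m for m in TREE_METRICS if m in wide.columns]:
                try:
                    res = fit_herbivory_model(
                        wide, pred, area_reference=area_ref,
                        n_boot=min(config.n_boot, 400), k_folds=config.k_folds,
                        knn=config.knn, random_state=config.seed,
                    )
                    herb_models.append(res)
                except ValueError as exc:
                    log.warning("herbivory model ~ %s failed: %s", pred, exc)
            if len(herb_models) >= 2:
                try:
                    compare_models_elpd(herb_models)
                except ValueError:
                    pass
            for res in herb_models:
                report_blocks.append(res.summary())
                for _, r in res.coef.iterrows():
                    model_rows.append({
                        "response": res.response, "predictor": res.predictors[0],
                        "term": r["term"], "estimate": r["estimate"],
                        "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                        "significant": bool(r["significant"]),
                        "r2": res.variance_explained, "elpd": res.elpd,
                        "delta_elpd": res.delta_elpd,
                        "moran_i": (res.moran_i or {}).get("I", np.nan),
                        "moran_p": (res.moran_i or {}).get("p", np.nan),
                        "n": res.n, "family": res.family,
                    })

        pd.DataFrame(model_rows).to_csv(out / "models.csv", index=False,
                                        float_format="%.6g")
        record("models", out / "models.csv")
        (out / "report.txt").write_text(
            "\n\n".join(report_blocks) + "\n" if report_blocks else "no models fit\n"
        )
        record("report", out / "report.txt")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
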