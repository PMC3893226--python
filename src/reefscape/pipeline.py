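"""End-to-end workflow: train fish-seascape models in one area, transfer
them to a second area, and validate the transfer.

Stages (fully seeded, reproducible from config + seed):

1. simulate both areas (bathymetry, survey track, fish targets);
2. splitbeam processing: TS threshold, TS -> length, size classes,
   equal-ensonified-area density bins;
3. multiscale terrain predictor stacks from each area's bathymetry;
4. per response (3 size classes x {occurrence, density}) a replicate
   ensemble of boosted-tree models fit on the training area — 60 models
   under the defaults;
5. ensemble-mean prediction surfaces for both areas (6 per area);
6. evaluation: training-area replicate-holdout AUC, and transfer validation
   in the second area with subsampling, local-polynomial detrending,
   spherical-variogram range estimation, spatial thinning, ROC/AUC,
   Jenks density classes with pairwise and Hand–Till multiclass AUC,
   MAE/RMSE, and Local Moran's I clustering of residuals.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import acoustics, brt, synthetic, terrain, validation
from .grids import write_ascii_grid

logger = logging.getLogger(__name__)

__version__ = "0.1.0"
SIZE_CLASSES = acoustics.SIZE_CLASSES


def desk_brt_config(seed: int = 0) -> brt.BRTConfig:
    """Boosting settings sized for desk-scale synthetic surveys.

    A faster learning rate and smaller tree budget than the working-guide
    defaults, appropriate for a few hundred training bins.
    """
    return brt.BRTConfig(learning_rate=0.05, tree_complexity=3, bag_fraction=0.5,
                         n_folds=5, step_size=25, max_trees=250, seed=seed, patience=2)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a full two-area run."""

    training: synthetic.SyntheticScenario = field(
        default_factory=synthetic.training_scenario)
    validation_area: synthetic.SyntheticScenario = field(
        default_factory=synthetic.validation_scenario)
    frequency_khz: float = acoustics.DEFAULT_FREQUENCY_KHZ
    ts_threshold_db: float = acoustics.DEFAULT_TS_THRESHOLD_DB
    beam_angle_deg: float = acoustics.DEFAULT_BEAM_ANGLE_DEG
    bin_area_m2: float = acoustics.DEFAULT_BIN_AREA_M2
    surfaces: tuple = terrain.DEFAULT_SURFACES
    radii: tuple = terrain.DEFAULT_RADII
    brt_config: brt.BRTConfig = field(default_factory=desk_brt_config)
    n_replicates: int = 10
    train_fraction: float = 0.5
    k_density_classes: int = 4
    subsample_fraction: float = 0.5
    n_variogram_lags: int = 15
    variogram_max_lag_fraction: float = 1 / 3  # of the max pairwise distance
    alpha: float = 0.05
    lisa_permutations: int = 199
    seed: int = 0

    def hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:16]


@dataclass
class AreaData:
    name: str
    grid: object
    track: np.ndarray
    targets: list
    bins: list
    bin_frame: pd.DataFrame
    stack: object
    features: pd.DataFrame


@dataclass
class PipelineResult:
    report: dict
    areas: dict
    ensembles: dict            # response name -> BRTEnsemble
    prediction_rasters: dict   # (area, response) -> 2D array
    residual_tables: dict = field(default_factory=dict)  # response -> DataFrame


def _derived_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence([master, *key])
    return int(ss.generate_state(1)[0] % (2**31))


def _prepare_area(name: str, scenario, config: PipelineConfig) -> AreaData:
    """Simulate one area and run it through acoustics and terrain stages."""
    area_key = int.from_bytes(hashlib.sha256(name.encode()).digest()[:2], "big")
    sim_seed = _derived_seed(config.seed, area_key, 1)
    grid, track, fish = synthetic.simulate_area(scenario, seed=sim_seed)
    retained = acoustics.filter_targets(fish, config.ts_threshold_db)
    # lengths/classes are re-derived from the *measured* TS, as a survey would
    measured = acoustics.derive_lengths(retained, config.frequency_khz)
    bins = acoustics.bin_survey(measured, track, grid, config.beam_angle_deg,
                                config.bin_area_m2)
    bin_frame = acoustics.bins_to_frame(bins)
    logger.info("%s: %d targets (%d retained), %d bins", name, len(fish),
                len(retained), len(bins))
    stack = terrain.build_predictor_stack(grid, config.surfaces, config.radii)
    resp_cols = ([f"count_{c}" for c in SIZE_CLASSES]
                 + [f"dens_{c}" for c in SIZE_CLASSES])
    features = terrain.sample_stack(stack, bin_frame, response_columns=tuple(resp_cols))
    for c in SIZE_CLASSES:
        features[f"occ_{c}"] = (features[f"dens_{c}"] > 0).astype(float)
    return AreaData(name=name, grid=grid, track=track, targets=measured, bins=bins,
                    bin_frame=bin_frame, stack=stack, features=features)


def _training_cv_auc(ensemble: brt.BRTEnsemble, features: pd.DataFrame,
                     y: np.ndarray) -> dict:
    """Replicate-holdout AUC (occurrence) across the ensemble."""
    aucs = []
    for m, hold in zip(ensemble.models, ensemble.holdout_indices):
        yh = y[hold]
        if len(np.unique(yh)) < 2 or m.degenerate:
            continue
        p = brt.predict_brt(m, features.iloc[hold])
        aucs.append(validation.roc_auc(p, yh).auc)
    if not aucs:
        return {"mean": None, "sd": None, "n_replicates_scored": 0}
    return {"mean": float(np.mean(aucs)), "sd": float(np.std(aucs)),
            "n_replicates_scored": len(aucs)}


def _transfer_validation(pred: np.ndarray, obs: np.ndarray, occurrence: bool,
                         xy: np.ndarray, config: PipelineConfig, seed: int,
                         full_obs_density: np.ndarray | None = None) -> dict:
    """Thinned transfer metrics for one response in the validation area."""
    rng = np.random.default_rng(seed)
    n = len(obs)
    sub = np.sort(rng.choice(n, size=int(round(config.subsample_fraction * n)),
                             replace=False))
    res: dict = {"n_validation": n, "n_subsampled": len(sub)}
    detrended = validation.detrend_residuals(xy[sub], obs[sub])
    from scipy.spatial.distance import pdist

    max_lag = float(pdist(xy[sub]).max()) * config.variogram_max_lag_fraction
    emp = validation.empirical_semivariogram(xy[sub], detrended,
                                             n_lags=config.n_variogram_lags,
                                             max_lag=max_lag)
    max_emp_lag = float(np.nanmax(emp[:, 0]))
    try:
        vg = validation.fit_spherical_variogram(emp)
        res["variogram"] = {"nugget": vg.nugget, "partial_sill": vg.partial_sill,
                            "range_m": vg.range_m, "flagged": bool(vg.flagged)}
        sill = vg.nugget + vg.partial_sill
        if vg.partial_sill < 1e-6 * max(sill, 1e-12):
            range_m = 0.0  # pure nugget: no autocorrelation, nothing to thin
        elif vg.flagged:
            # range beyond the lag support: cap the thinning distance where
            # pair support is still strong
            range_m = min(vg.range_m, max_emp_lag / 2.0)
        else:
            range_m = vg.range_m
    except (ValueError, RuntimeError) as exc:
        logger.warning("variogram fit failed: %s", exc)
        res["variogram"] = None
        range_m = 0.0
    res["thinning_distance_m"] = range_m
    if range_m > 0:
        keep_local = validation.thin_by_range(xy[sub], range_m, seed=seed + 1)
        keep = sub[keep_local]
    else:
        keep = sub
    res["n_after_thinning"] = len(keep)
    p_k, o_k = pred[keep], obs[keep]
    em = validation.error_metrics(p_k, o_k)
    res["mae"] = em.mae
    res["rmse"] = em.rmse
    res["pearson_r"] = em.r
    res["residual_class_freq"] = {
        c: float(np.mean([rc == c for rc in em.residual_classes]))
        for c in ("neg_gt_mae", "neg_le_mae", "pos_le_mae", "pos_gt_mae")}
    if occurrence:
        try:
            roc = validation.roc_auc(p_k, o_k.astype(int))
            res["auc"] = roc.auc
            res["auc_ci_halfwidth"] = roc.ci_halfwidth
        except ValueError:
            res["auc"] = None
    else:
        base = obs if full_obs_density is None else full_obs_density
        try:
            classing = validation.jenks_breaks(base, config.k_density_classes)
            labels = validation.classify_by_breaks(o_k, classing.thresholds,
                                                   classing.class_names)
            res["density_class_thresholds"] = classing.thresholds.tolist()
            res["density_class_freq"] = classing.frequencies
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mc = validation.multiclass_auc(p_k, labels)
            res["multiclass_auc"] = mc.m
            res["pairwise_auc"] = {f"{a}_vs_{b}": (None if np.isnan(v) else v)
                                   for (a, b), v in mc.pairwise.items()}
        except ValueError as exc:
            logger.warning("density classing failed: %s", exc)
            res["multiclass_auc"] = None
    # spatial structure of the residual errors at the thinned points
    points = pd.DataFrame({"x": xy[keep, 0], "y": xy[keep, 1], "predicted": p_k,
                           "observed": o_k, "residual": em.residuals,
                           "residual_class": em.residual_classes})
    try:
        lisa = validation.local_morans(xy[keep], p_k - o_k,
                                       n_permutations=config.lisa_permutations,
                                       alpha=config.alpha, seed=seed + 2)
        res["lisa"] = {
            "global_morans_i": lisa.global_i,
            "n_significant": int(np.sum(np.array(lisa.p_values) < config.alpha)),
            "label_counts": {lb: lisa.labels.count(lb)
                             for lb in ("HH", "LL", "HL", "LH", "not-significant")}}
        points["local_i"] = lisa.local_i
        points["p_value"] = lisa.p_values
        points["cluster"] = lisa.labels
    except ValueError as exc:
        logger.warning("LISA skipped: %s", exc)
        res["lisa"] = None
    return res, points


def run_pipeline(config: PipelineConfig | None = None,
                 output_dir: str | Path | None = None) -> PipelineResult:
    """Run the full two-area train/transfer workflow; optionally write artifacts."""
    if config is None:
        config = PipelineConfig()
    areas = {
        "training": _prepare_area("training", config.training, config),
        "validation": _prepare_area("validation", config.validation_area, config),
    }
    train = areas["training"]
    valid = areas["validation"]
    pred_cols = list(train.stack.layers)

    ensembles: dict[str, brt.BRTEnsemble] = {}
    rasters: dict[tuple, np.ndarray] = {}
    responses_report: dict[str, dict] = {}
    residual_tables: dict[str, pd.DataFrame] = {}
    for ci, cname in enumerate(SIZE_CLASSES):
        for kind in ("occurrence", "density"):
            rname = f"{cname}_{kind}"
            if kind == "occurrence":
                y = train.features[f"occ_{cname}"].to_numpy()
                family = "bernoulli"
            else:
                y = train.features[f"count_{cname}"].to_numpy()
                family = "poisson"
            cfg = dataclasses.replace(
                config.brt_config, family=family,
                seed=_derived_seed(config.seed, 7, ci, 0 if kind == "occurrence" else 1))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ens = brt.fit_ensemble(train.features[pred_cols], y, cfg,
                                       n_replicates=config.n_replicates,
                                       train_fraction=config.train_fraction)
            ensembles[rname] = ens
            entry: dict = {
                "family": family,
                "n_models": len(ens.models),
                "n_degenerate": int(sum(m.degenerate for m in ens.models)),
                "mean_optimal_n_trees": float(np.mean(
                    [m.optimal_n_trees for m in ens.models])),
            }
            # averaged relative influence across replicates
            infl = pd.DataFrame(
                [brt.relative_influence(m) for m in ens.models if not m.degenerate])
            if len(infl):
                mean_infl = infl.mean(axis=0).sort_values(ascending=False)
                entry["top_predictors"] = {k: float(v)
                                           for k, v in mean_infl.head(5).items()}
            if kind == "occurrence":
                entry["training_cv_auc"] = _training_cv_auc(
                    ens, train.features[pred_cols], y)
            for aname, area in areas.items():
                rasters[(aname, rname)] = brt.predict_ensemble_raster(ens, area.stack)
            v_pred = brt.predict_ensemble(ens, valid.features[pred_cols])
            if kind == "occurrence":
                v_obs = valid.features[f"occ_{cname}"].to_numpy()
                full_dens = None
            else:
                v_obs = valid.features[f"dens_{cname}"].to_numpy()
                # poisson models predict counts per bin; bins are 100 m^2 so the
                # expected count equals fish per 100 m^2
                full_dens = v_obs
            xy = valid.features[["x", "y"]].to_numpy()
            entry["transfer"], resid_points = _transfer_validation(
                v_pred, v_obs, kind == "occurrence", xy, config,
                seed=_derived_seed(config.seed, 11, ci, 0 if kind == "occurrence" else 1),
                full_obs_density=full_dens)
            residual_tables[rname] = resid_points
            responses_report[rname] = entry

    report = {
        "provenance": {"seed": config.seed, "config_hash": config.hash(),
                       "version": __version__},
        "n_models_total": int(sum(len(e.models) for e in ensembles.values())),
        "n_responses": len(ensembles),
        "n_prediction_surfaces_per_area": len(
            {r for (a, r) in rasters if a == "training"}),
        "areas": {
            name: {
                "n_targets": len(a.targets),
                "n_bins": len(a.bins),
                "n_predictor_layers": len(a.stack.layers),
                "prevalence": {c: float((a.features[f"occ_{c}"] > 0).mean())
                               for c in SIZE_CLASSES},
                "max_density_per_100m2": {
                    c: float(a.features[f"dens_{c}"].max()) for c in SIZE_CLASSES},
            } for name, a in areas.items()},
        "responses": responses_report,
    }
    result = PipelineResult(report=report, areas=areas, ensembles=ensembles,
                            prediction_rasters=rasters, residual_tables=residual_tables)
    if output_dir is not None:
        _write_artifacts(result, config, Path(output_dir))
    return result


def _write_artifacts(result: PipelineResult, config: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
    for name, area in result.areas.items():
        write_ascii_grid(area.grid.depth, area.grid.cell_size, area.grid.origin,
                         out / f"{name}_bathymetry.asc", area.grid.nodata_mask)
        acoustics.targets_to_frame(area.targets).to_csv(
            out / f"{name}_targets.csv", index=False)
        area.bin_frame.to_csv(out / f"{name}_bins.csv", index=False)
    for (aname, rname), arr in result.prediction_rasters.items():
        grid = result.areas[aname].grid
        write_ascii_grid(arr, grid.cell_size, grid.origin,
                         out / f"{aname}_pred_{rname}.asc")
    for rname, table in result.residual_tables.items():
        table.to_csv(out / f"validation_residuals_{rname}.csv", index=False)
    manifest = {"config_hash": config.hash(), "seed": config.seed,
                "files": sorted(p.name for p in out.iterdir())}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
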