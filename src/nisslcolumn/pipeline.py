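"""End-to-end orchestration of the quantification stages.

A single configuration dictionary drives the run: stereological
exclusion, the nonlinear depth grid and profile, layer classification
(trained on the labeled cells, then applied to all cells), per-layer
alpha-hull densities and heights, and the morphometry battery.  Every
stage's seed and the effective configuration are echoed into the run
log so identical config + inputs reproduce identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from nisslcolumn import (depth_density, io_formats, layer_classifier,
                         layer_geometry, morphometry, stereology)

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "run_all"]

#: Stage defaults; any override is echoed into the run log.
DEFAULT_CONFIG: dict = {
    "thickness_um": 50.0,
    "stereology": {"n_iterations": 100, "seed": 0, "k_neighbors": 6},
    "grid": {"n_cols": 10, "n_rows": 20},
    "classifier": {"model": "rf", "folds": 10, "seed": 0,
                   "paradigm": "separated", "n_estimators": 500},
    "alpha": {"general": 0.05, "layer1": 0.005},
    "stats": {"alpha": 0.05, "bonferroni_m": 6},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            if key in base and base[key] != val:
                logger.info("config override: %s = %r (default %r)",
                            key, val, base[key])
            out[key] = val
    return out


class _StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(cells: pd.DataFrame, regions: io_formats.RegionSet,
            out_dir, config: dict | None = None) -> dict:
    """Run every stage on one image's cells and regions.

    Writes ``profile.csv``, ``layers.json``, ``morph.json`` and
    ``report.json`` into ``out_dir`` and returns the report dictionary.
    On a stage failure, partial outputs are retained next to a FAILED
    marker naming the stage and cause.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": cfg, "stages": {}}
    thickness = float(cfg["thickness_um"])
    stage = "setup"
    try:
        stage = "stereology"
        cells = depth_density.filter_in_polygon(cells, regions.s1hl)
        excl = stereology.bootstrap_exclusion(
            cells, thickness_um=thickness,
            n_iterations=cfg["stereology"]["n_iterations"],
            seed=cfg["stereology"]["seed"], k=cfg["stereology"]["k_neighbors"])
        report["stages"]["stereology"] = {
            "mean_fraction": excl.mean_fraction, "sd_fraction": excl.sd_fraction}

        stage = "depth_density"
        grid = depth_density.build_depth_grid(
            regions, n_cols=cfg["grid"]["n_cols"], n_rows=cfg["grid"]["n_rows"])
        filled = depth_density.bin_densities(grid, cells, thickness, excl)
        profile = depth_density.depth_profile([filled])
        profile.to_frame().to_csv(out_dir / "profile.csv", index=False)
        report["stages"]["depth_density"] = {
            "n_bins": grid.n_cols * grid.n_rows,
            "mean_density": float(np.nanmean(filled.density_cells_mm3))}

        stage = "layer_classifier"
        feats = layer_classifier.assemble_features(cells, regions)
        labels = feats["layer_label"].to_numpy()
        if cfg["classifier"]["paradigm"] == "merged":
            labels = layer_classifier.merge_l23(labels)
        labeled = labels != "none"
        ccfg = cfg["classifier"]
        if labeled.any():
            model, names = layer_classifier.fit(
                feats.loc[labeled], labels[labeled], model_kind=ccfg["model"],
                seed=ccfg["seed"], n_estimators=ccfg["n_estimators"])
            predicted = layer_classifier.predict(model, feats, names)
            cells = cells.assign(predicted_layer=predicted["predicted_layer"])
            report["stages"]["layer_classifier"] = {
                "model": ccfg["model"], "n_features": len(names),
                "n_labeled": int(labeled.sum())}
        else:
            cells = cells.assign(predicted_layer=cells["layer_label"])
            report["stages"]["layer_classifier"] = {"skipped": "no labels"}

        stage = "layer_geometry"
        # densities and mixtures are per image first, then aggregated,
        # so images with different cell counts weigh equally
        image_groups = cells.groupby("image_id", sort=False).indices
        per_image_density: dict[str, dict[str, float]] = {}
        for image_id, idx in image_groups.items():
            sub = cells.iloc[idx].reset_index(drop=True)
            sub_excl = stereology.ExclusionResult(
                n_iterations=excl.n_iterations, thickness_um=excl.thickness_um,
                per_iteration_excluded_fraction=excl.per_iteration_excluded_fraction,
                mean_fraction=excl.mean_fraction, sd_fraction=excl.sd_fraction,
                per_cell_exclusion_probability=
                    excl.per_cell_exclusion_probability[idx])
            for label in io_formats.LAYER_ORDER:
                if (sub["predicted_layer"] == label).sum() < 3:
                    continue
                alpha = (cfg["alpha"]["layer1"] if label == "LI"
                         else cfg["alpha"]["general"])
                try:
                    hull = layer_geometry.layer_density(
                        sub, label, alpha=alpha, thickness_um=thickness,
                        exclusion=sub_excl)
                except layer_geometry.DegenerateGeometryError:
                    continue
                per_image_density.setdefault(label, {})[str(image_id)] = \
                    hull.density_cells_mm3
        layers_out = {
            "per_layer_density": {
                label: {
                    "mean_cells_mm3": float(np.mean(list(v.values()))),
                    "sd_cells_mm3": (float(np.std(list(v.values()), ddof=1))
                                     if len(v) > 1 else 0.0),
                    "n_images": len(v),
                }
                for label, v in per_image_density.items()},
            "heights": None,
        }
        heights = layer_geometry.layer_heights(cells, grid)
        layers_out["heights"] = heights.to_dict()
        (out_dir / "layers.json").write_text(json.dumps(layers_out, indent=2))
        report["stages"]["layer_geometry"] = {
            "n_layers": len(per_image_density),
            "total_height_um": heights.total_height_um}

        stage = "morphometry"
        morph: dict = {"mixtures": {}, "tests": {}}
        diam = morphometry.diameter_from_area(cells["area_um2"].to_numpy(float))
        for label in per_image_density:
            fits = []
            for image_id, idx in image_groups.items():
                sub_lab = cells.iloc[idx]["predicted_layer"].to_numpy()
                sample = diam[np.asarray(idx)][sub_lab == label]
                if len(sample) >= 10:
                    fits.append(morphometry.fit_diameter_mixture(
                        sample, seed=cfg["stereology"]["seed"]))
            if fits:
                agg = morphometry.aggregate_mixtures(fits)
                if agg.get("test") is not None:
                    agg["test"] = agg["test"].to_dict()
                morph["mixtures"][label] = agg
        dens_groups = {label: np.array(list(v.values()))
                       for label, v in per_image_density.items()
                       if len(v) >= 2}
        if len(dens_groups) >= 2:
            morph["tests"]["kruskal_wallis"] = morphometry.density_across_layers(
                dens_groups, alpha=cfg["stats"]["alpha"]).to_dict()
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                morph["tests"]["adjacent_layers"] = {
                    k: v.to_dict() for k, v in
                    morphometry.adjacent_layer_tests(
                        dens_groups,
                        family_alpha=cfg["stats"]["alpha"]).items()}
        report["stages"]["morphometry"] = {"n_mixtures": len(morph["mixtures"])}
        morph["per_layer_density"] = layers_out["per_layer_density"]
        (out_dir / "morph.json").write_text(json.dumps(morph, indent=2))
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        (out_dir / "FAILED").write_text(f"{stage}: {exc}\n")
        raise _StageFailure(stage, exc) from exc
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report
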