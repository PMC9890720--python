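"""End-to-end orchestration: simulate -> detect -> classify -> phenotype -> stats.

Each stage reads the previous stage's CSV/image outputs from the configured
output directory and is individually re-runnable. All CSVs start with a
``# immunotopo config=<hash> seed=<seed>`` provenance comment (read them
back with ``pandas.read_csv(..., comment="#")``). Stage functions also
return their tables, so the same flow can be driven in memory.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import celldetect, stainsep, statlab, synthcore, tissueclass, topography
from .config import PipelineConfig
from .statlab import DegenerateTableError

log = logging.getLogger("immunotopo")

__all__ = [
    "simulate",
    "detect_stage",
    "classify_stage",
    "phenotype_stage",
    "stats_stage",
    "run_all",
    "run_statistics",
]


def _write_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# immunotopo config={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, index=False)


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _stain_vectors(cfg: PipelineConfig) -> stainsep.StainVectorSet:
    return stainsep.StainVectorSet.from_pair(
        cfg.stains.hematoxylin, cfg.stains.dab, background=cfg.stains.background
    )


def _sim_dir(cfg: PipelineConfig) -> Path:
    return Path(cfg.out_dir) / "sim"


def simulate(cfg: PipelineConfig) -> pd.DataFrame:
    """Generate the synthetic cohort and write images + ground truth to disk.

    Writes per case: ``<case>_<marker>.tiff`` (RGB), ``<case>_mask.png``
    (0 background / 1 tumour / 2 stroma), ``<case>_cells.csv``; plus
    ``clinical.csv`` and the echoed ``cohort.yaml``.
    """
    sim = _sim_dir(cfg)
    sim.mkdir(parents=True, exist_ok=True)
    cohort_spec = synthcore.CohortSpec(
        n_cases=cfg.cohort.n_cases,
        markers=tuple(cfg.cohort.markers),
        marker_corr=cfg.cohort.marker_corr,
        tumour_fraction=cfg.cohort.tumour_fraction,
        seed=cfg.seed,
    )
    template = synthcore.CoreSpec(
        core_diameter_um=cfg.cohort.core_diameter_um,
        pixel_size_um=cfg.cohort.pixel_size_um,
        tumour_fraction=cfg.cohort.tumour_fraction,
        noise_sd=cfg.cohort.noise_sd,
        seed=cfg.seed,
    )
    cases, clinical = synthcore.generate_cohort(cohort_spec, template, render=True)
    for case in cases:
        for marker, image in case.images.items():
            tifffile.imwrite(sim / f"{case.case_id}_{marker}.tiff", image)
        iio.imwrite(sim / f"{case.case_id}_mask.png", case.truth.mask.labels)
        _write_csv(case.truth.cells, sim / f"{case.case_id}_cells.csv", cfg)
    _write_csv(clinical, sim / "clinical.csv", cfg)
    with open(sim / "cohort.yaml", "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=True)
    log.info("simulated %d cases into %s", len(cases), sim)
    return clinical


def detect_stage(cfg: PipelineConfig) -> pd.DataFrame:
    """Run stain separation + tissue detection + cell detection per image."""
    sim = _sim_dir(cfg)
    stains = _stain_vectors(cfg)
    clinical = _read_csv(sim / "clinical.csv")
    frames = []
    flagged = 0
    for case_id in clinical["case_id"]:
        for marker in cfg.cohort.markers:
            image = tifffile.imread(sim / f"{case_id}_{marker}.tiff")
            od = stainsep.rgb_to_od(image, stains.background)
            if cfg.stains.estimate_per_image:
                stains_i, _ = stainsep.estimate_stain_vectors(
                    od, od_floor=cfg.stains.od_floor, background=stains.background
                )
            else:
                stains_i = stains
            sep = stainsep.deconvolve(od, stains_i)
            try:
                tissue = celldetect.simple_tissue_detection(od, cfg.cohort.pixel_size_um)
            except celldetect.EmptyTissueError:
                log.warning("case %s marker %s: no tissue, flagged unusable", case_id, marker)
                flagged += 1
                continue
            params = celldetect.DetectionParams(
                **cfg.detection_params_for(marker).model_dump()
            )
            det = celldetect.detect_cells(sep, params, tissue)
            det.insert(0, "marker", marker)
            det.insert(0, "case_id", case_id)
            frames.append(det)
    detections = pd.concat(frames, ignore_index=True)
    _write_csv(detections, Path(cfg.out_dir) / "detections.csv", cfg)
    log.info("detected %d cells (%d images flagged unusable)", len(detections), flagged)
    return detections


def classify_stage(cfg: PipelineConfig) -> dict[str, tissueclass.CompartmentMask]:
    """Train one tumour/stroma classifier and apply it to every core.

    Training annotations emulate a pathologist outlining representative
    areas: square boxes sampled inside the ground-truth compartments of the
    first ``n_annotation_cases`` cores. One shared classifier serves the
    whole cohort.
    """
    sim = _sim_dir(cfg)
    stains = _stain_vectors(cfg)
    clinical = _read_csv(sim / "clinical.csv")
    case_ids = list(clinical["case_id"])
    ref_marker = cfg.cohort.markers[0]
    rng = np.random.default_rng(cfg.seed + 1)

    train_x, train_anns, schema_feats = [], [], None
    features_cache: dict[str, np.ndarray] = {}

    def _features(case_id: str) -> np.ndarray:
        if case_id not in features_cache:
            image = tifffile.imread(sim / f"{case_id}_{ref_marker}.tiff")
            od = stainsep.rgb_to_od(image, stains.background)
            features_cache[case_id] = tissueclass.extract_features(
                stainsep.deconvolve(od, stains)
            )
        return features_cache[case_id]

    # pool annotation pixels across the annotation cases by training on a
    # feature mosaic (stacked rows) with polygon coordinates offset per case
    n_train = min(cfg.classifier.n_annotation_cases, len(case_ids))
    stacks, anns = [], []
    row_offset = 0
    for case_id in case_ids[:n_train]:
        feats = _features(case_id)
        mask = tissueclass.CompartmentMask(
            labels=iio.imread(sim / f"{case_id}_mask.png"),
            pixel_size_um=cfg.cohort.pixel_size_um,
        )
        for ann in synthcore.annotations_from_mask(
            mask, rng, n_per_class=cfg.classifier.annotations_per_class,
            box_px=cfg.classifier.annotation_box_px,
        ):
            poly = ann.polygon.copy()
            poly[:, 1] += row_offset
            anns.append(tissueclass.Annotation(polygon=poly, label=ann.label))
        stacks.append(feats)
        row_offset += feats.shape[0]
    mosaic = np.concatenate(stacks, axis=0)
    model = tissueclass.train_pixel_classifier(
        mosaic, anns, seed=cfg.seed + 2,
        n_trees=cfg.classifier.n_trees, max_depth=cfg.classifier.max_depth,
        cap_per_class=cfg.classifier.cap_per_class,
    )
    log.info("pixel classifier held-out accuracy: %.3f", model.holdout_accuracy)

    masks = {}
    for case_id in case_ids:
        feats = _features(case_id)
        image = tifffile.imread(sim / f"{case_id}_{ref_marker}.tiff")
        od = stainsep.rgb_to_od(image, stains.background)
        tissue = celldetect.simple_tissue_detection(od, cfg.cohort.pixel_size_um)
        cm = tissueclass.classify_pixels(model, feats, tissue)
        cm = tissueclass.post_process(
            cm, min_region_area_um2=cfg.classifier.min_region_area_um2,
            mode_filter_radius_px=cfg.classifier.mode_filter_radius_px,
        )
        iio.imwrite(sim / f"{case_id}_predmask.png", cm.labels)
        masks[case_id] = cm
        features_cache.pop(case_id, None)
    with open(Path(cfg.out_dir) / "classifier_report.yaml", "w") as fh:
        yaml.safe_dump({"holdout_accuracy": model.holdout_accuracy,
                        "n_annotation_cases": n_train}, fh)
    return masks


def phenotype_stage(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Densities, cohort cutoffs, phenotype calls (and CPS when applicable).

    Cases contributing several cores per (case, marker) are averaged before
    thresholding. Cores without both compartments are dropped as unusable.
    """
    sim = _sim_dir(cfg)
    out = Path(cfg.out_dir)
    detections = _read_csv(out / "detections.csv")
    clinical = _read_csv(sim / "clinical.csv")

    rows = []
    for case_id in clinical["case_id"]:
        mask = tissueclass.CompartmentMask(
            labels=iio.imread(sim / f"{case_id}_predmask.png"),
            pixel_size_um=cfg.cohort.pixel_size_um,
        )
        for marker in cfg.cohort.markers:
            det = detections[(detections["case_id"] == case_id)
                             & (detections["marker"] == marker)]
            assigned = topography.assign_cells(det, mask)
            try:
                rec = topography.compute_density(assigned, mask, case_id, marker)
            except topography.UnusableCaseError:
                log.warning("case %s marker %s unusable (missing compartment)",
                            case_id, marker)
                continue
            rows.append(rec.as_row())
    densities = pd.DataFrame(rows)
    # two cores per patient -> mean of per-core values before thresholding
    densities = (
        densities.groupby(["case_id", "marker"], as_index=False)
        .mean(numeric_only=True)
    )
    thresholds = topography.cohort_median_threshold(
        densities, derivation=cfg.thresholds.derivation
    )
    phenotypes = topography.phenotype_table(
        densities, thresholds, combos=cfg.combos, rule=cfg.combo_rule
    )
    cutoffs = dict(zip(thresholds["marker"], thresholds["cutoff"]))
    densities["density_class"] = [
        topography.dichotomize(row.overall_density, cutoffs[row.marker])
        for row in densities.itertuples()
    ]
    _write_csv(densities, out / "densities.csv", cfg)
    _write_csv(thresholds, out / "thresholds.csv", cfg)
    _write_csv(phenotypes, out / "phenotypes.csv", cfg)

    tables = {"densities": densities, "thresholds": thresholds, "phenotypes": phenotypes}
    pdl1 = next((m for m in cfg.cohort.markers if m.lower().replace("-", "") == "pdl1"), None)
    if pdl1 is not None:
        cps_rows = []
        for case_id, grp in detections[detections["marker"] == pdl1].groupby("case_id"):
            mask = tissueclass.CompartmentMask(
                labels=iio.imread(sim / f"{case_id}_predmask.png"),
                pixel_size_um=cfg.cohort.pixel_size_um,
            )
            assigned = topography.assign_cells(grp, mask)
            n_pos = int(assigned["positive"].sum())
            viable = int(((~assigned["positive"].astype(bool))
                          & (assigned["compartment"] == "tumour")).sum())
            try:
                res = topography.compute_cps(n_pos, viable, cutoff=cfg.cps_cutoff,
                                             case_id=case_id)
            except topography.UnusableCaseError:
                continue
            cps_rows.append({"case_id": case_id, "n_positive": res.n_positive,
                             "n_viable_tumour_cells": res.n_viable_tumour_cells,
                             "cps": res.cps, "high": res.high})
        cps = pd.DataFrame(cps_rows)
        _write_csv(cps, out / "cps.csv", cfg)
        tables["cps"] = cps
    return tables


def run_statistics(
    densities: pd.DataFrame,
    phenotypes: pd.DataFrame,
    clinical: pd.DataFrame,
    cps_column: str = "cps_high",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The association + survival battery on the pipeline's tables.

    Per marker: dichotomized density vs FGFR3 mutation and vs PD-L1 CPS
    status (chi-square); phenotype distribution vs CPS status (Fisher /
    Freeman-Halton); overall survival by measured perforin density class
    (log-rank + restricted mean). Returns (results, km_curves).
    """
    results, km_rows = [], []

    def _crosstab_test(col_a: pd.Series, col_b: pd.Series, method: str, **meta):
        table = pd.crosstab(col_a, col_b)
        table = table.loc[(table.sum(axis=1) > 0), (table.sum(axis=0) > 0)]
        if table.shape[0] < 2 or table.shape[1] < 2:
            return
        try:
            if method == "chi_square":
                res = statlab.pearson_chi_square(table.to_numpy())
            else:
                res = statlab.fisher_exact(table.to_numpy())
        except DegenerateTableError:
            return
        results.append({**meta, "method": res.method, "statistic": res.statistic,
                        "df": res.df, "p_value": res.p_value, "n": res.n})

    merged = densities.merge(clinical, on="case_id")
    for marker, grp in merged.groupby("marker", sort=True):
        if "fgfr3_mutated" in grp:
            _crosstab_test(grp["density_class"], grp["fgfr3_mutated"], "chi_square",
                           analysis="density_vs_fgfr3", marker=marker)
        if cps_column in grp:
            _crosstab_test(grp["density_class"], grp[cps_column], "chi_square",
                           analysis="density_vs_cps", marker=marker)
    pheno = phenotypes.merge(clinical, on="case_id")
    for marker, grp in pheno.groupby("marker", sort=True):
        if cps_column in grp:
            _crosstab_test(grp["phenotype"], grp[cps_column], "fisher",
                           analysis="topography_vs_cps", marker=marker)

    perf = merged[merged["marker"] == "perforin"]
    if len(perf) and "os_months" in perf and perf["event"].any():
        groups = perf["density_class"].to_numpy()
        if len(np.unique(groups)) == 2:
            res = statlab.logrank(perf["os_months"], perf["event"], groups)
            results.append({"analysis": "os_by_perforin_density", "marker": "perforin",
                            "method": res.method, "statistic": res.statistic,
                            "df": res.df, "p_value": res.p_value, "n": res.n})
            for label, sub in perf.groupby("density_class"):
                curve = statlab.km_estimate(sub["os_months"], sub["event"], label=label)
                rmst, se = statlab.restricted_mean(curve)
                results.append({"analysis": "mean_os", "marker": "perforin",
                                "method": f"restricted_mean[{label}]",
                                "statistic": rmst, "df": se,
                                "p_value": np.nan, "n": len(sub)})
                for t, s, r in zip(curve.times, curve.survival, curve.at_risk):
                    km_rows.append({"group": label, "time": t, "survival": s,
                                    "at_risk": r})
    return (
        pd.DataFrame(results, columns=["analysis", "marker", "method", "statistic",
                                       "df", "p_value", "n"]),
        pd.DataFrame(km_rows, columns=["group", "time", "survival", "at_risk"]),
    )


def stats_stage(cfg: PipelineConfig) -> pd.DataFrame:
    out = Path(cfg.out_dir)
    densities = _read_csv(out / "densities.csv")
    phenotypes = _read_csv(out / "phenotypes.csv")
    clinical = _read_csv(_sim_dir(cfg) / "clinical.csv")
    results, km = run_statistics(densities, phenotypes, clinical)
    _write_csv(results, out / "results.csv", cfg)
    _write_csv(km, out / "km_curves.csv", cfg)
    return results


def run_all(cfg: PipelineConfig) -> pd.DataFrame:
    """Full flow: simulate -> detect -> classify -> phenotype -> stats."""
    simulate(cfg)
    detect_stage(cfg)
    classify_stage(cfg)
    phenotype_stage(cfg)
    return stats_stage(cfg)
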