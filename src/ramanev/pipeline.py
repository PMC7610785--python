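"""End-to-end pipeline: preprocess -> band images -> uptake quantification ->
chemometrics, with reproducible on-disk outputs.

Two preprocessing variants are produced per cube. A linear "quantification"
cube (crop, baseline removal, exterior-mean subtraction — no per-pixel
normalization) drives deuterium detection and the inside/outside intensity
partition, because per-pixel area normalization rescales interior and
exterior pixels by different factors and would bias any cross-pixel
intensity comparison. The fully normalised "spectral" cube (the conventional
display chain) supplies band images, composites and the spectra handed to
PCA. Every threshold actually applied (Otsu level, detection cutoff, FWHM
noise floor) is logged and stored in the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .bands import band_auc, deuterium_fwhm, render_composite
from .chemometrics import cohort_separation, fit_pca
from .config import PipelineConfig
from .preprocess import preprocess_cube, shape_baseline_cube, crop_cube, subtract_system_background
from .spectral import HyperCube
from .uptake import UptakeReport, estimate_exterior_mask, quantify_uptake

__all__ = ["run_pipeline", "process_cube", "CubeResult"]

logger = logging.getLogger("ramanev")

_FLOAT_FMT = "%.10g"


@dataclass
class CubeResult:
    name: str
    cohort: str
    report: UptakeReport
    band_maps: dict
    fwhm_map: object
    score_map: object
    composite: np.ndarray
    is_3d: bool = False


def _preprocess_variants(cube: HyperCube, config: PipelineConfig):
    """(quantification cube, spectral cube, exterior mask)."""
    pre = config.preprocess
    base = crop_cube(cube, *pre.crop_range)
    corrected, _ = shape_baseline_cube(base, pre.shape_size)
    exterior = estimate_exterior_mask(corrected, margin=config.exterior_margin)
    if pre.background_mode == "exterior_mean":
        quant = subtract_system_background(corrected, exterior)
    else:
        quant = corrected
    spectral = preprocess_cube(cube, pre, exterior_mask=exterior)
    return quant, spectral, exterior


def _fwhm_noise_floor(spectral_cube: HyperCube, exterior: np.ndarray, window) -> float:
    """Sentinel threshold: mean + 3 SD of deuterium-window maxima over
    exterior pixels."""
    sl = spectral_cube.axis.window_slice(*window)
    maxima = spectral_cube.data[..., sl].max(axis=-1)
    if spectral_cube.is_3d:
        maxima = maxima.max(axis=-1)
    ext = maxima[exterior]
    return float(ext.mean() + 3.0 * ext.std(ddof=1 if ext.size > 1 else 0))


def process_cube(cube: HyperCube, config: PipelineConfig, name: str = "cell", cohort: str = "all") -> CubeResult:
    """Run preprocessing, band imaging and uptake quantification on one cube.

    Z-stacks are processed slice by slice with a shared exterior mask;
    distances and signal partitions are pooled across slices.
    """
    quant, spectral, exterior = _preprocess_variants(cube, config)

    from .bands import DEUTERIUM_WINDOW

    noise_floor = _fwhm_noise_floor(spectral, exterior, DEUTERIUM_WINDOW)

    if cube.data.ndim == 4:
        slices = [
            (quant.slice_2d(z), spectral.slice_2d(z)) for z in range(quant.n_slices)
        ]
    else:
        slices = [(quant, spectral)]

    reports = []
    for z, (q2, s2) in enumerate(slices):
        rep = quantify_uptake(
            q2,
            exterior,
            spectral_cube=s2,
            k=config.detection_k,
            prune_isolated=config.prune_isolated,
            closing_radius=config.closing_radius,
            cell_id=z,
        )
        logger.info(
            "%s slice %d: threshold %s -> %d positive pixels",
            name,
            z,
            rep.thresholds,
            rep.n_positive,
        )
        reports.append(rep)

    if len(reports) == 1:
        report = reports[0]
    else:  # pool z-slices
        distances = np.concatenate([r.distances_um for r in reports])
        inside = sum(r.signal_inside for r in reports)
        total = sum(r.signal_total for r in reports)
        tables = [r.pixel_table.assign(z=i) for i, r in enumerate(reports)]
        spectra = np.concatenate([r.spectra for r in reports], axis=0)
        no_d = total == 0
        report = UptakeReport(
            cell_id=0,
            distances_um=distances,
            pct_inside=float("nan") if no_d else 100.0 * inside / total,
            pct_outside=float("nan") if no_d else 100.0 - 100.0 * inside / total,
            n_positive=int(sum(r.n_positive for r in reports)),
            thresholds={"slices": [r.thresholds for r in reports], "pooled_3d": True},
            pixel_table=pd.concat(tables, ignore_index=True) if tables else reports[0].pixel_table,
            spectra=spectra,
            no_deuterium=no_d,
            signal_inside=inside,
            signal_total=total,
        )

    display = spectral.slice_2d(0) if spectral.is_3d else spectral
    band_maps = {b.name: band_auc(display, b) for b in config.bands}
    fwhm_map, score_map = deuterium_fwhm(display, noise_floor=noise_floor)
    composite = render_composite(band_maps)
    return CubeResult(
        name=name,
        cohort=cohort,
        report=report,
        band_maps=band_maps,
        fwhm_map=fwhm_map,
        score_map=score_map,
        composite=composite,
        is_3d=cube.data.ndim == 4,
    )


def _normalise_inputs(cubes) -> list[tuple[str, str, object]]:
    """Accept {cohort: [items]}, [(item, cohort)], or [items]; items may be
    paths or HyperCube objects. Returns (name, cohort, item) triples."""
    triples = []
    if isinstance(cubes, dict):
        for cohort, items in cubes.items():
            for i, item in enumerate(items):
                name = Path(item).stem if isinstance(item, (str, Path)) else f"{cohort}_{i}"
                triples.append((name, str(cohort), item))
    else:
        for i, item in enumerate(cubes):
            if isinstance(item, tuple):
                item, cohort = item
            else:
                cohort = "all"
            name = Path(item).stem if isinstance(item, (str, Path)) else f"cell_{i}"
            triples.append((name, str(cohort), item))
    if not triples:
        raise ValueError("no input cubes")
    return triples


def run_pipeline(config: PipelineConfig, cubes, out_dir) -> dict:
    """Process every cube, aggregate across cells, and write the report
    bundle (CSV tables, PNG images, HDF5 arrays, resolved config, summary
    JSON). Returns the summary dictionary.

    Deterministic: a fixed (config, inputs) pair yields byte-identical CSV
    and JSON outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")

    results: list[CubeResult] = []
    failures: list[dict] = []
    for name, cohort, item in _normalise_inputs(cubes):
        cube = item if isinstance(item, HyperCube) else rio.read_cube(item)
        try:
            results.append(process_cube(cube, config, name=name, cohort=cohort))
        except Exception as exc:  # keep partial outputs, log stage context
            logger.error("cube %s (%s) failed: %s", name, cohort, exc)
            failures.append({"cube": name, "cohort": cohort, "error": str(exc)})
    if not results:
        raise ValueError(f"all cubes failed: {failures}")

    import h5py
    import imageio.v3 as iio

    rows = []
    pixel_tables = []
    for res in results:
        cell_dir = out / res.name
        cell_dir.mkdir(exist_ok=True)
        with h5py.File(cell_dir / "maps.h5", "w") as f:
            for bname, bmap in res.band_maps.items():
                f.create_dataset(f"bands/{bname}", data=bmap.values)
            f.create_dataset("deuterium_fwhm", data=np.asarray(res.fwhm_map.values))
            f.create_dataset("deuterium_score", data=np.asarray(res.score_map.values))
        iio.imwrite(
            cell_dir / "composite.png",
            (np.clip(res.composite, 0, 1) * 255).astype(np.uint8),
        )
        rep = res.report
        table = rep.pixel_table.assign(cube=res.name, cohort=res.cohort)
        table.to_csv(cell_dir / "deuterium_pixels.csv", index=False, float_format=_FLOAT_FMT)
        pixel_tables.append(table)
        rows.append(
            {
                "cube": res.name,
                "cohort": res.cohort,
                "n_positive": rep.n_positive,
                "pct_inside": rep.pct_inside,
                "pct_outside": rep.pct_outside,
                "median_distance_um": float(np.median(rep.distances_um))
                if rep.distances_um.size
                else float("nan"),
                "median_interior_distance_um": float(
                    np.median(rep.distances_um[rep.distances_um >= 0])
                )
                if (rep.distances_um >= 0).any()
                else float("nan"),
                "no_deuterium": rep.no_deuterium,
                "is_3d": res.is_3d,
            }
        )

    cells = pd.DataFrame(rows)
    cells.to_csv(out / "uptake_by_cell.csv", index=False, float_format=_FLOAT_FMT)
    if pixel_tables:
        pd.concat(pixel_tables, ignore_index=True).to_csv(
            out / "deuterium_pixels.csv", index=False, float_format=_FLOAT_FMT
        )

    with_signal = cells[~cells["no_deuterium"]]
    cohorts = (
        with_signal.groupby("cohort")
        .agg(
            n_cells=("cube", "count"),
            mean_pct_inside=("pct_inside", "mean"),
            median_distance_um=("median_distance_um", "median"),
        )
        .reset_index()
        .sort_values("cohort")
    )
    cohorts.to_csv(out / "uptake_by_cohort.csv", index=False, float_format=_FLOAT_FMT)

    # PCA of all extracted deuterium-positive spectra across cells
    spectra = [r.report.spectra for r in results if r.report.spectra.shape[0] > 0]
    labels = np.concatenate(
        [[r.cohort] * r.report.spectra.shape[0] for r in results if r.report.spectra.shape[0] > 0]
    ) if spectra else np.empty(0, dtype=str)
    pca_summary: dict = {"fitted": False}
    if spectra:
        X = np.concatenate(spectra, axis=0)
        if X.shape[0] > config.pca_components:
            pca = fit_pca(X, config.pca_components, labels=labels)
            scores = pd.DataFrame(
                pca.scores, columns=[f"PC{i + 1}" for i in range(config.pca_components)]
            )
            scores.insert(0, "cohort", labels)
            scores.to_csv(out / "pca_scores.csv", index=False, float_format=_FLOAT_FMT)
            np.savetxt(out / "pca_loadings.csv", pca.loadings, delimiter=",", fmt=_FLOAT_FMT)
            pca_summary = {
                "fitted": True,
                "explained_variance_fraction": [float(v) for v in pca.explained_variance_fraction],
            }
            unique = sorted(set(labels.tolist()))
            pairs = {}
            for i, a in enumerate(unique):
                for b in unique[i + 1 :]:
                    if (labels == a).sum() >= 2 and (labels == b).sum() >= 2:
                        pairs[f"{a}|{b}"] = cohort_separation(pca, a, b)
            pca_summary["pc1_separation"] = pairs

    summary = {
        "n_cubes": len(results),
        "failures": failures,
        "cohorts": cohorts.to_dict(orient="records"),
        "cells": rows,
        "pca": pca_summary,
        "thresholds": {r.name: r.report.thresholds for r in results},
        "seed": config.seed,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
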