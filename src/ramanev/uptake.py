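"""Automated EV-uptake quantification.

Overlays the whole-cell (2800–3000 cm⁻¹) and deuterium (2025–2275 cm⁻¹)
univariate images to (i) segment the cell and extract its membrane, (ii)
detect deuterium-positive pixels against exterior statistics, (iii) compute
the signed Euclidean distance of each positive pixel to the nearest membrane
segment (positive = interior, in µm), (iv) partition the deuterium signal
into inside-(or associated with)-cell vs outside-of-cell percentages, and
(v) extract the deuterium-positive pixel spectra for chemometrics.

The segmentation recipe (Otsu threshold, binary closing, largest connected
component, hole filling) is a conventional choice and fully configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion, distance_transform_edt
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import closing as grey_closing, disk

from .bands import BandDefinition, BandMap, band_auc, band_net_auc
from .spectral import HyperCube

__all__ = [
    "CellMask",
    "UptakeReport",
    "segment_cell",
    "segment_cells",
    "estimate_exterior_mask",
    "exterior_stats",
    "detect_deuterium_pixels",
    "membrane_distances",
    "partition_signal",
    "extract_deuterium_spectra",
    "quantify_uptake",
]

WHOLE_CELL_BAND = BandDefinition("whole_cell", 2800.0, 3000.0)
DEUTERIUM_BAND = BandDefinition("deuterium", 2025.0, 2275.0)

EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass
class CellMask:
    """Cell footprint plus its 8-connected boundary ('membrane')."""

    mask: np.ndarray
    pixel_size_um: float = 0.5
    cell_id: int = 0
    membrane: np.ndarray = field(init=False)
    membrane_coords: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or not self.mask.any():
            raise ValueError("cell mask must be a nonempty 2D boolean image")
        # boundary pixels: in the mask, with at least one 8-neighbour outside
        self.membrane = self.mask & ~binary_erosion(self.mask, structure=EIGHT_CONNECTED)
        self.membrane_coords = np.argwhere(self.membrane)


def _postprocess_foreground(fg: np.ndarray, closing_radius: int) -> np.ndarray:
    from scipy.ndimage import binary_fill_holes

    if closing_radius > 0:
        fg = grey_closing(fg, disk(closing_radius))
    labels = cc_label(fg, connectivity=2)
    if labels.max() == 0:
        raise ValueError("no foreground found in the whole-cell image")
    sizes = np.bincount(labels.ravel())[1:]
    keep = int(np.argmax(sizes)) + 1
    return binary_fill_holes(labels == keep)


def segment_cell(
    whole_cell_map: BandMap | np.ndarray,
    pixel_size_um: float = 0.5,
    closing_radius: int = 1,
) -> CellMask:
    """Segment the (single, largest) cell from the whole-cell band image.

    Otsu threshold -> binary closing -> largest connected component -> hole
    filling; the membrane is the mask's 8-connected boundary.
    """
    values = whole_cell_map.values if isinstance(whole_cell_map, BandMap) else np.asarray(whole_cell_map)
    if values.ndim != 2:
        raise ValueError("segmentation expects a 2D map")
    if np.ptp(values) == 0:
        raise ValueError("whole-cell map is constant; cannot segment")
    threshold = threshold_otsu(values)
    mask = _postprocess_foreground(values > threshold, closing_radius)
    return CellMask(mask, pixel_size_um)


def segment_cells(
    whole_cell_map: BandMap | np.ndarray,
    pixel_size_um: float = 0.5,
    closing_radius: int = 1,
    min_area: int = 25,
) -> list[CellMask]:
    """Segment every connected component above ``min_area`` as its own cell."""
    values = whole_cell_map.values if isinstance(whole_cell_map, BandMap) else np.asarray(whole_cell_map)
    if np.ptp(values) == 0:
        raise ValueError("whole-cell map is constant; cannot segment")
    from scipy.ndimage import binary_fill_holes

    fg = values > threshold_otsu(values)
    if closing_radius > 0:
        fg = grey_closing(fg, disk(closing_radius))
    labels = cc_label(fg, connectivity=2)
    cells = []
    cell_id = 0
    for cid in range(1, labels.max() + 1):
        component = labels == cid
        if component.sum() < min_area:
            continue
        cells.append(CellMask(binary_fill_holes(component), pixel_size_um, cell_id=cell_id))
        cell_id += 1
    if not cells:
        raise ValueError("no cell-sized foreground components found")
    return cells


def estimate_exterior_mask(
    cube: HyperCube, margin: int = 3, band: BandDefinition = WHOLE_CELL_BAND
) -> np.ndarray:
    """Pixels safely exterior to any cell, from the whole-cell band image.

    Otsu foreground is dilated by ``margin`` pixels and the complement taken,
    so the exterior estimate stays clear of the membrane. For z-stacks the
    per-slice foregrounds are pooled (shared exterior mask per slice).
    """
    from scipy.ndimage import binary_dilation

    values = band_auc(cube, band).values
    if cube.is_3d:
        values = values.max(axis=-1)
    if np.ptp(values) == 0:
        raise ValueError("whole-cell map is constant; cannot locate the exterior")
    fg = values > threshold_otsu(values)
    exterior = ~binary_dilation(fg, iterations=margin, structure=EIGHT_CONNECTED)
    if not exterior.any():
        raise ValueError("no exterior pixels left after dilating the foreground")
    return exterior


@dataclass
class ExteriorStats:
    mean: float
    sd: float
    n: int


def exterior_stats(map_values: np.ndarray, exterior_mask: np.ndarray) -> ExteriorStats:
    ext = np.asarray(map_values)[np.asarray(exterior_mask, dtype=bool)]
    if ext.size == 0:
        raise ValueError("exterior mask selects no pixels")
    return ExteriorStats(float(ext.mean()), float(ext.std(ddof=1)) if ext.size > 1 else 0.0, int(ext.size))


def detect_deuterium_pixels(
    deuterium_map: BandMap | np.ndarray,
    exterior: ExteriorStats | np.ndarray,
    k: float = 3.0,
    prune_isolated: bool = False,
    fallback_quantile: float = 0.999,
) -> tuple[np.ndarray, dict]:
    """Threshold the deuterium band image against exterior statistics.

    A pixel is positive iff its value exceeds mean_exterior + k * SD_exterior
    (3-sigma rule by default). If the exterior SD is degenerate (zero where
    noise is expected, e.g. noise-free phantoms) a warning is issued and the
    threshold falls back to a high exterior quantile plus a tiny scale-aware
    offset. Returns (positive mask, info dict with the threshold used).
    """
    values = deuterium_map.values if isinstance(deuterium_map, BandMap) else np.asarray(deuterium_map)
    if isinstance(exterior, ExteriorStats):
        stats = exterior
        ext_values = None
    else:
        ext_mask = np.asarray(exterior, dtype=bool)
        stats = exterior_stats(values, ext_mask)
        ext_values = values[ext_mask]

    scale = float(np.max(np.abs(values))) or 1.0
    if stats.sd <= 1e-12 * max(abs(stats.mean), scale):
        warnings.warn(
            "degenerate exterior SD; falling back to a fixed exterior quantile",
            RuntimeWarning,
            stacklevel=2,
        )
        # absolute floor keeps numerical dust in an empty map sub-threshold
        atol = 1e-9 * max(scale, 1.0)
        if ext_values is None:
            threshold = stats.mean + atol
        else:
            threshold = float(np.quantile(ext_values, fallback_quantile)) + atol
        rule = f"quantile({fallback_quantile})"
    else:
        threshold = stats.mean + k * stats.sd
        rule = f"mean + {k}*sd"

    positive = values > threshold
    if prune_isolated:
        from scipy.ndimage import convolve

        neighbours = convolve(positive.astype(int), EIGHT_CONNECTED.astype(int), mode="constant") - positive
        positive &= neighbours > 0
    info = {
        "threshold": float(threshold),
        "rule": rule,
        "exterior_mean": stats.mean,
        "exterior_sd": stats.sd,
        "n_exterior": stats.n,
        "n_positive": int(positive.sum()),
    }
    return positive, info


def membrane_distances(deuterium_mask: np.ndarray, cell: CellMask) -> np.ndarray:
    """Signed Euclidean distance (µm) from each positive pixel to the nearest
    membrane pixel; positive inside the cell, negative outside, zero on the
    membrane. Pixels are visited in row-major order.

    Distances are centre-to-centre between pixel centres; the exact nearest
    membrane pixel is found via the Euclidean distance transform with feature
    indices, so the result matches a brute-force nearest-boundary search.
    """
    deuterium_mask = np.asarray(deuterium_mask, dtype=bool)
    if deuterium_mask.shape != cell.mask.shape:
        raise ValueError("deuterium mask and cell mask shapes differ")
    if not cell.membrane.any():
        raise ValueError("cell membrane is empty")
    _, (ir, ic) = distance_transform_edt(~cell.membrane, return_indices=True)
    coords = np.argwhere(deuterium_mask)
    if coords.size == 0:
        return np.empty(0)
    dr = coords[:, 0] - ir[coords[:, 0], coords[:, 1]]
    dc = coords[:, 1] - ic[coords[:, 0], coords[:, 1]]
    dist = np.sqrt((dr.astype(float)) ** 2 + (dc.astype(float)) ** 2) * cell.pixel_size_um
    sign = np.where(cell.mask[coords[:, 0], coords[:, 1]], 1.0, -1.0)
    return sign * dist


def partition_signal(
    deuterium_map: BandMap | np.ndarray,
    deuterium_mask: np.ndarray,
    cell: CellMask,
) -> tuple[float, float]:
    """Percentage of deuterium signal inside (or associated with) the cell vs
    outside.

    Intensity-weighted: pct_inside sums the deuterium-map values of positive
    pixels with signed membrane distance >= 0 (membrane pixels count as
    associated with the cell) over the total across all positive pixels.
    Returns (nan, nan) when there are no positive pixels.
    """
    values = deuterium_map.values if isinstance(deuterium_map, BandMap) else np.asarray(deuterium_map)
    deuterium_mask = np.asarray(deuterium_mask, dtype=bool)
    if not deuterium_mask.any():
        warnings.warn("no deuterium-positive pixels; partition undefined", RuntimeWarning, stacklevel=2)
        return float("nan"), float("nan")
    distances = membrane_distances(deuterium_mask, cell)
    weights = values[deuterium_mask]
    total = float(weights.sum())
    if total == 0:
        warnings.warn("deuterium signal sums to zero; partition undefined", RuntimeWarning, stacklevel=2)
        return float("nan"), float("nan")
    inside = float(weights[distances >= 0].sum())
    pct_inside = 100.0 * inside / total
    return pct_inside, 100.0 - pct_inside


def extract_deuterium_spectra(
    cube: HyperCube, deuterium_mask: np.ndarray, cell: CellMask | None = None, cell_id: int = 0
):
    """Spectra at deuterium-positive pixels, tagged with location and signed
    membrane distance. Returns (DataFrame, spectra array n x B)."""
    import pandas as pd

    deuterium_mask = np.asarray(deuterium_mask, dtype=bool)
    coords = np.argwhere(deuterium_mask)
    if coords.size == 0:
        warnings.warn("empty deuterium mask; no spectra extracted", RuntimeWarning, stacklevel=2)
        return (
            pd.DataFrame(columns=["cell_id", "row", "col", "distance_um"]),
            np.empty((0, cube.axis.n_bins)),
        )
    if cube.is_3d:
        raise ValueError("extract per 2D slice; use HyperCube.slice_2d first")
    spectra = cube.data[deuterium_mask]
    distances = (
        membrane_distances(deuterium_mask, cell)
        if cell is not None
        else np.full(len(coords), np.nan)
    )
    table = pd.DataFrame(
        {
            "cell_id": cell_id,
            "row": coords[:, 0],
            "col": coords[:, 1],
            "distance_um": distances,
        }
    )
    return table, spectra


@dataclass
class UptakeReport:
    """Per-cell uptake quantification results."""

    cell_id: int
    distances_um: np.ndarray
    pct_inside: float
    pct_outside: float
    n_positive: int
    thresholds: dict
    pixel_table: object  # DataFrame: cell_id, row, col, distance_um
    spectra: np.ndarray  # n_positive x B, from the spectral-shape cube
    no_deuterium: bool = False
    signal_inside: float = 0.0  # summed deuterium intensity, distance >= 0
    signal_total: float = 0.0

    def __post_init__(self) -> None:
        if not self.no_deuterium:
            total = self.pct_inside + self.pct_outside
            if abs(total - 100.0) > 1e-9:
                raise ValueError(f"inside/outside percentages sum to {total}, not 100")


def quantify_uptake(
    quant_cube: HyperCube,
    exterior_mask: np.ndarray,
    spectral_cube: HyperCube | None = None,
    k: float = 3.0,
    prune_isolated: bool = False,
    closing_radius: int = 1,
    cell_id: int = 0,
) -> UptakeReport:
    """End-to-end uptake quantification of one preprocessed 2D cube.

    ``quant_cube`` is the linear (unnormalised) corrected cube used for
    detection and intensity partition; ``spectral_cube`` (default: the same
    cube) supplies the extracted spectra, typically the AUC-normalised
    variant for chemometrics.
    """
    wc_map = band_auc(quant_cube, WHOLE_CELL_BAND)
    cell = segment_cell(wc_map, quant_cube.pixel_size_um, closing_radius=closing_radius)
    # net band integral: removes each pixel's smooth residual background so
    # detection statistics and intensity weights are clean and linear
    d_map = band_net_auc(quant_cube, DEUTERIUM_BAND)
    positive, info = detect_deuterium_pixels(d_map, exterior_mask, k=k, prune_isolated=prune_isolated)

    if not positive.any():
        return UptakeReport(
            cell_id=cell_id,
            distances_um=np.empty(0),
            pct_inside=float("nan"),
            pct_outside=float("nan"),
            n_positive=0,
            thresholds=info,
            pixel_table=extract_deuterium_spectra(quant_cube, positive, cell, cell_id)[0],
            spectra=np.empty((0, quant_cube.axis.n_bins)),
            no_deuterium=True,
        )

    distances = membrane_distances(positive, cell)
    pct_inside, pct_outside = partition_signal(d_map, positive, cell)
    weights = d_map.values[positive]
    table, spectra = extract_deuterium_spectra(
        spectral_cube if spectral_cube is not None else quant_cube, positive, cell, cell_id
    )
    return UptakeReport(
        cell_id=cell_id,
        distances_um=distances,
        pct_inside=pct_inside,
        pct_outside=pct_outside,
        n_positive=int(positive.sum()),
        thresholds=info,
        pixel_table=table,
        spectra=spectra,
        signal_inside=float(weights[distances >= 0].sum()),
        signal_total=float(weights.sum()),
    )
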