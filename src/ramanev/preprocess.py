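"""Spectral preprocessing chain: crop, 'shape' baseline filter, area
normalization, and exterior-spectrum system background subtraction.

The chain reproduces the standard confocal-Raman image workflow: spectra are
cropped to remove the laser line, autofluorescence is removed with a
morphological 'shape' filter (flat-window opening followed by smoothing with
the same window — the open reimplementation of commercial rolling-ball-style
background filters), each spectrum is normalised to unit area under the
curve, and the mean spectrum of pixels exterior to the cell is subtracted to
remove the system (substrate/buffer/optics) background.

``preprocess_cube`` applies the stages in that order as a pure function of
(cube, config). Negative post-subtraction intensities are retained so the
pipeline stays linear; all-zero pixels are flagged rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d, uniform_filter1d

from .spectral import HyperCube, SpectralAxis, Spectrum

__all__ = [
    "PreprocessConfig",
    "crop",
    "crop_cube",
    "shape_baseline",
    "auc_normalize",
    "subtract_system_background",
    "preprocess_cube",
]

DEFAULT_CROP = (400.0, 3600.0)
DEFAULT_SHAPE_SIZE = 500.0


@dataclass
class PreprocessConfig:
    """Preprocessing parameters.

    crop_range : (lo, hi) cm⁻¹ retained after laser-line removal.
    shape_size : width of the 'shape' filter structuring window, in cm⁻¹.
    normalize : per-pixel area-under-curve normalization (visualization /
        spectral-shape route). Disable for quantification where cross-pixel
        intensity linearity must be preserved.
    background_mode : "exterior_mean" subtracts the mean exterior-pixel
        spectrum; "none" skips the stage.
    """

    crop_range: tuple[float, float] = DEFAULT_CROP
    shape_size: float = DEFAULT_SHAPE_SIZE
    normalize: bool = True
    background_mode: str = "exterior_mean"

    def __post_init__(self) -> None:
        lo, hi = self.crop_range
        if not lo < hi:
            raise ValueError(f"crop range inverted: [{lo}, {hi}]")
        if self.shape_size <= 0:
            raise ValueError("shape_size must be positive")
        if self.background_mode not in ("exterior_mean", "none"):
            raise ValueError(f"unknown background_mode {self.background_mode!r}")


def crop(spectrum: Spectrum, lo: float, hi: float) -> Spectrum:
    """Retain bins with lo <= wavenumber <= hi (idempotent)."""
    sl = spectrum.axis.window_slice(lo, hi)
    return Spectrum(SpectralAxis(spectrum.axis.values[sl]), spectrum.intensities[sl], spectrum.empty)


def crop_cube(cube: HyperCube, lo: float, hi: float) -> HyperCube:
    sl = cube.axis.window_slice(lo, hi)
    return HyperCube(
        SpectralAxis(cube.axis.values[sl]),
        cube.data[..., sl],
        cube.pixel_size_um,
        cube.empty_mask,
    )


def _shape_window_bins(axis: SpectralAxis, shape_size: float) -> int:
    w = int(round(shape_size / axis.resolution))
    if w % 2 == 0:
        w += 1
    if w < 3:
        raise ValueError(
            f"shape_size {shape_size} cm-1 spans fewer than 3 bins at "
            f"{axis.resolution} cm-1 resolution"
        )
    if w > axis.n_bins:
        raise ValueError(
            f"shape_size {shape_size} cm-1 ({w} bins) exceeds the spectrum "
            f"length ({axis.n_bins} bins)"
        )
    return w


def _shape_baseline_array(data: np.ndarray, axis: SpectralAxis, shape_size: float) -> np.ndarray:
    """Lower-envelope baseline: flat-window grey opening (erosion then
    dilation) along the spectral axis, smoothed with the same window."""
    w = _shape_window_bins(axis, shape_size)
    opened = maximum_filter1d(
        minimum_filter1d(data, size=w, axis=-1, mode="nearest"),
        size=w,
        axis=-1,
        mode="nearest",
    )
    return uniform_filter1d(opened, size=w, axis=-1, mode="nearest")


def shape_baseline(
    spectrum: Spectrum, shape_size: float = DEFAULT_SHAPE_SIZE
) -> tuple[Spectrum, Spectrum]:
    """Split a spectrum into (corrected, baseline); corrected + baseline
    reconstructs the input exactly."""
    baseline = _shape_baseline_array(spectrum.intensities, spectrum.axis, shape_size)
    corrected = spectrum.intensities - baseline
    return (
        Spectrum(spectrum.axis, corrected, spectrum.empty),
        Spectrum(spectrum.axis, baseline),
    )


def shape_baseline_cube(
    cube: HyperCube, shape_size: float = DEFAULT_SHAPE_SIZE
) -> tuple[HyperCube, np.ndarray]:
    baseline = _shape_baseline_array(cube.data, cube.axis, shape_size)
    corrected = HyperCube(cube.axis, cube.data - baseline, cube.pixel_size_um, cube.empty_mask)
    return corrected, baseline


_AUC_TOL = 1e-12


def _auc_normalize_array(data: np.ndarray, axis: SpectralAxis) -> tuple[np.ndarray, np.ndarray]:
    """Normalise along the last axis to unit trapezoidal area.

    Returns (normalised, empty_flags); pixels whose absolute area is ~0 (or
    whose signed area is non-positive, so no meaningful scale exists) are
    flagged and returned unchanged.
    """
    x = axis.values
    area = np.trapezoid(data, x, axis=-1)
    abs_area = np.trapezoid(np.abs(data), x, axis=-1)
    empty = (abs_area <= _AUC_TOL) | (area <= _AUC_TOL * np.maximum(abs_area, 1.0))
    scale = np.where(empty, 1.0, area)
    return data / scale[..., None], empty


def auc_normalize(spectrum: Spectrum) -> Spectrum:
    """Scale to unit area under the curve; all-zero spectra are returned
    unchanged with the empty-pixel flag set."""
    normalised, empty = _auc_normalize_array(spectrum.intensities[None, :], spectrum.axis)
    return Spectrum(spectrum.axis, normalised[0], bool(empty[0]) or spectrum.empty)


def subtract_system_background(cube: HyperCube, exterior_mask: np.ndarray) -> HyperCube:
    """Subtract the mean exterior-pixel spectrum from every pixel.

    For z-stacks the exterior mask is shared across slices and the mean is
    taken per slice.
    """
    exterior_mask = np.asarray(exterior_mask, dtype=bool)
    if exterior_mask.shape != cube.data.shape[:2]:
        raise ValueError("exterior mask shape does not match cube")
    if not exterior_mask.any():
        raise ValueError("exterior mask is empty")
    if cube.is_3d:
        mean = cube.data[exterior_mask].mean(axis=0)  # (Z, B), per-slice mean
        data = cube.data - mean[None, None, :, :]
    else:
        mean = cube.data[exterior_mask].mean(axis=0)
        data = cube.data - mean
    return HyperCube(cube.axis, data, cube.pixel_size_um, cube.empty_mask)


def preprocess_cube(
    cube: HyperCube,
    config: PreprocessConfig | None = None,
    exterior_mask: np.ndarray | None = None,
) -> HyperCube:
    """Full chain: crop -> shape baseline -> AUC normalise -> exterior
    background subtraction. Pure function of (cube, config, exterior_mask)."""
    config = config or PreprocessConfig()
    out = crop_cube(cube, *config.crop_range)
    out, _ = shape_baseline_cube(out, config.shape_size)
    if config.normalize:
        data, empty = _auc_normalize_array(out.data, out.axis)
        prior = out.empty_mask
        out = HyperCube(
            out.axis,
            data,
            out.pixel_size_um,
            empty if prior is None else (empty | prior),
        )
    if config.background_mode == "exterior_mean":
        if exterior_mask is None:
            raise ValueError(
                "background_mode='exterior_mean' requires an exterior mask"
            )
        out = subtract_system_background(out, exterior_mask)
    return out
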