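"""Core containers: wavenumber axis, single spectra, hyperspectral cubes.

All downstream modules operate on these three types. Intensities are kept as
plain float arrays with the spectral dimension last, so the same vectorised
routines serve single spectra, 2D images (H, W, B) and z-stacks (H, W, Z, B).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpectralAxis", "Spectrum", "HyperCube", "make_axis"]

#: instrument defaults: 0–3700 cm⁻¹ range at 11 cm⁻¹ spectral resolution,
#: 0.5 µm spatial pixels
DEFAULT_AXIS_RANGE = (0.0, 3700.0)
DEFAULT_RESOLUTION = 11.0
DEFAULT_PIXEL_SIZE_UM = 0.5

_UNIFORMITY_RTOL = 1e-6


@dataclass(frozen=True)
class SpectralAxis:
    """Shared wavenumber grid (cm⁻¹), strictly increasing and uniform.

    Parameters
    ----------
    values : ndarray
        Ascending wavenumbers in cm⁻¹; spacing must be uniform to within
        1e-6 relative.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("spectral axis needs at least two wavenumber bins")
        if not np.all(np.isfinite(values)):
            raise ValueError("spectral axis contains non-finite wavenumbers")
        steps = np.diff(values)
        if np.any(steps <= 0):
            raise ValueError("spectral axis must be strictly increasing")
        mean_step = float(steps.mean())
        if np.any(np.abs(steps - mean_step) > _UNIFORMITY_RTOL * abs(mean_step)):
            raise ValueError("spectral axis spacing is not uniform")
        object.__setattr__(self, "values", values)

    @property
    def resolution(self) -> float:
        """Nominal bin spacing in cm⁻¹."""
        return float(self.values[1] - self.values[0])

    @property
    def n_bins(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n_bins

    def covers(self, wavenumber: float) -> bool:
        return bool(self.values[0] <= wavenumber <= self.values[-1])

    def nearest_bin(self, wavenumber: float) -> int:
        """Index of the bin closest to ``wavenumber`` (must lie on the axis)."""
        if not self.covers(wavenumber):
            raise ValueError(
                f"wavenumber {wavenumber} cm-1 outside axis "
                f"[{self.values[0]}, {self.values[-1]}]"
            )
        return int(np.argmin(np.abs(self.values - wavenumber)))

    def window_slice(self, lo: float, hi: float) -> slice:
        """Slice of bins with lo <= wavenumber <= hi (inclusive both ends)."""
        if lo >= hi:
            raise ValueError(f"window bounds inverted: [{lo}, {hi}]")
        i0 = int(np.searchsorted(self.values, lo, side="left"))
        i1 = int(np.searchsorted(self.values, hi, side="right"))
        if i1 - i0 < 1:
            raise ValueError(f"window [{lo}, {hi}] cm-1 contains no bins")
        return slice(i0, i1)

    def __eq__(self, other: object) -> bool:  # axes compare by grid values
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:
        return hash((self.values[0], self.values[-1], self.values.size))


def make_axis(min_cm1: float, max_cm1: float, resolution_cm1: float) -> SpectralAxis:
    """Build a uniform wavenumber grid from ``min_cm1`` with the given spacing.

    The grid starts exactly at ``min_cm1`` and extends in steps of
    ``resolution_cm1``; the last bin is the largest grid point <= ``max_cm1``
    (hence within one bin of the requested maximum).
    """
    for name, v in (("min", min_cm1), ("max", max_cm1), ("resolution", resolution_cm1)):
        if not math.isfinite(v):
            raise ValueError(f"non-finite axis {name}: {v!r}")
    if min_cm1 >= max_cm1:
        raise ValueError(f"inverted axis bounds: min {min_cm1} >= max {max_cm1}")
    if resolution_cm1 <= 0:
        raise ValueError(f"resolution must be positive, got {resolution_cm1}")
    n = int(math.floor((max_cm1 - min_cm1) / resolution_cm1)) + 1
    if n < 2:
        raise ValueError(
            f"range [{min_cm1}, {max_cm1}] at {resolution_cm1} cm-1 yields "
            "fewer than 2 bins"
        )
    values = min_cm1 + resolution_cm1 * np.arange(n, dtype=float)
    return SpectralAxis(values)


@dataclass
class Spectrum:
    """One intensity vector on a shared :class:`SpectralAxis`."""

    axis: SpectralAxis
    intensities: np.ndarray
    empty: bool = False  # quality flag, set e.g. for all-zero pixels

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (self.axis.n_bins,):
            raise ValueError(
                f"intensity length {self.intensities.shape} does not match "
                f"axis with {self.axis.n_bins} bins"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("spectrum contains non-finite intensities")

    def copy(self) -> "Spectrum":
        return Spectrum(self.axis, self.intensities.copy(), self.empty)


@dataclass
class HyperCube:
    """Hyperspectral image: (H, W, B) or (H, W, Z, B) intensities.

    The spectral dimension is always last. ``pixel_size_um`` is the in-plane
    spatial sampling (0.5 µm for the imaging configuration emulated here).
    """

    axis: SpectralAxis
    data: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    empty_mask: np.ndarray | None = field(default=None)  # quality flags, spatial shape

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError("cube data must be (H, W, B) or (H, W, Z, B)")
        if self.data.shape[-1] != self.axis.n_bins:
            raise ValueError(
                f"cube spectral dimension {self.data.shape[-1]} does not match "
                f"axis with {self.axis.n_bins} bins"
            )
        if min(self.data.shape[:2]) < 1:
            raise ValueError("cube spatial dimensions must be >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if self.empty_mask is not None:
            self.empty_mask = np.asarray(self.empty_mask, dtype=bool)
            if self.empty_mask.shape != self.spatial_shape:
                raise ValueError("empty_mask shape does not match cube")

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.data.shape[:-1]

    @property
    def is_3d(self) -> bool:
        return self.data.ndim == 4

    @property
    def n_slices(self) -> int:
        return self.data.shape[2] if self.is_3d else 1

    def slice_2d(self, z: int) -> "HyperCube":
        """Extract one z-slice as a 2D cube (no copy of the axis)."""
        if not self.is_3d:
            raise ValueError("cube is already 2D")
        return HyperCube(
            self.axis,
            self.data[:, :, z, :],
            self.pixel_size_um,
            None if self.empty_mask is None else self.empty_mask[:, :, z],
        )

    def pixel(self, row: int, col: int, z: int | None = None) -> Spectrum:
        if self.is_3d:
            vec = self.data[row, col, 0 if z is None else z, :]
        else:
            vec = self.data[row, col, :]
        empty = bool(self.empty_mask[row, col]) if (
            self.empty_mask is not None and not self.is_3d
        ) else False
        return Spectrum(self.axis, vec.copy(), empty)

    def copy(self) -> "HyperCube":
        return HyperCube(
            self.axis,
            self.data.copy(),
            self.pixel_size_um,
            None if self.empty_mask is None else self.empty_mask.copy(),
        )
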